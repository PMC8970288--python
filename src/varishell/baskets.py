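"""Pericellular basket detection and basket-by-cell-type association.

A *basket* is a dense arrangement of varicosities encircling a cell body.
The visual call is formalised here as a two-part criterion on the attributed
in-shell spots of a cell: at least ``n_min`` spots, and directional coverage
(fraction of quasi-uniform angular bins, built by a Fibonacci-sphere
partition, that contain at least one spot direction as seen from the cell
centroid) of at least ``c_min``.  Manual basket annotations override the
automatic call.  Association between basket status and ChAT/NOS type is
tested with a Pearson chi-square on the (basket, no-basket) x type table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from .celltypes import CellType, TypedCell
from .geometry import morphometry
from .scene import GanglionScene

__all__ = [
    "BasketCall",
    "BasketConfig",
    "ContingencyTable",
    "fibonacci_directions",
    "angular_coverage",
    "detect_baskets",
    "chisq_association",
    "basket_summary",
]


@dataclass(frozen=True)
class BasketConfig:
    n_min: int = 15  # minimum attributed in-shell spots
    c_min: float = 0.33  # minimum angular coverage fraction
    bins: int = 64  # Fibonacci-sphere directional bins


@dataclass
class BasketCall:
    cell_id: str
    marker: str
    is_basket: bool
    shell_count: int
    coverage: float
    source: str = "auto"  # auto | manual


@dataclass
class ContingencyTable:
    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("table shape inconsistent with labels")
        if self.counts.shape[0] < 2 or self.counts.shape[1] < 2:
            raise ValueError("contingency table must be at least 2x2")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")


def fibonacci_directions(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors on the sphere (deterministic lattice)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i  # golden-angle increments
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def angular_coverage(directions: np.ndarray, bins: int = 64) -> float:
    """Fraction of directional bins occupied by at least one direction.

    Bin membership is nearest Fibonacci-lattice vector by angle.
    """
    if len(directions) == 0:
        return 0.0
    d = np.asarray(directions, dtype=float)
    norms = np.linalg.norm(d, axis=1)
    d = d[norms > 1e-12] / norms[norms > 1e-12, None]
    if len(d) == 0:
        return 0.0
    lattice = fibonacci_directions(bins)
    # nearest unit vector by Euclidean distance == nearest by angle
    _, idx = cKDTree(lattice).query(d)
    return len(np.unique(idx)) / bins


def detect_baskets(
    typed_cells: list[TypedCell],
    scene: GanglionScene,
    attributed: dict[str, dict[str, np.ndarray]],
    cfg: BasketConfig = BasketConfig(),
) -> list[BasketCall]:
    """Basket call per (cell, marker) from attributed in-shell spots.

    ``attributed`` maps marker -> {cell_id -> (k, 3) attributed spot
    coordinates} as produced by :func:`varishell.geometry.attribute_spots`.
    Manual annotations on the typed cells override the automatic criterion.
    """
    meshes = {c.cell_id: c for c in scene.cells}
    calls: list[BasketCall] = []
    for tc in typed_cells:
        mesh = meshes.get(tc.cell_id)
        for marker in sorted(attributed):
            pts = attributed[marker].get(tc.cell_id, np.empty((0, 3)))
            count = int(len(pts))
            if mesh is None:
                raise ValueError(f"cell {tc.cell_id!r}: no mesh in scene for basket call")
            center = morphometry(mesh).centroid
            coverage = angular_coverage(pts - center, bins=cfg.bins) if count else 0.0
            manual = tc.basket_th if marker == "TH" else tc.basket_enk
            if manual is not None:
                calls.append(BasketCall(tc.cell_id, marker, bool(manual), count, coverage, "manual"))
            else:
                is_basket = count >= cfg.n_min and coverage >= cfg.c_min
                calls.append(BasketCall(tc.cell_id, marker, is_basket, count, coverage, "auto"))
    return calls


def chisq_association(table: ContingencyTable) -> tuple[float, int, float]:
    """Pearson chi-square of independence (no continuity correction)."""
    counts = table.counts
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined: zero row or column margin")
    res = stats.chi2_contingency(counts, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def basket_summary(
    calls: list[BasketCall],
    typed_cells: list[TypedCell],
    marker: str,
) -> tuple[ContingencyTable, dict[str, float]]:
    """(basket, no-basket) x cell-type table and per-type share of baskets.

    Only included cells enter the table.  The percentage dict gives, for each
    type, its share of all basket-bearing cells for this marker (the Table-2
    style breakdown).
    """
    types = {tc.cell_id: tc.cell_type for tc in typed_cells if tc.included}
    marker_calls = {c.cell_id: c for c in calls if c.marker == marker}
    missing = set(types) - set(marker_calls)
    if missing:
        raise ValueError(f"no {marker} basket call for cells {sorted(missing)[:5]}")
    order = list(CellType)
    counts = np.zeros((2, len(order)), dtype=int)
    for cell_id, ctype in types.items():
        row = 0 if marker_calls[cell_id].is_basket else 1
        counts[row, order.index(ctype)] += 1
    table = ContingencyTable(
        row_labels=["basket", "no_basket"],
        col_labels=[t.value for t in order],
        counts=counts,
    )
    n_baskets = counts[0].sum()
    pct = {
        t.value: (100.0 * counts[0, j] / n_baskets if n_baskets else 0.0)
        for j, t in enumerate(order)
    }
    return table, pct
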