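"""Four-way ChAT/NOS classification of nerve cell bodies and QC exclusion.

Each HuC/D cell body is one of four types by cholinergic (ChAT) and nitrergic
(NOS) immunoreactivity.  Cells are excluded from density analysis when they
are manually flagged, incomplete at the image border, or their surface could
not be repaired.  ChAT-/NOS- cells are kept through typing, baskets and
morphometry but dropped from the density model (too few for inference).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .geometry import CellMorphometry, morphometry
from .scene import CellLabelRecord, GanglionScene, SurfaceMesh

__all__ = [
    "CellType",
    "MODELLED_TYPES",
    "TypedCell",
    "classify_cells",
    "apply_exclusions",
    "type_proportions",
]


class CellType(enum.Enum):
    CHAT_ONLY = "ChAT+/NOS-"
    NOS_ONLY = "ChAT-/NOS+"
    CHAT_NOS = "ChAT+/NOS+"
    NEITHER = "ChAT-/NOS-"

    @classmethod
    def from_flags(cls, chat: bool, nos: bool) -> "CellType":
        return {
            (True, False): cls.CHAT_ONLY,
            (False, True): cls.NOS_ONLY,
            (True, True): cls.CHAT_NOS,
            (False, False): cls.NEITHER,
        }[(bool(chat), bool(nos))]


#: Types entering the density model (ChAT-/NOS- are excluded as too few).
MODELLED_TYPES = (CellType.CHAT_ONLY, CellType.NOS_ONLY, CellType.CHAT_NOS)


@dataclass
class TypedCell:
    cell_id: str
    cell_type: CellType
    included: bool = True
    exclusion_reason: str = ""
    morphometry: CellMorphometry | None = None
    intrinsic_th: bool = False
    basket_th: bool | None = None  # manual basket calls carried through
    basket_enk: bool | None = None


def classify_cells(
    labels: list[CellLabelRecord],
    channel_means: dict[str, tuple[float, float]] | None = None,
    chat_threshold: float = 100.0,
    nos_threshold: float = 100.0,
) -> list[TypedCell]:
    """Assign each cell a ChAT/NOS type.

    Explicit boolean labels take precedence; otherwise the cell is positive
    for a channel iff its mean intensity exceeds the channel threshold
    (``channel_means[cell_id] = (chat_mean, nos_mean)``).  A cell with
    neither source is an error.
    """
    channel_means = channel_means or {}
    out = []
    for rec in labels:
        chat, nos = rec.chat, rec.nos
        if chat is None or nos is None:
            if rec.cell_id not in channel_means:
                raise ValueError(
                    f"cell {rec.cell_id!r}: no ChAT/NOS labels and no channel intensities"
                )
            chat_mean, nos_mean = channel_means[rec.cell_id]
            chat = chat if chat is not None else chat_mean > chat_threshold
            nos = nos if nos is not None else nos_mean > nos_threshold
        out.append(
            TypedCell(
                cell_id=rec.cell_id,
                cell_type=CellType.from_flags(chat, nos),
                included=not rec.excluded,
                exclusion_reason=rec.exclusion_reason,
                intrinsic_th=bool(rec.intrinsic_th),
                basket_th=rec.basket_th,
                basket_enk=rec.basket_enk,
            )
        )
    return out


def apply_exclusions(
    cells: list[TypedCell],
    scene: GanglionScene | None = None,
    border_margin: float = 0.5,
) -> list[TypedCell]:
    """Mark cells excluded: manual flag, image-border contact, failed repair.

    A cell touches the border when its axis-aligned bounds come within
    ``border_margin`` um of a face of the scene bounding box (such cells are
    typically truncated by the imaged volume).  Morphometry is attached for
    cells whose mesh is present.  Returns the same cells, never mutating
    geometry; included + excluded partition the input.
    """
    meshes: dict[str, SurfaceMesh] = {c.cell_id: c for c in scene.cells} if scene else {}
    out = []
    for tc in cells:
        included = tc.included
        reason = tc.exclusion_reason
        if included and tc.exclusion_reason:
            included, reason = False, tc.exclusion_reason
        mesh = meshes.get(tc.cell_id)
        if scene is not None and mesh is None and included:
            included, reason = False, "mesh missing or failed repair"
        if mesh is not None and included and scene is not None:
            v = mesh.vertices
            near_lo = np.any(v.min(axis=0) - scene.bbox[0] < border_margin)
            near_hi = np.any(scene.bbox[1] - v.max(axis=0) < border_margin)
            if near_lo or near_hi:
                included, reason = False, "border"
        out.append(
            TypedCell(
                cell_id=tc.cell_id,
                cell_type=tc.cell_type,
                included=included,
                exclusion_reason=reason if not included else "",
                morphometry=morphometry(mesh) if mesh is not None else tc.morphometry,
                intrinsic_th=tc.intrinsic_th,
                basket_th=tc.basket_th,
                basket_enk=tc.basket_enk,
            )
        )
    return out


def type_proportions(cells: list[TypedCell], included_only: bool = True) -> dict:
    """Pooled per-type counts and percentages over (included) cells."""
    pool = [c for c in cells if c.included] if included_only else list(cells)
    if not pool:
        raise ValueError("type_proportions requires at least one included cell")
    counts = {t: 0 for t in CellType}
    for c in pool:
        counts[c.cell_type] += 1
    total = len(pool)
    return {
        "total": total,
        "counts": {t.value: n for t, n in counts.items()},
        "percentages": {t.value: 100.0 * n / total for t, n in counts.items()},
    }


def intrinsic_th_proportion(n_th_positive: int, n_total: int) -> float:
    """Percentage of HuC/D somata that are themselves TH-immunoreactive."""
    if n_total <= 0:
        raise ValueError("total cell count must be positive")
    return 100.0 * n_th_positive / n_total
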