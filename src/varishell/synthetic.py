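"""Synthetic myenteric ganglion scenes with exact ground truth.

Emulates the study design this package analyses: 7 subjects x 2 ganglia,
~35 reconstructed cell bodies per ganglion in four ChAT/NOS types
(≈38/42/12/8%), per-type soma volumes matching the reported morphometry, two
varicosity markers (TH, ENK) whose true perisomatic shell densities are of
order 5-20 per 1,000 um^3, negative-binomial count dispersion, nested
subject/ganglion log-scale random variation, and pericellular baskets
concentrated on ChAT+/NOS- cells.

Cell bodies are ellipsoid meshes (closed-form bookkeeping, facet size
~1 um) with random in-plane orientation — the shortest axis stays along z,
as in a flattened, stretched wholemount — packed without overlap in a
tissue slab.  Per cell x
marker a count is drawn from NB(mean = density x shell_volume x group
effects), and that many spots are placed inside the ±1 um shell,
concentrated in a few angular patches as if strung along passing axon
branches (baskets instead get a multiplied count placed area-uniformly
over the whole surface, i.e. full angular coverage — the encirclement that
distinguishes a basket from ordinary innervation).  Background spots form a homogeneous Poisson
process in the slab outside every shell.  Placement uses the same distance
engine as the analysis and is then re-verified with an exhaustive
per-triangle distance check, so generated scenes cannot silently agree with
a broken query path.

Two layers are provided:

* :func:`generate` — full 3D scenes (meshes + spots), for the geometry
  pipeline.
* :func:`simulate_model_rows` — the same count model without geometry
  (shell volumes drawn from sphere-equivalent per-type distributions), for
  calibration and parameter-recovery studies of the density model at scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .celltypes import CellType
from .density_model import ModelInputRow
from .distance import brute_force_unsigned
from .geometry import ShellConfig, shell_volume, _distance_query
from .scene import CellLabelRecord, GanglionScene, SurfaceMesh, VaricositySet, MARKERS

__all__ = [
    "GeneratorParams",
    "SyntheticTruth",
    "generate",
    "make_sphere_fixture",
    "simulate_model_rows",
]

_TYPES = list(CellType)  # canonical order: ChAT+/NOS-, ChAT-/NOS+, ChAT+/NOS+, ChAT-/NOS-


@dataclass(frozen=True)
class GeneratorParams:
    """Ground-truth parameters of the synthetic study.

    Densities are per 1,000 um^3 per (marker, cell type in canonical order);
    the first three per-type values are the study's reported posterior
    medians, the fourth (ChAT-/NOS-) is a background value of the same
    order.  Volumes are the reported per-type means (um^3).  Random-effect
    standard deviations act on the log mean count; components across the
    type x marker combinations are exchangeably correlated (staining
    intensity varies mostly globally within a subject or ganglion).
    """

    n_subjects: int = 7
    ganglia_per_subject: int = 2
    cells_per_ganglion: float = 35.0  # Poisson mean
    type_proportions: tuple[float, ...] = (0.38, 0.42, 0.12, 0.08)
    mean_volumes: tuple[float, ...] = (4566.0, 3177.0, 6078.0, 2156.0)
    densities: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "TH": (7.43, 5.59, 6.02, 5.0),
            "ENK": (19.52, 12.99, 13.22, 12.0),
        }
    )
    nb_shape: dict[str, float] = field(default_factory=lambda: {"TH": 8.0, "ENK": 5.0})
    subject_sd: float = 0.2
    ganglion_sd: float = 0.1
    effect_corr: float = 0.6
    basket_prob: dict[tuple[str, str], float] = field(
        default_factory=lambda: {("ENK", "ChAT+/NOS-"): 0.10, ("TH", "ChAT+/NOS-"): 0.02}
    )
    basket_multiplier: float = 3.0
    innervation_patches: float = 3.0  # mean number of angular patches per cell
    patch_concentration: float = 30.0  # vMF kappa of each patch (0 = uniform)
    background_intensity: float = 1e-4  # spots per um^3 per marker
    slab: tuple[float, float, float] = (400.0, 400.0, 40.0)
    border_margin: float = 3.0  # placement clearance from the bbox faces
    volume_sigma: float = 0.3  # lognormal sd of per-cell volume (log scale)
    axis_ratio_b: tuple[float, float] = (0.7, 1.0)
    axis_ratio_c: tuple[float, float] = (0.5, 0.85)
    mesh_subdivisions: int = 3
    shell_half_width: float = 1.0
    gen_voxel_pitch: float = 0.5
    min_gap: float = 2.5  # min surface-to-surface separation; keeps shells disjoint
    max_place_attempts: int = 500

    def __post_init__(self):
        if abs(sum(self.type_proportions) - 1.0) > 1e-9:
            raise ValueError("type proportions must sum to 1")
        if any(d < 0 for dd in self.densities.values() for d in dd):
            raise ValueError("densities must be >= 0")
        if any(s <= 0 for s in self.nb_shape.values()):
            raise ValueError("NB shapes must be > 0")
        if self.subject_sd < 0 or self.ganglion_sd < 0:
            raise ValueError("random-effect SDs must be >= 0")
        if self.min_gap <= 2 * self.shell_half_width:
            raise ValueError("min_gap must exceed twice the shell half-width")


@dataclass
class CellTruth:
    subject_id: str
    ganglion_id: str
    cell_id: str
    cell_type: str
    semi_axes: tuple[float, float, float]
    volume: float  # enclosed mesh volume, um^3
    shell_volume: float  # voxelized at gen_voxel_pitch, um^3
    subject_effect: dict[str, float]  # per marker, log scale
    ganglion_effect: dict[str, float]
    basket: dict[str, bool]
    expected_count: dict[str, float]  # NB mean per marker
    count: dict[str, int]  # realised count per marker


@dataclass
class SyntheticTruth:
    """Every latent quantity needed to recompute expected counts exactly."""

    params: GeneratorParams
    seed: int
    cells: list[CellTruth]
    n_background: dict[tuple[str, str, str], int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        """JSON-safe dump (tuple-keyed maps flattened to 'a|b' strings)."""
        import dataclasses

        params = dataclasses.asdict(self.params)
        params["basket_prob"] = {
            f"{m}|{t}": p for (m, t), p in self.params.basket_prob.items()
        }
        return {
            "params": params,
            "seed": self.seed,
            "cells": [dataclasses.asdict(c) for c in self.cells],
            "n_background": {"|".join(k): v for k, v in self.n_background.items()},
        }

    def expected_count(self, cell: CellTruth, marker: str) -> float:
        k = [t.value for t in _TYPES].index(cell.cell_type)
        base = (
            self.params.densities[marker][k]
            / 1000.0
            * cell.shell_volume
            * np.exp(cell.subject_effect[marker] + cell.ganglion_effect[marker])
        )
        if cell.basket[marker]:
            base *= self.params.basket_multiplier
        return base


# --------------------------------------------------------------------------- #
def _inplane_rotation(rng: np.random.Generator) -> np.ndarray:
    """Random rotation about z.  Cells keep their shortest axis along z,
    matching the flattened geometry of a stretched wholemount slab."""
    theta = rng.uniform(0.0, 2.0 * np.pi)
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _exchangeable_effects(rng, sd: float, corr: float, n: int) -> np.ndarray:
    """n-vector with Var = sd^2, pairwise correlation = corr."""
    common = rng.standard_normal() * sd * np.sqrt(corr)
    return common + rng.standard_normal(n) * sd * np.sqrt(1.0 - corr)


def _ellipsoid_cell(cell_id, semi, rotation, center, subdivisions) -> SurfaceMesh:
    mesh = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    mesh.apply_transform(
        np.vstack(
            [np.column_stack([rotation @ np.diag(semi), center]), [0.0, 0.0, 0.0, 1.0]]
        )
    )
    return SurfaceMesh.from_trimesh(str(cell_id), mesh, repair=False)


def _sample_in_shell(cell: SurfaceMesh, n: int, t: float, rng) -> np.ndarray:
    """n points uniform in the ±t shell, by rejection from the padded AABB."""
    if n == 0:
        return np.empty((0, 3))
    q = _distance_query(cell)
    lo = cell.vertices.min(axis=0) - t
    hi = cell.vertices.max(axis=0) + t
    out = []
    got = 0
    while got < n:
        batch = max(256, 4 * (n - got))
        pts = rng.uniform(lo, hi, size=(batch, 3))
        d = q.unsigned_within(pts, t)
        keep = pts[d <= t]
        out.append(keep)
        got += len(keep)
    return np.concatenate(out)[:n]


def _sample_clustered_in_shell(
    cell: SurfaceMesh, n: int, t: float, rng, n_patches_mean: float, kappa: float
) -> np.ndarray:
    """n in-shell points concentrated in a few angular patches.

    Emulates varicosities strung along a handful of axon branches passing a
    cell: candidate points are drawn uniformly in the shell and thinned by a
    von Mises-Fisher mixture over directions from the cell centroid, so
    coverage stays partial (unlike a pericellular basket).
    """
    if n == 0:
        return np.empty((0, 3))
    if kappa <= 0:
        return _sample_in_shell(cell, n, t, rng)
    # 1 + capped Poisson keeps the patch count near its mean: many patches
    # would jointly cover enough of the sphere to mimic a basket
    m = 1 + min(int(rng.poisson(max(n_patches_mean - 1.0, 0.0))), 4)
    mu = rng.standard_normal((m, 3))
    mu /= np.linalg.norm(mu, axis=1, keepdims=True)
    center = cell.vertices.mean(axis=0)
    q = _distance_query(cell)
    lo = cell.vertices.min(axis=0) - t
    hi = cell.vertices.max(axis=0) + t
    out = []
    got = 0
    while got < n:
        batch = max(512, 8 * (n - got))
        pts = rng.uniform(lo, hi, size=(batch, 3))
        d = q.unsigned_within(pts, t)
        pts = pts[d <= t]
        if len(pts) == 0:
            continue
        dirs = pts - center
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        # thinning weight: nearest-patch vMF kernel, max value 1
        w = np.exp(kappa * ((dirs @ mu.T).max(axis=1) - 1.0))
        keep = pts[rng.uniform(size=len(pts)) < w]
        out.append(keep)
        got += len(keep)
    return np.concatenate(out)[:n]


def _sample_on_surface_shell(cell: SurfaceMesh, n: int, t: float, rng) -> np.ndarray:
    """n points near the surface with area-uniform (full) angular coverage."""
    if n == 0:
        return np.empty((0, 3))
    mesh = cell.mesh
    tris = np.asarray(mesh.triangles)
    areas = np.asarray(mesh.area_faces)
    q = _distance_query(cell)
    out = []
    got = 0
    while got < n:
        batch = max(64, 2 * (n - got))
        faces = rng.choice(len(tris), size=batch, p=areas / areas.sum())
        r1, r2 = rng.uniform(size=batch), rng.uniform(size=batch)
        s1 = np.sqrt(r1)
        bary = np.column_stack([1 - s1, s1 * (1 - r2), s1 * r2])
        pts = np.einsum("bk,bkj->bj", bary, tris[faces])
        normals = np.asarray(mesh.face_normals)[faces]
        pts = pts + normals * rng.uniform(-0.9 * t, 0.9 * t, size=batch)[:, None]
        d = q.unsigned_within(pts, t)
        keep = pts[d <= t]
        out.append(keep)
        got += len(keep)
    return np.concatenate(out)[:n]


def _nb_draw(rng, mean: float, shape: float) -> int:
    if mean <= 0:
        return 0
    return int(rng.negative_binomial(shape, shape / (shape + mean)))


def _verify_spot_distances(cell: SurfaceMesh, pts: np.ndarray, t: float, rng) -> None:
    """Independent exhaustive distance check on a subsample of placed spots."""
    if len(pts) == 0:
        return
    take = pts if len(pts) <= 10 else pts[rng.choice(len(pts), 10, replace=False)]
    d = brute_force_unsigned(np.asarray(cell.mesh.triangles), take)
    if not np.all(d <= t + 1e-9):
        raise AssertionError(
            f"cell {cell.cell_id}: placed spot at distance {d.max():.4f} > {t}"
        )


def generate(
    params: GeneratorParams = GeneratorParams(), seed: int = 0
) -> tuple[list[GanglionScene], dict[str, list[CellLabelRecord]], SyntheticTruth]:
    """Generate full synthetic scenes; deterministic for a given seed.

    Returns (scenes, labels keyed by '<subject>_<ganglion>', truth).
    """
    rng = np.random.default_rng(seed)
    t = params.shell_half_width
    cfg = ShellConfig(half_width=t, voxel_pitch=params.gen_voxel_pitch)
    slab = np.asarray(params.slab)
    bbox = np.array([[0.0, 0.0, 0.0], slab])
    type_values = [ct.value for ct in _TYPES]
    scenes: list[GanglionScene] = []
    labels: dict[str, list[CellLabelRecord]] = {}
    truth_cells: list[CellTruth] = []
    n_background: dict[tuple[str, str, str], int] = {}

    for si in range(params.n_subjects):
        subject_id = f"S{si + 1:02d}"
        subj_eff = {
            m: _exchangeable_effects(rng, params.subject_sd, params.effect_corr, len(_TYPES))
            for m in MARKERS
        }
        for gi in range(params.ganglia_per_subject):
            ganglion_id = f"G{gi + 1}"
            gang_eff = {
                m: _exchangeable_effects(
                    rng, params.ganglion_sd, params.effect_corr, len(_TYPES)
                )
                for m in MARKERS
            }
            n_cells = max(1, int(rng.poisson(params.cells_per_ganglion)))
            cells: list[SurfaceMesh] = []
            placed: list[tuple[np.ndarray, float]] = []  # (center, bounding radius)
            cell_meta = []
            for ci in range(n_cells):
                k = int(rng.choice(len(_TYPES), p=params.type_proportions))
                semi = rotation = None
                for _ in range(50):  # resample until the cell fits the slab
                    vol = params.mean_volumes[k] * np.exp(
                        rng.normal(-0.5 * params.volume_sigma**2, params.volume_sigma)
                    )
                    qb = rng.uniform(*params.axis_ratio_b)
                    qc = rng.uniform(*params.axis_ratio_c)
                    a = (3.0 * vol / (4.0 * np.pi * qb * qc)) ** (1.0 / 3.0)
                    cand_semi = np.array([a, qb * a, qc * a])  # shortest along z
                    cand_rot = _inplane_rotation(rng)
                    # tight AABB half-extents of the rotated ellipsoid
                    half = np.sqrt((cand_rot**2) @ cand_semi**2)
                    if np.all(slab - 2 * (params.border_margin + half) > 0):
                        semi, rotation, half_ext = cand_semi, cand_rot, half
                        break
                if semi is None:
                    raise ValueError("slab too small for the sampled cell sizes")
                r_bound = semi.max()
                lo = params.border_margin + half_ext
                hi = slab - params.border_margin - half_ext
                center = None
                for _ in range(params.max_place_attempts):
                    cand = rng.uniform(lo, hi)
                    ok = all(
                        np.linalg.norm(cand - c0) >= r_bound + r0 + params.min_gap
                        for c0, r0 in placed
                    )
                    if ok:
                        center = cand
                        break
                if center is None:
                    raise RuntimeError(
                        f"packing failure: could not place cell {ci} in "
                        f"{subject_id}/{ganglion_id} (params too dense)"
                    )
                placed.append((center, r_bound))
                cell_id = f"{subject_id}{ganglion_id}C{ci + 1:03d}"
                cell = _ellipsoid_cell(
                    cell_id, semi, rotation, center, params.mesh_subdivisions
                )
                cells.append(cell)
                cell_meta.append((cell, k, semi))

            spots_by_marker = {m: [] for m in MARKERS}
            for cell, k, semi in cell_meta:
                v_shell = shell_volume(cell, cfg)
                basket = {}
                expected = {}
                counts = {}
                for mi, marker in enumerate(MARKERS):
                    basket[marker] = bool(
                        rng.uniform() < params.basket_prob.get((marker, type_values[k]), 0.0)
                    )
                    mean = (
                        params.densities[marker][k]
                        / 1000.0
                        * v_shell
                        * np.exp(subj_eff[marker][k] + gang_eff[marker][k])
                    )
                    if basket[marker]:
                        mean *= params.basket_multiplier
                    expected[marker] = mean
                    n_spots = _nb_draw(rng, mean, params.nb_shape[marker])
                    counts[marker] = n_spots
                    if basket[marker]:
                        pts = _sample_on_surface_shell(cell, n_spots, t, rng)
                    else:
                        pts = _sample_clustered_in_shell(
                            cell,
                            n_spots,
                            t,
                            rng,
                            params.innervation_patches,
                            params.patch_concentration,
                        )
                    _verify_spot_distances(cell, pts, t, rng)
                    spots_by_marker[marker].append(pts)
                truth_cells.append(
                    CellTruth(
                        subject_id=subject_id,
                        ganglion_id=ganglion_id,
                        cell_id=cell.cell_id,
                        cell_type=type_values[k],
                        semi_axes=tuple(semi),
                        volume=float(cell.mesh.volume),
                        shell_volume=float(v_shell),
                        subject_effect={m: float(subj_eff[m][k]) for m in MARKERS},
                        ganglion_effect={m: float(gang_eff[m][k]) for m in MARKERS},
                        basket=basket,
                        expected_count=expected,
                        count=counts,
                    )
                )

            # homogeneous background outside every shell
            slab_volume = float(np.prod(slab))
            for marker in MARKERS:
                n_bg = int(rng.poisson(params.background_intensity * slab_volume))
                if n_bg:
                    pts = rng.uniform(bbox[0], bbox[1], size=(n_bg, 3))
                    near = np.zeros(len(pts), dtype=bool)
                    for cell in cells:
                        blo = cell.vertices.min(axis=0) - t
                        bhi = cell.vertices.max(axis=0) + t
                        cand = np.flatnonzero(
                            np.all((pts >= blo) & (pts <= bhi), axis=1) & ~near
                        )
                        if cand.size:
                            d = _distance_query(cell).unsigned_within(pts[cand], t)
                            near[cand[np.isfinite(d)]] = True
                    pts = pts[~near]
                else:
                    pts = np.empty((0, 3))
                n_background[(subject_id, ganglion_id, marker)] = len(pts)
                spots_by_marker[marker].append(pts)

            varicosities = {
                m: VaricositySet(
                    marker=m,
                    points=(
                        np.concatenate(spots_by_marker[m])
                        if spots_by_marker[m]
                        else np.empty((0, 3))
                    ),
                )
                for m in MARKERS
            }
            scene = GanglionScene(
                subject_id=subject_id,
                ganglion_id=ganglion_id,
                cells=cells,
                varicosities=varicosities,
                bbox=bbox.copy(),
            )
            scenes.append(scene)
            labels[f"{subject_id}_{ganglion_id}"] = [
                CellLabelRecord(
                    cell_id=ct.cell_id,
                    chat="ChAT+" in ct.cell_type,
                    nos="NOS+" in ct.cell_type,
                )
                for ct in truth_cells
                if ct.subject_id == subject_id and ct.ganglion_id == ganglion_id
            ]

    truth = SyntheticTruth(
        params=params, seed=seed, cells=truth_cells, n_background=n_background
    )
    return scenes, labels, truth


# --------------------------------------------------------------------------- #
def make_sphere_fixture(
    radius: float = 5.0,
    n_spots_in_shell: int = 10,
    seed: int = 0,
    marker: str = "TH",
    subdivisions: int = 4,
    half_width: float = 1.0,
) -> GanglionScene:
    """Single spherical cell with exactly n spots in its ±t shell."""
    if radius <= half_width:
        raise ValueError("radius must exceed the shell half-width")
    rng = np.random.default_rng(seed)
    side = 4.0 * radius
    center = np.full(3, side / 2.0)
    mesh = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    mesh.apply_translation(center)
    cell = SurfaceMesh.from_trimesh("C001", mesh, repair=False)
    pts = _sample_in_shell(cell, n_spots_in_shell, half_width, rng)
    sets = {m: VaricositySet(marker=m, points=np.empty((0, 3))) for m in MARKERS}
    sets[marker] = VaricositySet(marker=marker, points=pts)
    return GanglionScene(
        subject_id="S01",
        ganglion_id="G1",
        cells=[cell],
        varicosities=sets,
        bbox=np.array([[0.0, 0.0, 0.0], [side, side, side]]),
    )


# --------------------------------------------------------------------------- #
def _sphere_equivalent_shell_volume(volume: float, t: float) -> float:
    r = (3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0)
    return 4.0 * np.pi / 3.0 * ((r + t) ** 3 - (r - t) ** 3)


def simulate_model_rows(
    params: GeneratorParams = GeneratorParams(), seed: int = 0
) -> tuple[list[ModelInputRow], dict]:
    """Simulate density-model input rows directly (no geometry).

    Shell volumes are sphere-equivalent volumes of the per-type soma volume
    distribution; counts follow the same NB / nested random-effect model as
    :func:`generate`.  ChAT-/NOS- cells are sampled but, as in the analysis,
    produce no model rows.  Returns (rows, truth dict).
    """
    rng = np.random.default_rng(seed)
    t = params.shell_half_width
    type_values = [ct.value for ct in _TYPES]
    modelled = type_values[:3]
    rows: list[ModelInputRow] = []
    truth = {"params": params, "seed": seed, "cells": []}
    for si in range(params.n_subjects):
        subject_id = f"S{si + 1:02d}"
        subj_eff = {
            m: _exchangeable_effects(rng, params.subject_sd, params.effect_corr, len(_TYPES))
            for m in MARKERS
        }
        for gi in range(params.ganglia_per_subject):
            ganglion_id = f"G{gi + 1}"
            gang_eff = {
                m: _exchangeable_effects(
                    rng, params.ganglion_sd, params.effect_corr, len(_TYPES)
                )
                for m in MARKERS
            }
            n_cells = max(1, int(rng.poisson(params.cells_per_ganglion)))
            for _ in range(n_cells):
                k = int(rng.choice(len(_TYPES), p=params.type_proportions))
                vol = params.mean_volumes[k] * np.exp(
                    rng.normal(-0.5 * params.volume_sigma**2, params.volume_sigma)
                )
                v_shell = _sphere_equivalent_shell_volume(vol, t)
                counts = {}
                expected = {}
                for marker in MARKERS:
                    basket = rng.uniform() < params.basket_prob.get(
                        (marker, type_values[k]), 0.0
                    )
                    mean = (
                        params.densities[marker][k]
                        / 1000.0
                        * v_shell
                        * np.exp(subj_eff[marker][k] + gang_eff[marker][k])
                    )
                    if basket:
                        mean *= params.basket_multiplier
                    expected[marker] = float(mean)
                    counts[marker] = _nb_draw(rng, mean, params.nb_shape[marker])
                    if type_values[k] in modelled:
                        rows.append(
                            ModelInputRow(
                                count=counts[marker],
                                cell_type=type_values[k],
                                marker=marker,
                                volume=float(v_shell),
                                subject=subject_id,
                                ganglion=ganglion_id,
                            )
                        )
                truth["cells"].append(
                    {
                        "subject": subject_id,
                        "ganglion": ganglion_id,
                        "cell_type": type_values[k],
                        "shell_volume": float(v_shell),
                        "expected": expected,
                        "counts": counts,
                    }
                )
    return rows, truth
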