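"""Scene data model: cell-body surfaces, varicosity point sets, ganglion scenes.

All coordinates are physical micrometres.  A *scene* corresponds to one imaged
ganglion: a set of closed triangle meshes (one per HuC/D nerve cell body), one
point set per varicosity marker, the imaged bounding box and the voxel size of
the acquisition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

#: Varicosity markers handled by default: tyrosine hydroxylase (sympathetic
#: noradrenergic axons) and enkephalin (enteric interneuron axons).
MARKERS = ("TH", "ENK")


class SceneValidationError(ValueError):
    """A scene component violates the data model."""


class MeshRepairError(SceneValidationError):
    """Mesh could not be repaired to a watertight, outward-oriented surface.

    Signals that the cell must be excluded from analysis (the imaging
    equivalent is an imperfect surface render).
    """


def as_points(points) -> np.ndarray:
    """Coerce to an (n, 3) float64 array of finite coordinates (um)."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts.reshape(1, 3)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise SceneValidationError(f"expected (n, 3) coordinates, got shape {pts.shape}")
    if pts.size and not np.isfinite(pts).all():
        raise SceneValidationError("coordinates must be finite")
    return pts


def _repair_mesh(mesh: trimesh.Trimesh) -> tuple[trimesh.Trimesh, list[str]]:
    """Attempt one round of repair; return (mesh, actions). May still fail QC."""
    actions: list[str] = []
    if not mesh.is_watertight:
        mesh.update_faces(mesh.unique_faces())
        mesh.remove_unreferenced_vertices()
        if mesh.fill_holes():
            actions.append("filled holes")
    if not mesh.is_winding_consistent:
        mesh.fix_normals()
        actions.append("fixed winding")
    if mesh.is_watertight and mesh.volume < 0:
        mesh.invert()
        actions.append("flipped inward-facing normals")
    # volume sign is only meaningful once watertight
    if mesh.is_watertight and mesh.volume < 0:
        mesh.fix_normals()
        actions.append("fixed normals")
    return mesh, actions


@dataclass
class SurfaceMesh:
    """Closed triangulated surface of one nerve cell body (um).

    Wraps a :class:`trimesh.Trimesh` validated/repaired to be watertight with
    outward normals and positive enclosed volume.
    """

    cell_id: str
    mesh: trimesh.Trimesh
    repair_log: list[str] = field(default_factory=list)

    @classmethod
    def from_trimesh(cls, cell_id: str, mesh: trimesh.Trimesh, repair: bool = True) -> "SurfaceMesh":
        if len(mesh.vertices) < 4:
            raise SceneValidationError(f"cell {cell_id!r}: mesh has fewer than 4 vertices")
        if len(mesh.faces) and mesh.faces.max() >= len(mesh.vertices):
            raise SceneValidationError(f"cell {cell_id!r}: face index out of range")
        log: list[str] = []
        if repair:
            mesh, log = _repair_mesh(mesh)
        if not mesh.is_watertight:
            raise MeshRepairError(f"cell {cell_id!r}: mesh is non-watertight after repair")
        if mesh.volume <= 0:
            raise MeshRepairError(f"cell {cell_id!r}: enclosed volume is not positive")
        return cls(cell_id=cell_id, mesh=mesh, repair_log=log)

    @classmethod
    def from_arrays(cls, cell_id: str, vertices, faces, repair: bool = True) -> "SurfaceMesh":
        vertices = as_points(vertices)
        tm = trimesh.Trimesh(vertices=vertices, faces=np.asarray(faces, dtype=int), process=False)
        return cls.from_trimesh(cell_id, tm, repair=repair)

    @property
    def vertices(self) -> np.ndarray:
        return np.asarray(self.mesh.vertices)

    @property
    def faces(self) -> np.ndarray:
        return np.asarray(self.mesh.faces)


@dataclass
class VaricositySet:
    """Marker-tagged 3D points, one per axonal varicosity."""

    marker: str
    points: np.ndarray  # (n, 3) um

    def __post_init__(self):
        if self.marker not in MARKERS:
            raise SceneValidationError(
                f"unknown marker {self.marker!r}; expected one of {MARKERS}"
            )
        self.points = as_points(self.points) if np.size(self.points) else np.empty((0, 3))

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class CellLabelRecord:
    """Manual per-cell annotations: immunoreactivity, QC exclusion, basket calls."""

    cell_id: str
    chat: bool | None = None
    nos: bool | None = None
    excluded: bool = False
    exclusion_reason: str = ""
    basket_th: bool | None = None
    basket_enk: bool | None = None
    intrinsic_th: bool = False

    def __post_init__(self):
        if self.excluded and not self.exclusion_reason:
            raise SceneValidationError(
                f"cell {self.cell_id!r}: excluded flag requires an exclusion_reason"
            )


@dataclass
class GanglionScene:
    """One imaged ganglion: cells, varicosity sets, bounding box, voxel size."""

    subject_id: str
    ganglion_id: str
    cells: list[SurfaceMesh]
    varicosities: dict[str, VaricositySet]
    bbox: np.ndarray  # (2, 3): [min_corner, max_corner] um
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.bbox = np.asarray(self.bbox, dtype=float).reshape(2, 3)
        self.validate()

    def validate(self) -> None:
        ids = [c.cell_id for c in self.cells]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise SceneValidationError(f"duplicate cell_ids in scene: {dupes}")
        if not all(v > 0 for v in self.voxel_size):
            raise SceneValidationError("voxel_size components must be > 0")
        if np.any(self.bbox[1] < self.bbox[0]):
            raise SceneValidationError("bbox max corner below min corner")
        for cell in self.cells:
            v = cell.vertices
            if np.any(v < self.bbox[0] - 1e-9) or np.any(v > self.bbox[1] + 1e-9):
                raise SceneValidationError(
                    f"cell {cell.cell_id!r} has vertices outside the scene bbox"
                )
        for marker, vs in self.varicosities.items():
            if vs.marker != marker:
                raise SceneValidationError(
                    f"varicosity set keyed {marker!r} carries marker {vs.marker!r}"
                )

    @property
    def cell_ids(self) -> list[str]:
        return [c.cell_id for c in self.cells]

    def cell(self, cell_id: str) -> SurfaceMesh:
        for c in self.cells:
            if c.cell_id == cell_id:
                return c
        raise KeyError(cell_id)
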