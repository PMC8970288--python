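"""Readers and writers for scene data and result tables.

Conventions: all coordinates and sizes in um; CSV files are comma-separated,
UTF-8, ``.`` decimal, header required.  Meshes are PLY/OBJ/STL.  A *scene
manifest* (YAML) lists, per ganglion, the mesh files, spot tables, label
table, bounding box and voxel size of one imaged scene.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import trimesh
import yaml

from .geometry import ShellDensityRecord
from .scene import (
    CellLabelRecord,
    GanglionScene,
    MeshRepairError,
    SceneValidationError,
    SurfaceMesh,
    VaricositySet,
    MARKERS,
)

__all__ = [
    "SpotTableError",
    "read_spots",
    "write_spots",
    "read_mesh",
    "write_mesh",
    "read_labels",
    "write_labels",
    "read_density_table",
    "write_density_table",
    "read_manifest",
    "write_manifest",
    "write_scene",
    "read_scene",
]


class SpotTableError(ValueError):
    """Malformed varicosity spot table; names the offending row and field."""


_SPOT_COLUMNS = ("marker", "x_um", "y_um", "z_um")


def read_spots(path, markers: tuple[str, ...] = MARKERS) -> list[VaricositySet]:
    """Read a varicosity table (columns marker,x_um,y_um,z_um) into one
    :class:`VaricositySet` per distinct marker, point order preserved."""
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in _SPOT_COLUMNS:
            if col not in header:
                raise SpotTableError(f"{path.name}: missing column {col!r}")
        by_marker: dict[str, list[list[float]]] = {}
        for row_num, row in enumerate(reader, start=1):
            marker = (row.get("marker") or "").strip()
            if marker not in markers:
                raise SpotTableError(
                    f"{path.name} row {row_num}: unknown marker {marker!r} "
                    f"(expected one of {markers})"
                )
            coords = []
            for col in ("x_um", "y_um", "z_um"):
                raw = row.get(col)
                if raw is None or raw.strip() == "":
                    raise SpotTableError(f"{path.name} row {row_num}: missing field {col!r}")
                try:
                    coords.append(float(raw))
                except ValueError:
                    raise SpotTableError(
                        f"{path.name} row {row_num}: non-numeric {col!r} value {raw!r}"
                    ) from None
            by_marker.setdefault(marker, []).append(coords)
    return [
        VaricositySet(marker=m, points=np.asarray(pts, dtype=float))
        for m, pts in by_marker.items()
    ]


def write_spots(sets: list[VaricositySet], path, overwrite: bool = False) -> None:
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists (pass overwrite=True to replace)")
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_SPOT_COLUMNS)
        for vs in sets:
            for x, y, z in vs.points:
                writer.writerow([vs.marker, repr(float(x)), repr(float(y)), repr(float(z))])


# --------------------------------------------------------------------------- #
def read_mesh(path, cell_id: str | None = None) -> SurfaceMesh:
    """Load a PLY/OBJ/STL cell-body surface (um) and validate/repair it.

    Raises :class:`MeshRepairError` if the mesh cannot be made watertight —
    the caller should exclude that cell rather than abort the run.
    """
    path = Path(path)
    loaded = trimesh.load(str(path), force="mesh", process=True)
    if not isinstance(loaded, trimesh.Trimesh) or len(loaded.faces) == 0:
        raise SceneValidationError(f"{path}: no triangle mesh found")
    return SurfaceMesh.from_trimesh(cell_id or path.stem, loaded)


def write_mesh(cell: SurfaceMesh, path, overwrite: bool = False) -> None:
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists (pass overwrite=True to replace)")
    cell.mesh.export(str(path))


# --------------------------------------------------------------------------- #
_LABEL_COLUMNS = (
    "cell_id",
    "chat",
    "nos",
    "excluded",
    "exclusion_reason",
    "basket_th",
    "basket_enk",
    "intrinsic_th",
)


def _parse_bool(raw: str | None, default=None):
    if raw is None or raw.strip() == "":
        return default
    val = raw.strip().lower()
    if val in ("true", "1", "yes"):
        return True
    if val in ("false", "0", "no"):
        return False
    raise SceneValidationError(f"cannot parse boolean value {raw!r}")


def read_labels(path) -> list[CellLabelRecord]:
    path = Path(path)
    records = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if "cell_id" not in (reader.fieldnames or []):
            raise SceneValidationError(f"{path.name}: missing column 'cell_id'")
        for row in reader:
            records.append(
                CellLabelRecord(
                    cell_id=row["cell_id"],
                    chat=_parse_bool(row.get("chat")),
                    nos=_parse_bool(row.get("nos")),
                    excluded=_parse_bool(row.get("excluded"), default=False),
                    exclusion_reason=(row.get("exclusion_reason") or "").strip(),
                    basket_th=_parse_bool(row.get("basket_th")),
                    basket_enk=_parse_bool(row.get("basket_enk")),
                    intrinsic_th=_parse_bool(row.get("intrinsic_th"), default=False),
                )
            )
    return records


def write_labels(records: list[CellLabelRecord], path, overwrite: bool = False) -> None:
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists (pass overwrite=True to replace)")

    def fmt(v):
        return "" if v is None else str(bool(v)).lower()

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_LABEL_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.cell_id,
                    fmt(r.chat),
                    fmt(r.nos),
                    fmt(r.excluded),
                    r.exclusion_reason,
                    fmt(r.basket_th),
                    fmt(r.basket_enk),
                    fmt(r.intrinsic_th),
                ]
            )


# --------------------------------------------------------------------------- #
_DENSITY_COLUMNS = (
    "subject_id",
    "ganglion_id",
    "cell_id",
    "cell_type",
    "marker",
    "count",
    "shell_volume_um3",
    "density_per_1000um3",
)


def write_density_table(records: list[ShellDensityRecord], path, overwrite: bool = False) -> None:
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists (pass overwrite=True to replace)")
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_DENSITY_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.subject_id,
                    r.ganglion_id,
                    r.cell_id,
                    r.cell_type,
                    r.marker,
                    r.count,
                    repr(float(r.shell_volume)),
                    repr(float(r.density)),
                ]
            )


def read_density_table(path) -> list[ShellDensityRecord]:
    path = Path(path)
    records = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(_DENSITY_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise SceneValidationError(f"{path.name}: missing columns {sorted(missing)}")
        for row in reader:
            records.append(
                ShellDensityRecord(
                    cell_id=row["cell_id"],
                    marker=row["marker"],
                    count=int(row["count"]),
                    shell_volume=float(row["shell_volume_um3"]),
                    density=float(row["density_per_1000um3"]),
                    subject_id=row["subject_id"],
                    ganglion_id=row["ganglion_id"],
                    cell_type=row["cell_type"],
                )
            )
    return records


# --------------------------------------------------------------------------- #
def write_scene(scene: GanglionScene, out_dir, labels=None, overwrite: bool = False) -> Path:
    """Write one scene (meshes, spots, labels) under ``out_dir`` and return
    the path of its manifest entry directory."""
    out_dir = Path(out_dir)
    scene_dir = out_dir / f"{scene.subject_id}_{scene.ganglion_id}"
    scene_dir.mkdir(parents=True, exist_ok=True)
    mesh_entries = []
    for cell in scene.cells:
        mesh_path = scene_dir / f"{cell.cell_id}.ply"
        cell.mesh.export(str(mesh_path), encoding="ascii")
        mesh_entries.append({"cell_id": cell.cell_id, "path": str(mesh_path.relative_to(out_dir))})
    spots_path = scene_dir / "spots.csv"
    write_spots(list(scene.varicosities.values()), spots_path, overwrite=overwrite)
    entry = {
        "subject_id": scene.subject_id,
        "ganglion_id": scene.ganglion_id,
        "meshes": mesh_entries,
        "spots": str(spots_path.relative_to(out_dir)),
        "bbox": scene.bbox.tolist(),
        "voxel_size": list(scene.voxel_size),
    }
    if labels is not None:
        labels_path = scene_dir / "labels.csv"
        write_labels(labels, labels_path, overwrite=overwrite)
        entry["labels"] = str(labels_path.relative_to(out_dir))
    return entry


def write_manifest(entries: list[dict], out_dir, overwrite: bool = False) -> Path:
    out_dir = Path(out_dir)
    manifest_path = out_dir / "manifest.yaml"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"{manifest_path} exists")
    with open(manifest_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump({"scenes": entries}, fh, sort_keys=False)
    return manifest_path


def read_manifest(path) -> list[dict]:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "scenes" not in doc:
        raise SceneValidationError(f"{path}: manifest must contain a 'scenes' list")
    return doc["scenes"]


def read_scene(entry: dict, root) -> tuple[GanglionScene, list[CellLabelRecord]]:
    """Materialise one manifest entry.  Cells whose mesh fails repair are
    dropped from the scene and recorded as excluded in the returned labels."""
    root = Path(root)
    cells = []
    failed: dict[str, str] = {}
    for m in entry["meshes"]:
        try:
            cells.append(read_mesh(root / m["path"], cell_id=m["cell_id"]))
        except MeshRepairError as err:
            failed[m["cell_id"]] = str(err)
    sets = read_spots(root / entry["spots"])
    scene = GanglionScene(
        subject_id=str(entry["subject_id"]),
        ganglion_id=str(entry["ganglion_id"]),
        cells=cells,
        varicosities={vs.marker: vs for vs in sets},
        bbox=np.asarray(entry["bbox"], dtype=float),
        voxel_size=tuple(entry.get("voxel_size", (1.0, 1.0, 1.0))),
    )
    labels = read_labels(root / entry["labels"]) if "labels" in entry else []
    by_id = {r.cell_id: r for r in labels}
    for cell_id, reason in failed.items():
        by_id[cell_id] = CellLabelRecord(
            cell_id=cell_id, excluded=True, exclusion_reason=f"mesh repair failed: {reason}"
        )
    return scene, list(by_id.values())
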