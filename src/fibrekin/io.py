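"""File-format plumbing: TIFF stacks, raw volumes, CSV tables, VTK.

Volumes are written as multi-page TIFF (one page per X slice) with a
JSON sidecar recording voxel size, axis order and gray-level convention,
or as raw binary with the same sidecar. Damage histories and lumen
statistics go to CSV; meshes with per-element fields go to legacy ASCII
VTK unstructured grids for visualization.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .damage import DamageCriterion, DamageHistory, DamageIncrement
from .meshing import HexMesh
from .segmentation import LumenStats
from .synthetic import VoxelVolume

__all__ = [
    "FormatError",
    "write_volume",
    "read_volume",
    "write_raw",
    "read_raw",
    "write_history_csv",
    "read_history_csv",
    "write_lumen_stats_csv",
    "write_vtk",
]


class FormatError(ValueError):
    """Malformed or inconsistent on-disk data."""


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _write_sidecar(path: Path, volume: VoxelVolume) -> None:
    meta = {
        "voxel_size_um": volume.voxel_size,
        "axis_order": "XYZ",
        "loading_axis": "X",
        "gray_levels": {"air": 0, "solid": 255},
        "shape": list(volume.shape),
        "dtype": str(volume.data.dtype),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))


def _read_sidecar(path: Path) -> dict | None:
    sc = _sidecar_path(path)
    if sc.exists():
        try:
            return json.loads(sc.read_text())
        except json.JSONDecodeError as exc:
            raise FormatError(f"malformed sidecar {sc}: {exc}") from exc
    return None


def write_volume(volume: VoxelVolume, path: str | Path) -> Path:
    """Write a multi-page TIFF (one page per X slice) plus JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(volume.data, dtype=volume.data.dtype))
    _write_sidecar(path, volume)
    return path


def read_volume(path: str | Path, voxel_size: float | None = None) -> VoxelVolume:
    """Read a TIFF stack; voxel size from the sidecar unless overridden."""
    path = Path(path)
    try:
        data = tifffile.imread(path)
    except Exception as exc:  # tifffile raises several exception types
        raise FormatError(f"cannot read TIFF volume {path}: {exc}") from exc
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise FormatError(f"expected a 3D stack in {path}, got ndim={data.ndim}")
    meta = _read_sidecar(path)
    if voxel_size is None:
        voxel_size = (meta or {}).get("voxel_size_um", 0.28)
    return VoxelVolume(data, float(voxel_size))


def write_raw(volume: VoxelVolume, path: str | Path) -> Path:
    """Write the volume as raw binary (C order) with a JSON header."""
    path = Path(path)
    np.asarray(volume.data, dtype=np.uint8).tofile(path)
    _write_sidecar(path, volume)
    return path


def read_raw(path: str | Path) -> VoxelVolume:
    path = Path(path)
    meta = _read_sidecar(path)
    if meta is None:
        raise FormatError(f"raw volume {path} requires its JSON sidecar")
    shape = tuple(meta["shape"])
    data = np.fromfile(path, dtype=meta.get("dtype", "uint8"))
    if data.size != int(np.prod(shape)):
        raise FormatError(
            f"raw volume {path}: {data.size} voxels on disk, sidecar declares {shape}"
        )
    return VoxelVolume(data.reshape(shape), float(meta["voxel_size_um"]))


# ---------------------------------------------------------------------------
# damage history

def write_history_csv(history: DamageHistory, path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {
            "increment": inc.increment,
            "U_um": repr(inc.U),
            "force_uN": repr(inc.force),
            "damage_ratio": repr(inc.damage_ratio),
            "max_criterion_MPa": repr(inc.max_criterion),
            "new_damaged_ids": " ".join(str(e) for e in inc.new_damaged),
        }
        for inc in history.increments
    ]
    df = pd.DataFrame(rows, columns=[
        "increment", "U_um", "force_uN", "damage_ratio", "max_criterion_MPa", "new_damaged_ids",
    ])
    header = f"# criterion={history.criterion.value} n_damageable={history.n_damageable} stopped={history.stopped}\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)
    return path


def read_history_csv(path: str | Path) -> DamageHistory:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# criterion="):
            raise FormatError(f"{path}: missing damage-history header line")
        fields = dict(tok.split("=", 1) for tok in first[2:].split())
        df = pd.read_csv(fh, dtype={"new_damaged_ids": str}, keep_default_na=False)
    history = DamageHistory(
        criterion=DamageCriterion(fields["criterion"]),
        n_damageable=int(fields["n_damageable"]),
        stopped=fields.get("stopped", ""),
    )
    for _, row in df.iterrows():
        ids = tuple(int(t) for t in str(row["new_damaged_ids"]).split()) if row["new_damaged_ids"] else ()
        history.increments.append(
            DamageIncrement(
                increment=int(row["increment"]),
                U=float(row["U_um"]),
                new_damaged=ids,
                damage_ratio=float(row["damage_ratio"]),
                force=float(row["force_uN"]),
                max_criterion=float(row["max_criterion_MPa"]),
            )
        )
    return history


def write_lumen_stats_csv(stats: LumenStats, path: str | Path) -> Path:
    """One row per slice, then a summary block (mean/median/porosity)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("slice,area_um2,aspect\n")
        for rec in stats.slices:
            fh.write(f"{rec.slice_index},{rec.area!r},{rec.aspect!r}\n")
        fh.write("mean,{!r},{!r}\n".format(stats.mean_area, stats.mean_aspect))
        fh.write("median,{!r},{!r}\n".format(stats.median_area, stats.median_aspect))
        fh.write(f"porosity,{stats.porosity!r},\n")
        fh.write(f"skipped_slices,{stats.n_skipped_slices},\n")
    return path


# ---------------------------------------------------------------------------
# VTK export (legacy ASCII unstructured grid, hexahedra)

def write_vtk(
    mesh: HexMesh,
    path: str | Path,
    cell_data: dict[str, np.ndarray] | None = None,
    point_data: dict[str, np.ndarray] | None = None,
) -> Path:
    """Write the hex mesh with optional per-element / per-node scalar or
    vector fields as a legacy ASCII VTK unstructured grid."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nfibrekin voxel mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} float\n")
        np.savetxt(fh, mesh.nodes, fmt="%.6g")
        ne = mesh.n_elements
        fh.write(f"CELLS {ne} {9 * ne}\n")
        cells = np.column_stack([np.full(ne, 8, dtype=np.int64), mesh.elements])
        np.savetxt(fh, cells, fmt="%d")
        fh.write(f"CELL_TYPES {ne}\n")
        np.savetxt(fh, np.full(ne, 12, dtype=np.int64), fmt="%d")  # VTK_HEXAHEDRON
        if cell_data:
            fh.write(f"CELL_DATA {ne}\n")
            _write_fields(fh, cell_data, ne)
        if point_data:
            fh.write(f"POINT_DATA {mesh.n_nodes}\n")
            _write_fields(fh, point_data, mesh.n_nodes)
    return path


def _write_fields(fh, fields: dict[str, np.ndarray], n: int) -> None:
    for name, arr in fields.items():
        arr = np.asarray(arr)
        if arr.shape[0] != n:
            raise FormatError(f"field {name!r} has {arr.shape[0]} entries, expected {n}")
        if arr.ndim == 1:
            fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, arr, fmt="%.6g")
        elif arr.ndim == 2 and arr.shape[1] == 3:
            fh.write(f"VECTORS {name} float\n")
            np.savetxt(fh, arr, fmt="%.6g")
        else:
            raise FormatError(f"field {name!r}: only scalars or 3-vectors are supported")
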