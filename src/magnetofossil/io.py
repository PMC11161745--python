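"""Artifact writers: VTK legacy STRUCTURED_POINTS, CSV tables, JSON manifests.

The VTK legacy ASCII format is simple enough to emit directly; fields are
written on the full voxel grid with zeros outside the magnetic region so
any VTK-reading tool can render occupancy, grain ids, magnetization and
helicity without a custom reader.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from .core import LEMResult, MagnetizationField
from .geometry import VoxelAssembly

__all__ = [
    "write_structured_points",
    "write_assembly_vtk",
    "write_field_checkpoint",
    "write_json",
    "sha256sum",
]


def _format_array(a: np.ndarray) -> str:
    return "\n".join(" ".join(f"{v:.9g}" for v in row) for row in a)


def write_structured_points(
    path,
    assembly: VoxelAssembly,
    scalars: dict[str, np.ndarray] | None = None,
    vectors: dict[str, np.ndarray] | None = None,
) -> Path:
    """Write grid-shaped scalar/vector fields as legacy VTK ASCII.

    Scalars have the grid shape; vectors the grid shape plus a trailing 3.
    VTK orders points with x fastest, so arrays are transposed from the
    package's (x, y, z) C-order indexing.
    """
    path = Path(path)
    nx, ny, nz = assembly.shape
    d = assembly.cell_size
    lines = [
        "# vtk DataFile Version 3.0",
        "magnetofossil voxel assembly",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {ny} {nz}",
        f"ORIGIN {assembly.origin[0]:.9g} {assembly.origin[1]:.9g} "
        f"{assembly.origin[2]:.9g}",
        f"SPACING {d:.9g} {d:.9g} {d:.9g}",
        f"POINT_DATA {nx * ny * nz}",
    ]
    for name, arr in (scalars or {}).items():
        flat = np.asarray(arr).transpose(2, 1, 0).reshape(-1, 1)
        lines.append(f"SCALARS {name} float 1")
        lines.append("LOOKUP_TABLE default")
        lines.append(_format_array(flat))
    for name, arr in (vectors or {}).items():
        flat = np.asarray(arr).transpose(2, 1, 0, 3).reshape(-1, 3)
        lines.append(f"VECTORS {name} float")
        lines.append(_format_array(flat))
    path.write_text("\n".join(lines) + "\n")
    return path


def write_assembly_vtk(path, assembly: VoxelAssembly) -> Path:
    """Occupancy and grain ids as VTK scalars, plus a JSON manifest."""
    out = write_structured_points(
        path,
        assembly,
        scalars={
            "occupancy": assembly.occupancy.astype(float),
            "grain_id": assembly.grain_id.astype(float),
        },
    )
    manifest = Path(str(path) + ".json")
    write_json(manifest, assembly.manifest())
    return out


def write_field_checkpoint(
    path,
    result: LEMResult,
    helicity: np.ndarray | None = None,
    vorticity: np.ndarray | None = None,
    extra_meta: dict | None = None,
) -> Path:
    """Magnetization (and optional helicity/vorticity) VTK + JSON sidecar."""
    fld = result.field
    scalars = {"occupancy": fld.assembly.occupancy.astype(float)}
    if helicity is not None:
        scalars["helicity"] = helicity
    vectors = {"m": fld.as_grid()}
    if vorticity is not None:
        vectors["vorticity"] = vorticity
    out = write_structured_points(path, fld.assembly, scalars, vectors)
    side = {
        "energies": result.energies.as_dict(),
        "M": result.M,
        "Mr_over_Ms": result.Mr_over_Ms,
        "Msc_Am2": result.Msc,
        "mean_m": [float(v) for v in result.mean_m],
        "init_mode": result.init_mode,
        "seed": result.seed,
        "iterations": result.iterations,
        "n_evaluations": result.n_evaluations,
        "converged": result.converged,
        "residual": result.residual,
        **(extra_meta or {}),
    }
    write_json(Path(str(path) + ".json"), side)
    return out


def write_json(path, obj) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")
    return path


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def sha256sum(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
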