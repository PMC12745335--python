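"""File output: legacy-VTK fields, STL surfaces, unit-stamped CSV, JSON.

Structured surfaces are written as VTK polydata with point-data arrays
(growth rate, stress, frames); solid meshes as VTK unstructured grids
(hex cell type 12).  Surface meshes go through trimesh (STL/PLY).  CSV
tables carry a leading ``# units:`` comment line.  Layer and region
indices in all file outputs are 1-based.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .meshmodel import SolidMesh, StructuredSurface

__all__ = [
    "write_vtk_surface",
    "write_vtk_solid",
    "write_scene_stl",
    "write_csv_with_units",
    "write_json",
]

_VTK_HEADER = "# vtk DataFile Version 3.0\n{title}\nASCII\n"


def _fmt_points(pts: np.ndarray) -> str:
    return "\n".join(" ".join(f"{x:.6f}" for x in p) for p in pts)


def _point_data_blocks(point_data: dict[str, np.ndarray], n: int) -> str:
    if not point_data:
        return ""
    out = [f"POINT_DATA {n}"]
    for name, arr in point_data.items():
        arr = np.asarray(arr, dtype=float).reshape(n, -1)
        if arr.shape[1] == 1:
            out.append(f"SCALARS {name} double 1\nLOOKUP_TABLE default")
            out.append("\n".join(f"{v:.6g}" for v in arr[:, 0]))
        elif arr.shape[1] == 3:
            out.append(f"VECTORS {name} double")
            out.append(_fmt_points(arr))
        else:
            raise ValueError(f"unsupported array width for {name}")
    return "\n".join(out) + "\n"


def write_vtk_surface(path, structured: StructuredSurface,
                      point_data: dict[str, np.ndarray] | None = None,
                      title: str = "structured aortic surface (mm)") -> Path:
    """Structured surface as VTK polydata with quad cells."""
    path = Path(path)
    nl, nc = structured.n_layers, structured.n_circ
    pts = structured.points()
    quads = []
    for j in range(nl - 1):
        for i in range(nc):
            i2 = (i + 1) % nc
            quads.append((j * nc + i, j * nc + i2, (j + 1) * nc + i2, (j + 1) * nc + i))
    with open(path, "w") as fh:
        fh.write(_VTK_HEADER.format(title=title))
        fh.write(f"DATASET POLYDATA\nPOINTS {len(pts)} double\n")
        fh.write(_fmt_points(pts) + "\n")
        fh.write(f"POLYGONS {len(quads)} {5 * len(quads)}\n")
        fh.write("\n".join("4 " + " ".join(map(str, q)) for q in quads) + "\n")
        fh.write(_point_data_blocks(point_data or {}, len(pts)))
    return path


def write_vtk_solid(path, solid: SolidMesh,
                    point_data: dict[str, np.ndarray] | None = None,
                    title: str = "solid aortic wall mesh (mm, kPa)") -> Path:
    """Solid hex mesh as a VTK unstructured grid."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_VTK_HEADER.format(title=title))
        fh.write(f"DATASET UNSTRUCTURED_GRID\nPOINTS {solid.n_nodes} double\n")
        fh.write(_fmt_points(solid.nodes) + "\n")
        fh.write(f"CELLS {solid.n_elements} {9 * solid.n_elements}\n")
        fh.write("\n".join("8 " + " ".join(map(str, h)) for h in solid.hexes) + "\n")
        fh.write(f"CELL_TYPES {solid.n_elements}\n")
        fh.write("\n".join(["12"] * solid.n_elements) + "\n")
        fh.write(_point_data_blocks(point_data or {}, solid.n_nodes))
    return path


def write_scene_stl(path, scene) -> Path:
    """Watertight outer wall as STL (plus flap as PLY alongside)."""
    path = Path(path)
    scene.outer_trimesh().export(path)
    if scene.flap is not None:
        import trimesh

        v, f = scene.flap.triangulated()
        trimesh.Trimesh(v, f, process=False).export(path.with_suffix(".flap.ply"))
    return path


def write_csv_with_units(df: pd.DataFrame, path, units: dict[str, str]) -> Path:
    """CSV with a leading ``# units:`` comment naming each column's unit."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# units: " + "; ".join(f"{k}={v}" for k, v in units.items()) + "\n")
        df.to_csv(fh, index=False)
    return path


def write_json(obj, path) -> Path:
    path = Path(path)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, default=default))
    return path
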