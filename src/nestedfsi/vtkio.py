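"""Minimal ASCII VTK-legacy writers for meshes and particle snapshots.

Only the small subset needed here is implemented (unstructured triangle
grids with point/cell data, and point clouds as VTK poly-vertex data), so the
package carries no mesh-IO dependency.  Files open directly in ParaView.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

__all__ = ["write_unstructured_grid", "write_point_cloud", "write_model"]


def _points3(points: np.ndarray) -> np.ndarray:
    points = np.asarray(points, dtype=float)
    if points.shape[1] == 2:
        points = np.column_stack([points, np.zeros(len(points))])
    return points


def _write_data_section(f, kind: str, n: int, data: dict) -> None:
    if not data:
        return
    f.write(f"{kind} {n}\n")
    for name, arr in data.items():
        arr = np.asarray(arr, dtype=float)
        if arr.ndim == 1:
            f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            np.savetxt(f, arr, fmt="%.9g")
        else:
            f.write(f"VECTORS {name} double\n")
            np.savetxt(f, _points3(arr), fmt="%.9g")


def write_unstructured_grid(path, points, triangles, point_data=None,
                            cell_data=None, title="nestedfsi mesh") -> None:
    """Write a triangle mesh with optional nodal/element fields."""
    points = _points3(points)
    triangles = np.asarray(triangles, dtype=int)
    with open(path, "w") as f:
        f.write(f"# vtk DataFile Version 3.0\n{title}\nASCII\n"
                "DATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {len(points)} double\n")
        np.savetxt(f, points, fmt="%.9g")
        m = len(triangles)
        f.write(f"CELLS {m} {4 * m}\n")
        np.savetxt(f, np.column_stack([np.full(m, 3), triangles]), fmt="%d")
        f.write(f"CELL_TYPES {m}\n")
        np.savetxt(f, np.full(m, 5), fmt="%d")  # VTK_TRIANGLE
        _write_data_section(f, "POINT_DATA", len(points), point_data or {})
        _write_data_section(f, "CELL_DATA", m, cell_data or {})


def write_point_cloud(path, positions, point_data=None,
                      title="nestedfsi particles") -> None:
    """Write a particle snapshot as VTK vertices with per-particle fields."""
    points = _points3(positions)
    n = len(points)
    with open(path, "w") as f:
        f.write(f"# vtk DataFile Version 3.0\n{title}\nASCII\n"
                "DATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {n} double\n")
        np.savetxt(f, points, fmt="%.9g")
        f.write(f"CELLS {n} {2 * n}\n")
        np.savetxt(f, np.column_stack([np.ones(n, int), np.arange(n)]), fmt="%d")
        f.write(f"CELL_TYPES {n}\n")
        np.savetxt(f, np.ones(n, int), fmt="%d")  # VTK_VERTEX
        _write_data_section(f, "POINT_DATA", n, point_data or {})


def write_model(model, outdir) -> None:
    """Write every model component as VTK plus a JSON sidecar with the
    landmark registry and a config echo."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, mesh in model.solids.items():
        write_unstructured_grid(outdir / f"{name}.vtk", mesh.nodes,
                                mesh.elements, title=name)
    for name, ps in model.fluids.items():
        write_point_cloud(outdir / f"{name}.vtk", ps.positions,
                          {"density": ps.densities, "pressure": ps.pressures,
                           "velocity": ps.velocities}, title=name)
    cfg = model.config
    sidecar = {
        "config": {k: getattr(cfg, k) for k in cfg.__dataclass_fields__},
        "landmarks": {
            lm: {"mesh": pair[0], "node": int(pair[1]),
                 "opposing_mesh": pair[2], "opposing_surface": pair[3],
                 "baseline_m": model.landmarks.baseline_distances[lm],
                 "level": model.landmarks.level(lm)}
            for lm, pair in model.landmarks.all_pairs.items()},
        "particle_counts": {k: len(v) for k, v in model.fluids.items()},
    }
    with open(outdir / "model.json", "w") as f:
        json.dump(sidecar, f, indent=2)
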