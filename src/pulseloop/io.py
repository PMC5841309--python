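"""Output writers: per-beat CSV time series, metrics JSON, and legacy
ASCII VTK snapshots of the chamber meshes with displacement/stress data.

The VTK writer emits VTK_QUADRATIC_TETRA (type 24) unstructured grids in
the legacy text format, readable by ParaView.
"""

from __future__ import annotations

import json
from pathlib import Path
import numpy as np

from .geometry import ChamberMesh
from .fe import ChamberProblem, FEState

__all__ = ["write_beats_csv", "write_metrics_json", "write_vtk",
           "write_curve_csv", "write_msh"]


def write_beats_csv(beats, path) -> None:
    """Concatenate beat records into one CSV (one row per timestep)."""
    import pandas as pd

    df = pd.concat([b.to_dataframe() for b in beats], ignore_index=True)
    df.to_csv(path, index=False)


def write_curve_csv(path, **columns) -> None:
    """Write named 1-D arrays as CSV columns (e.g. a P-D curve)."""
    import pandas as pd

    pd.DataFrame(columns).to_csv(path, index=False)


def write_metrics_json(records, path) -> None:
    """Write a list of MetricsRecord (or dicts) as JSON."""
    out = [r.as_dict() if hasattr(r, "as_dict") else dict(r) for r in records]
    Path(path).write_text(json.dumps(out, indent=2) + "\n")


def write_msh(path, mesh: ChamberMesh) -> None:
    """Gmsh v2.2 ASCII export: volume cells as 10-node tetrahedra
    (type 11) tagged 1, boundary patches as 6-node triangles (type 9)
    with one physical group per surface label.

    Gmsh orders the tet-10 edge nodes as (0,1),(1,2),(2,0),(0,3),(2,3),
    (1,3); the last two are swapped relative to the internal (VTK)
    ordering."""
    labels = sorted(mesh.surfaces)
    phys = {lab: i + 2 for i, lab in enumerate(labels)}
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat", "$PhysicalNames",
             str(len(labels) + 1), '3 1 "wall"']
    lines += [f'2 {phys[lab]} "{lab}"' for lab in labels]
    lines += ["$EndPhysicalNames", "$Nodes", str(mesh.n_nodes)]
    lines += [
        f"{i + 1} {x:.10g} {y:.10g} {z:.10g}"
        for i, (x, y, z) in enumerate(mesh.nodes)
    ]
    lines += ["$EndNodes", "$Elements"]
    n_elem = mesh.n_cells + sum(len(v) for v in mesh.surfaces.values())
    lines.append(str(n_elem))
    eid = 1
    gmsh_tet = [0, 1, 2, 3, 4, 5, 6, 7, 9, 8]
    for conn in mesh.tets:
        nodes = " ".join(str(conn[k] + 1) for k in gmsh_tet)
        lines.append(f"{eid} 11 2 1 1 {nodes}")
        eid += 1
    for lab in labels:
        for face in mesh.surfaces[lab]:
            nodes = " ".join(str(n + 1) for n in face)
            lines.append(f"{eid} 9 2 {phys[lab]} {phys[lab]} {nodes}")
            eid += 1
    lines.append("$EndElements")
    Path(path).write_text("\n".join(lines) + "\n")


def write_vtk(path, mesh: ChamberMesh, state: FEState | None = None,
              problem: ChamberProblem | None = None) -> None:
    """Legacy ASCII VTK snapshot: mesh, displacement, pressure multiplier
    and (if a problem is given) the per-cell mean Frobenius Cauchy stress."""
    n, e = mesh.n_nodes, mesh.n_cells
    lines = [
        "# vtk DataFile Version 3.0",
        f"pulseloop {mesh.chamber} chamber",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {n} double",
    ]
    pts = mesh.nodes
    lines += [" ".join(f"{x:.10g}" for x in row) for row in pts]
    lines.append(f"CELLS {e} {e * 11}")
    lines += ["10 " + " ".join(map(str, row)) for row in mesh.tets]
    lines.append(f"CELL_TYPES {e}")
    lines += ["24"] * e
    if state is not None:
        lines.append(f"POINT_DATA {n}")
        lines.append("VECTORS displacement double")
        lines += [" ".join(f"{x:.10g}" for x in row) for row in state.u]
        if problem is not None:
            sig = problem.stress_field(state)
            fro = np.sqrt((sig**2).sum(axis=(-2, -1))).mean(axis=1)
            lines.append(f"CELL_DATA {e}")
            lines.append("SCALARS frobenius_stress double 1")
            lines.append("LOOKUP_TABLE default")
            lines += [f"{v:.10g}" for v in fro]
    Path(path).write_text("\n".join(lines) + "\n")
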