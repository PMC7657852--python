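"""File I/O: suture polylines (CSV), surfaces/solids (STL), meshes and
fields (legacy ASCII VTK), result tables (CSV/JSON)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .errors import ParameterError
from .mesh import FEMesh
from .suture import SutureCurve

__all__ = [
    "write_suture_csv",
    "read_suture_csv",
    "write_vtk",
    "write_solution_vtk",
    "write_solution_summary",
]


def write_suture_csv(suture: SutureCurve, path) -> None:
    """Write a suture as a plain polyline CSV (x,y,z per row, mm)."""
    header = (
        f"# closed={int(suture.closed)} radius={suture.cylinder_radius:.9g} "
        f"axial_center={suture.axial_center:.9g}\nx_mm,y_mm,z_mm"
    )
    np.savetxt(path, suture.points, delimiter=",", header=header, comments="")


def read_suture_csv(path) -> SutureCurve:
    """Read a polyline CSV written by :func:`write_suture_csv`."""
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("#"):
        raise ParameterError("missing suture CSV header")
    meta = dict(kv.split("=") for kv in lines[0][1:].split())
    pts = np.loadtxt(lines[2:], delimiter=",")
    return SutureCurve(
        points=pts,
        cylinder_radius=float(meta["radius"]),
        axial_center=float(meta.get("axial_center", 0.0)),
        closed=bool(int(meta.get("closed", 1))),
    )


def write_vtk(path, points, cells=None, cell_type="tetra", point_data=None,
              cell_data=None, lines=None) -> None:
    """Minimal legacy ASCII VTK writer (tet/triangle cells or polylines)."""
    points = np.asarray(points, float)
    out = ["# vtk DataFile Version 3.0", "septamech output", "ASCII",
           "DATASET UNSTRUCTURED_GRID", f"POINTS {len(points)} double"]
    out += [" ".join(f"{x:.9g}" for x in p) for p in points]
    vtk_type = {"tetra": 10, "tetra10": 24, "triangle": 5, "line": 3}
    if cells is not None:
        cells = np.asarray(cells, int)
        n, k = cells.shape
        out.append(f"CELLS {n} {n * (k + 1)}")
        out += [f"{k} " + " ".join(map(str, row)) for row in cells]
        out.append(f"CELL_TYPES {n}")
        out += [str(vtk_type[cell_type])] * n
    elif lines is not None:
        n = len(lines)
        total = sum(len(l) + 1 for l in lines)
        out.append(f"CELLS {n} {total}")
        out += [f"{len(l)} " + " ".join(map(str, l)) for l in lines]
        out.append(f"CELL_TYPES {n}")
        out += ["4"] * n  # VTK_POLY_LINE
    if point_data:
        out.append(f"POINT_DATA {len(points)}")
        for name, arr in point_data.items():
            arr = np.asarray(arr, float)
            if arr.ndim == 1:
                out.append(f"SCALARS {name} double 1")
                out.append("LOOKUP_TABLE default")
                out += [f"{v:.9g}" for v in arr]
            else:
                out.append(f"FIELD {name}_field 1")
                out.append(f"{name} {arr.shape[1]} {len(points)} double")
                out += [" ".join(f"{x:.9g}" for x in row) for row in arr]
    if cell_data:
        ncell = len(cells) if cells is not None else len(lines)
        out.append(f"CELL_DATA {ncell}")
        for name, arr in cell_data.items():
            out.append(f"SCALARS {name} double 1")
            out.append("LOOKUP_TABLE default")
            out += [f"{v:.9g}" for v in np.asarray(arr, float)]
    Path(path).write_text("\n".join(out) + "\n")


def write_solution_vtk(path, solution, mesh: FEMesh | None = None) -> None:
    """Write displacements and nodal stress (Voigt) as VTK point data."""
    mesh = mesh or solution.mesh
    write_vtk(
        path,
        mesh.nodes,
        cells=mesh.tets,
        cell_type="tetra",
        point_data={
            "displacement": solution.displacements,
            "stress_voigt": solution.nodal_stress,
        },
        cell_data={"region": mesh.region.astype(float)},
    )


def write_solution_summary(path, solution, extras=None) -> None:
    """JSON summary: strain energy, displacement/stress extrema, diagnostics."""
    u = solution.displacements
    payload = {
        "pressure_MPa": solution.pressure,
        "strain_energy_mJ": solution.strain_energy,
        "max_displacement_mm": float(np.linalg.norm(u, axis=1).max()),
        "n_nodes": int(u.shape[0]),
        "diagnostics": {
            k: v
            for k, v in solution.diagnostics.items()
            if isinstance(v, (int, float, str))
        },
    }
    if extras:
        payload.update(extras)
    Path(path).write_text(json.dumps(payload, indent=1))
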