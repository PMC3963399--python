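"""Plain-text I/O: legacy-VTK meshes and fields, CSV time series, YAML configs.

Meshes and field snapshots are written in the ASCII legacy VTK unstructured
grid dialect (cell type 22 = quadratic triangle), readable by ParaView and
meshio alike; a minimal reader round-trips what the writer emits.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .geometry import EyeGeometry, ShellMesh
from .materials import make_material
from .protocols import PROTOCOLS, InfusionProtocol

__all__ = [
    "write_vtk",
    "read_vtk_points_cells",
    "write_timeseries_csv",
    "load_config",
    "geometry_from_config",
    "materials_from_config",
    "protocol_from_config",
]

_REGION_ID = {"cornea": 1, "transition": 2, "sclera": 3}


def write_vtk(path, mesh: ShellMesh, point_data: dict | None = None, cell_data: dict | None = None):
    """Write the mesh (and optional named fields) as ASCII legacy VTK.

    Point coordinates are embedded as (r, z, 0); per-element region ids
    (1 cornea, 2 transition, 3 sclera) are always included as cell data.
    """
    lines = [
        "# vtk DataFile Version 3.0",
        "axisymmetric corneoscleral shell section (r, z, 0) in mm",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    for r, z in mesh.points:
        lines.append(f"{r:.12g} {z:.12g} 0")
    lines.append(f"CELLS {mesh.n_elements} {mesh.n_elements * 7}")
    for cell in mesh.cells:
        lines.append("6 " + " ".join(str(int(i)) for i in cell))
    lines.append(f"CELL_TYPES {mesh.n_elements}")
    lines.extend(["22"] * mesh.n_elements)

    cell_data = dict(cell_data or {})
    cell_data.setdefault("region_id", np.array([_REGION_ID[r] for r in mesh.region]))
    lines.append(f"CELL_DATA {mesh.n_elements}")
    for name, values in cell_data.items():
        values = np.asarray(values)
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(f"{v:.12g}" for v in values)

    if point_data:
        lines.append(f"POINT_DATA {mesh.n_nodes}")
        for name, values in point_data.items():
            values = np.asarray(values)
            if values.ndim == 2:  # vector field (r, z) -> 3-vector
                lines.append(f"VECTORS {name} double")
                lines.extend(f"{v[0]:.12g} {v[1]:.12g} 0" for v in values)
            else:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines.extend(f"{v:.12g}" for v in values)
    Path(path).write_text("\n".join(lines) + "\n")


def read_vtk_points_cells(path):
    """Read points and quadratic-triangle connectivity back from legacy VTK."""
    tokens = Path(path).read_text().split("\n")
    points, cells = None, None
    i = 0
    while i < len(tokens):
        line = tokens[i].strip()
        if line.startswith("POINTS"):
            n = int(line.split()[1])
            vals = []
            i += 1
            while len(vals) < 3 * n:
                vals.extend(float(x) for x in tokens[i].split())
                i += 1
            points = np.asarray(vals).reshape(n, 3)[:, :2]
            continue
        if line.startswith("CELLS"):
            n = int(line.split()[1])
            rows = []
            i += 1
            for _ in range(n):
                parts = [int(x) for x in tokens[i].split()]
                if parts[0] != 6:
                    raise ValueError("only 6-node triangles supported")
                rows.append(parts[1:])
                i += 1
            cells = np.asarray(rows, dtype=np.int64)
            continue
        i += 1
    if points is None or cells is None:
        raise ValueError(f"{path} is not a recognised legacy VTK unstructured grid")
    return points, cells


def write_timeseries_csv(path, result) -> None:
    """Time series with header time_s,volume_uL,dIOP_mmHg,IOP_mmHg."""
    result.to_frame().to_csv(path, index=False)


# --------------------------------------------------------------------------
# YAML configuration


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def geometry_from_config(config: dict) -> EyeGeometry:
    """Build an EyeGeometry from the ``geometry:`` block (missing keys default)."""
    return EyeGeometry.from_dict(config.get("geometry", {}))


def materials_from_config(config: dict):
    """(cornea, sclera) materials from the ``material:`` block.

    Expected keys: instantaneous_modulus, equilibrium_modulus,
    short_time_constant, long_time_constant (corneal values, MPa / s),
    optional poisson_ratio and sclera_ratio (default 5).
    """
    block = dict(config.get("material", {}))
    ratio = float(block.pop("sclera_ratio", 5.0))
    defaults = dict(
        instantaneous_modulus=1.1,
        equilibrium_modulus=0.265,
        short_time_constant=0.35,
        long_time_constant=68.0,
        poisson_ratio=0.49,
    )
    defaults.update(block)
    cornea = make_material(
        defaults["instantaneous_modulus"],
        defaults["equilibrium_modulus"],
        defaults["short_time_constant"],
        defaults["long_time_constant"],
        defaults["poisson_ratio"],
    )
    return cornea, cornea.scaled(ratio)


def protocol_from_config(config: dict) -> InfusionProtocol:
    """Protocol from ``protocol:`` -- a named one or explicit rate/duration."""
    block = config.get("protocol", "fast")
    if isinstance(block, str):
        return PROTOCOLS[block]
    return InfusionProtocol(
        rate=float(block["rate"]),
        duration=float(block["duration"]),
        baseline_iop=float(block.get("baseline_iop", 15.0)),
        name=str(block.get("name", "custom")),
    )
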