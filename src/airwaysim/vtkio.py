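"""Minimal legacy-VTK ASCII readers/writers.

Two niche formats the pipeline exchanges with external tools: structured-
points velocity fields (import of externally computed flow solutions) and
poly-data point clouds (export of particle snapshots).  Only the legacy
ASCII dialect is supported.
"""

from __future__ import annotations

import numpy as np

from .flow import AIR_DENSITY, AIR_VISCOSITY, RegularGridField

__all__ = [
    "read_structured_velocity",
    "write_structured_velocity",
    "write_particle_polydata",
]


def write_structured_velocity(path, origin, spacing, values) -> None:
    """Write an (nx, ny, nz, 3) velocity array as STRUCTURED_POINTS."""
    values = np.asarray(values, float)
    nx, ny, nz, _ = values.shape
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("airwaysim velocity field\nASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write(f"ORIGIN {origin[0]} {origin[1]} {origin[2]}\n")
        fh.write(f"SPACING {spacing[0]} {spacing[1]} {spacing[2]}\n")
        fh.write(f"POINT_DATA {nx * ny * nz}\n")
        fh.write("VECTORS velocity double\n")
        # VTK structured points iterate x fastest
        v = values.transpose(2, 1, 0, 3).reshape(-1, 3)
        for row in v:
            fh.write(f"{row[0]:.9g} {row[1]:.9g} {row[2]:.9g}\n")


def read_structured_velocity(
    path, rho: float = AIR_DENSITY, mu: float = AIR_VISCOSITY
) -> RegularGridField:
    """Read a STRUCTURED_POINTS VECTORS file into a trilinear flow field."""
    dims = origin = spacing = None
    vectors = []
    reading = 0
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].upper()
            if key == "DIMENSIONS":
                dims = tuple(int(p) for p in parts[1:4])
            elif key == "ORIGIN":
                origin = np.array([float(p) for p in parts[1:4]])
            elif key == "SPACING":
                spacing = np.array([float(p) for p in parts[1:4]])
            elif key == "VECTORS":
                reading = dims[0] * dims[1] * dims[2]
            elif reading:
                vectors.append([float(p) for p in parts[:3]])
                reading -= 1
    if dims is None or origin is None or spacing is None or not vectors:
        raise ValueError(f"{path} is not a legacy-VTK structured velocity file")
    nx, ny, nz = dims
    values = (
        np.array(vectors).reshape(nz, ny, nx, 3).transpose(2, 1, 0, 3)
    )
    return RegularGridField(origin, spacing, values, rho=rho, mu=mu)


def write_particle_polydata(path, positions, status, diameters) -> None:
    """Particle snapshot as legacy poly-data (points + status + diameter)."""
    positions = np.atleast_2d(np.asarray(positions, float))
    status = np.asarray(status)
    diameters = np.broadcast_to(np.asarray(diameters, float), len(positions))
    n = len(positions)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("airwaysim particles\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {n} double\n")
        for p in positions:
            fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        fh.write(f"VERTICES {n} {2 * n}\n")
        for i in range(n):
            fh.write(f"1 {i}\n")
        fh.write(f"POINT_DATA {n}\n")
        fh.write("SCALARS status int 1\nLOOKUP_TABLE default\n")
        for s in status:
            fh.write(f"{int(s)}\n")
        fh.write("SCALARS diameter double 1\nLOOKUP_TABLE default\n")
        for d in diameters:
            fh.write(f"{d:.9g}\n")
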