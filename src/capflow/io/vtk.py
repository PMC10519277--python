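"""Minimal legacy-VTK ASCII writers for inspection in ParaView.

Covers the two shapes this package exports: triangulated surfaces with
per-vertex scalars (wall meshes with WSS fields, membranes with forces)
and uniform image data (domain labels, indicator, velocity magnitude).
"""
from __future__ import annotations

import numpy as np


def write_vtk_polydata(path, vertices, triangles, point_data: dict | None = None):
    """Write a triangle mesh with optional per-vertex scalar/vector fields."""
    vertices = np.asarray(vertices, dtype=float)
    triangles = np.asarray(triangles, dtype=np.int64)
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\ncapflow surface\nASCII\n")
        f.write("DATASET POLYDATA\n")
        f.write(f"POINTS {len(vertices)} float\n")
        np.savetxt(f, vertices, fmt="%.8g")
        f.write(f"POLYGONS {len(triangles)} {4 * len(triangles)}\n")
        np.savetxt(
            f,
            np.column_stack([np.full(len(triangles), 3), triangles]),
            fmt="%d",
        )
        if point_data:
            f.write(f"POINT_DATA {len(vertices)}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr, dtype=float)
                if arr.ndim == 1:
                    f.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                    np.savetxt(f, arr, fmt="%.8g")
                else:
                    f.write(f"VECTORS {name} float\n")
                    np.savetxt(f, arr, fmt="%.8g")


def write_vtk_image(path, origin, spacing, field_3d, name="field"):
    """Write a scalar field on a uniform lattice as STRUCTURED_POINTS."""
    field = np.asarray(field_3d)
    nx, ny, nz = field.shape
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\ncapflow image\nASCII\n")
        f.write("DATASET STRUCTURED_POINTS\n")
        f.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        f.write(f"ORIGIN {origin[0]} {origin[1]} {origin[2]}\n")
        f.write(f"SPACING {spacing} {spacing} {spacing}\n")
        f.write(f"POINT_DATA {nx * ny * nz}\n")
        f.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
        # VTK structured points expect x fastest
        np.savetxt(f, field.transpose(2, 1, 0).ravel(), fmt="%.8g")
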