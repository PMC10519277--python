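"""Regularized delta-function transfer between membranes and the grid.

Uses Peskin's standard 4-point immersed-boundary kernel (the piecewise
algebraic form built from the discrete delta conditions), which satisfies
the partition-of-unity and first-moment identities exactly, so spreading
conserves total force and interpolation is exact on constant and linear
fields.  Spreading and interpolation use the same kernel and are discrete
adjoints:  <spread(f), u>_grid * h^3 = <f, interp(u)>.
"""
from __future__ import annotations

import numba
import numpy as np


@numba.njit(cache=True, inline="always")
def _phi(r):
    a = abs(r)
    if a >= 2.0:
        return 0.0
    if a <= 1.0:
        return 0.125 * (3.0 - 2.0 * a + np.sqrt(1.0 + 4.0 * a - 4.0 * a * a))
    return 0.125 * (5.0 - 2.0 * a - np.sqrt(-7.0 + 12.0 * a - 4.0 * a * a))


@numba.njit(cache=True)
def spread(points, values, origin, h, shape, periodic_z, out):
    """Accumulate point forces onto a lattice as a force density (value/h^3)."""
    nx, ny, nz = shape[0], shape[1], shape[2]
    inv_h3 = 1.0 / (h * h * h)
    for p in range(points.shape[0]):
        rx = (points[p, 0] - origin[0]) / h
        ry = (points[p, 1] - origin[1]) / h
        rz = (points[p, 2] - origin[2]) / h
        ix = int(np.floor(rx)) - 1
        iy = int(np.floor(ry)) - 1
        iz = int(np.floor(rz)) - 1
        for a in range(4):
            i = ix + a
            if i < 0 or i >= nx:
                continue
            wx = _phi(rx - i)
            if wx == 0.0:
                continue
            for b in range(4):
                j = iy + b
                if j < 0 or j >= ny:
                    continue
                wy = _phi(ry - j)
                if wy == 0.0:
                    continue
                for c in range(4):
                    k = iz + c
                    wz = _phi(rz - k)
                    if wz == 0.0:
                        continue
                    if periodic_z:
                        k = k % nz
                    elif k < 0 or k >= nz:
                        continue
                    out[i, j, k] += values[p] * wx * wy * wz * inv_h3


@numba.njit(cache=True)
def interpolate(points, field, origin, h, shape, periodic_z):
    """Interpolate a lattice field at points with the same delta kernel."""
    nx, ny, nz = shape[0], shape[1], shape[2]
    out = np.zeros(points.shape[0])
    for p in range(points.shape[0]):
        rx = (points[p, 0] - origin[0]) / h
        ry = (points[p, 1] - origin[1]) / h
        rz = (points[p, 2] - origin[2]) / h
        ix = int(np.floor(rx)) - 1
        iy = int(np.floor(ry)) - 1
        iz = int(np.floor(rz)) - 1
        acc = 0.0
        for a in range(4):
            i = ix + a
            if i < 0 or i >= nx:
                continue
            wx = _phi(rx - i)
            if wx == 0.0:
                continue
            for b in range(4):
                j = iy + b
                if j < 0 or j >= ny:
                    continue
                wy = _phi(ry - j)
                if wy == 0.0:
                    continue
                for c in range(4):
                    k = iz + c
                    wz = _phi(rz - k)
                    if wz == 0.0:
                        continue
                    if periodic_z:
                        k = k % nz
                    elif k < 0 or k >= nz:
                        continue
                    acc += field[i, j, k] * wx * wy * wz
        out[p] = acc
    return out


def spread_forces(points, forces, lattice, periodic_z=False, check_support=True):
    """Spread vectorial point forces onto one component lattice.

    Returns a 3D force-density array over the lattice.  Raises if a point
    sits within kernel support of a non-periodic lattice edge (forces
    would be truncated).
    """
    pts = np.ascontiguousarray(points, dtype=np.float64)
    vals = np.ascontiguousarray(forces, dtype=np.float64)
    origin = np.asarray(lattice.origin, dtype=np.float64)
    shape = np.asarray(lattice.shape, dtype=np.int64)
    if check_support:
        r = (pts - origin) / lattice.h
        hi = shape - 1
        axes = (0, 1) if periodic_z else (0, 1, 2)
        for axis in axes:
            if np.any(r[:, axis] < 1.0) or np.any(r[:, axis] > hi[axis] - 1.0):
                raise ValueError("membrane vertex within kernel support of grid edge")
    out = np.zeros(tuple(lattice.shape), dtype=np.float64)
    spread(pts, vals, origin, lattice.h, shape, periodic_z, out)
    return out


def interpolate_field(points, field, lattice, periodic_z=False):
    """Kernel-weighted interpolation of one component field at points."""
    pts = np.ascontiguousarray(points, dtype=np.float64)
    origin = np.asarray(lattice.origin, dtype=np.float64)
    shape = np.asarray(lattice.shape, dtype=np.int64)
    return interpolate(
        pts, np.ascontiguousarray(field, dtype=np.float64), origin, lattice.h,
        shape, periodic_z,
    )
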