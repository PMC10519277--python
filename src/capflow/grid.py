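"""Uniform Cartesian lattices for the Eulerian flow discretization.

``EulerianGrid`` describes the cell decomposition of the computational box
(isotropic spacing ``h``).  The staggered solver and the ghost-node wall
machinery both operate on plain point lattices derived from it: cell centers
for pressure/viscosity/indicator, face centers for the three velocity
components.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class PointLattice:
    """A rectilinear lattice of points: ``origin + h * (i, j, k)``."""

    origin: tuple
    h: float
    shape: tuple  # number of lattice points per axis

    @property
    def n_points(self) -> int:
        return int(np.prod(self.shape))

    def axis_coords(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.h * np.arange(self.shape[axis])

    def points(self) -> np.ndarray:
        """All lattice points, C-ordered, shape (N, 3)."""
        xs, ys, zs = (self.axis_coords(a) for a in range(3))
        X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
        return np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def ravel_index(self, ijk: np.ndarray) -> np.ndarray:
        i, j, k = ijk[..., 0], ijk[..., 1], ijk[..., 2]
        return (i * self.shape[1] + j) * self.shape[2] + k

    def cell_of(self, pts: np.ndarray) -> np.ndarray:
        """Lower-corner lattice indices of the cells enclosing ``pts``."""
        return np.floor((np.asarray(pts) - np.asarray(self.origin)) / self.h).astype(int)


@dataclass(frozen=True)
class EulerianGrid:
    """Uniform isotropic cell grid covering the computational box.

    Parameters
    ----------
    origin : tuple
        Position of the lower corner of cell (0, 0, 0), um.
    h : float
        Isotropic grid spacing, um.
    shape : tuple
        Number of cells per axis.
    """

    origin: tuple
    h: float
    shape: tuple

    def __post_init__(self):
        if self.h <= 0:
            raise ValueError("grid spacing h must be positive")
        if any(n < 4 for n in self.shape):
            raise ValueError("grid needs at least 4 cells per axis")

    @property
    def extent(self) -> np.ndarray:
        return np.asarray(self.shape) * self.h

    @property
    def upper(self) -> np.ndarray:
        return np.asarray(self.origin) + self.extent

    def cell_centers(self) -> PointLattice:
        o = tuple(np.asarray(self.origin) + 0.5 * self.h)
        return PointLattice(o, self.h, tuple(self.shape))

    def face_lattice(self, axis: int, periodic: bool = False) -> PointLattice:
        """Lattice of face centers normal to ``axis``.

        With ``periodic`` the face at the upper domain boundary is identified
        with the one at the lower boundary and dropped.
        """
        o = np.asarray(self.origin) + 0.5 * self.h
        o[axis] = self.origin[axis]
        shape = list(self.shape)
        if not periodic:
            shape[axis] += 1
        return PointLattice(tuple(o), self.h, tuple(shape))

    def contains(self, pts: np.ndarray, margin: float = 0.0) -> np.ndarray:
        pts = np.atleast_2d(pts)
        lo = np.asarray(self.origin) + margin
        hi = self.upper - margin
        return np.all((pts >= lo) & (pts <= hi), axis=1)
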