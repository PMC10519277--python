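"""Indicator field tracking RBC interiors for viscosity blending.

The two fluids (plasma outside, hemoglobin solution inside the cells) are
distinguished by a smoothed indicator I(x, t) in [0, 1].  The field is
rebuilt from the instantaneous membrane configurations: the signed
distance to the nearest membrane (negative inside, from the nearest-vertex
normal test) is passed through a tanh profile of width ~ one grid cell, so
the transition layer stays under three cells.
"""
from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from ..units import MU_PLASMA
from ..membrane.mesh import vertex_normals_areas, area_volume


def update_indicator(membranes, lattice, periodic_z=False, width=0.7):
    """Indicator field on a cell lattice from closed membrane meshes.

    ``width`` is the tanh half-width in units of the lattice spacing.
    """
    shape = tuple(lattice.shape)
    I = np.zeros(shape)
    if not membranes:
        return I
    h = lattice.h
    pts = lattice.points()
    zext = lattice.shape[2] * h if periodic_z else None
    sd = np.full(len(pts), np.inf)
    for mesh in membranes:
        verts = mesh.vertices
        a, v = area_volume(mesh)
        if v <= 0:
            raise ValueError("open or inverted membrane passed to indicator update")
        vn, _ = vertex_normals_areas(verts, mesh.faces)
        reps = [0.0]
        if periodic_z:
            # image copies so cells crossing the periodic seam are seen
            zmin, zmax = verts[:, 2].min(), verts[:, 2].max()
            lat_lo = lattice.origin[2]
            if zmin < lat_lo + 2 * h:
                reps.append(zext)
            if zmax > lat_lo + zext - 2 * h:
                reps.append(-zext)
        for dz in reps:
            vv = verts + np.array([0.0, 0.0, dz])
            lo = vv.min(axis=0) - 3 * h
            hi = vv.max(axis=0) + 3 * h
            near = np.all((pts >= lo) & (pts <= hi), axis=1)
            if not np.any(near):
                continue
            tree = cKDTree(vv)
            d, idx = tree.query(pts[near])
            signed = np.einsum("ij,ij->i", pts[near] - vv[idx], vn[idx])
            sd_near = np.where(np.abs(signed) > 0, np.sign(signed), 1.0) * d
            sub = sd[near]
            sd[near] = np.where(np.abs(sd_near) < np.abs(sub), sd_near, sub)
    finite = np.isfinite(sd)
    I_flat = np.zeros(len(pts))
    I_flat[finite] = 0.5 * (1.0 - np.tanh(sd[finite] / (width * h)))
    return I_flat.reshape(shape)


def viscosity_field(I, mu_p=MU_PLASMA, mu_c=None, viscosity_ratio=5.0):
    """Pointwise viscosity blend mu = mu_p + (mu_c - mu_p) I."""
    if mu_c is None:
        mu_c = viscosity_ratio * mu_p
    if mu_c < mu_p or mu_p <= 0:
        raise ValueError("need mu_c >= mu_p > 0")
    return mu_p + (mu_c - mu_p) * np.asarray(I)
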