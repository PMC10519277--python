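"""Sharp-interface ghost-node treatment of rigid vessel walls.

The Eulerian domain is decomposed into fluid (inside the lumen) and solid
(outside) nodes.  Solid nodes with at least one fluid neighbor in the
6-neighborhood become ghost nodes (GN).  Each ghost node carries a boundary
intercept BI (nearest wall point), an image point IP mirrored across the BI
into the fluid, and trilinear interpolation weights over the 8 lattice
nodes enclosing the IP.  Enforcing

    u_GN = 2 u_BI - u_IP        (u_GN = -u_IP for a resting wall)

makes the interpolated velocity at the BI equal the wall velocity, which
imposes no-slip at the sharp interface.

All operations are generic over a uniform :class:`~capflow.grid.PointLattice`,
so the staggered flow solver can reuse them for each velocity-component
lattice and for the pressure lattice.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

FLUID, SOLID, GHOST = 0, 1, 2


@dataclass
class DomainLabels:
    """Per-lattice-node class: fluid, solid, or ghost."""

    lattice: object
    labels: np.ndarray  # flat array of FLUID/SOLID/GHOST codes
    sdf_values: np.ndarray | None = None

    @property
    def n_fluid(self):
        return int(np.count_nonzero(self.labels == FLUID))

    @property
    def n_ghost(self):
        return int(np.count_nonzero(self.labels == GHOST))


def _surface_sdf(surface):
    """Signed-distance callable for a wall surface: analytic if the surface
    carries one, otherwise mesh-based via closest-point queries."""
    if callable(surface):
        return surface
    if getattr(surface, "sdf", None) is not None:
        return surface.sdf

    tm = surface.as_trimesh()
    from trimesh.proximity import ProximityQuery

    pq = ProximityQuery(tm)

    def sdf(pts):
        # trimesh convention: positive inside; flip to negative-inside
        return -pq.signed_distance(np.atleast_2d(pts))

    return sdf


def classify_nodes(lattice, surface, periodic_axis: int | None = None) -> DomainLabels:
    """Decompose a lattice into fluid / solid / ghost against a lumen surface.

    Inside/outside is decided by the sign of the distance field (negative
    inside the lumen).  Boundary openings are handled by the distance field
    itself (analytic centerline fields extend through inlet/outlet planes).
    """
    sdf = _surface_sdf(surface)
    pts = lattice.points()
    vals = np.asarray(sdf(pts)).reshape(lattice.shape)
    labels = np.where(vals < 0.0, FLUID, SOLID).astype(np.int8)
    if not np.any(labels == FLUID):
        return DomainLabels(lattice, labels.ravel(), vals.ravel())
    fluid = labels == FLUID
    near_fluid = np.zeros_like(fluid)
    for axis in range(3):
        for shift in (-1, 1):
            if periodic_axis == axis:
                near_fluid |= np.roll(fluid, shift, axis=axis)
            else:
                sl = [slice(None)] * 3
                sl_src = [slice(None)] * 3
                if shift == 1:
                    sl[axis] = slice(1, None)
                    sl_src[axis] = slice(None, -1)
                else:
                    sl[axis] = slice(None, -1)
                    sl_src[axis] = slice(1, None)
                near_fluid[tuple(sl)] |= fluid[tuple(sl_src)]
    labels[(labels == SOLID) & near_fluid] = GHOST
    return DomainLabels(lattice, labels.ravel(), vals.ravel())


@dataclass
class GhostNodeMap:
    """Mirror-image machinery for every ghost node of a lattice."""

    lattice: object
    ghost_flat: np.ndarray      # flat lattice indices of ghost nodes
    bi: np.ndarray              # (n, 3) boundary intercepts, um
    ip: np.ndarray              # (n, 3) image points, um
    d_gn: np.ndarray            # (n,) ghost-to-BI distance
    d_ip: np.ndarray            # (n,) IP-to-BI distance
    corners: np.ndarray         # (n, 8) flat lattice indices enclosing each IP
    weights: np.ndarray         # (n, 8) trilinear weights, sum to 1
    fallback: np.ndarray        # (n,) True where the mirror distance was shrunk

    @property
    def n_ghost(self):
        return len(self.ghost_flat)


def _trilinear(lattice, pts, periodic_axis=None, clamp=False):
    r = (np.atleast_2d(pts) - np.asarray(lattice.origin)) / lattice.h
    base = np.floor(r).astype(int)
    shape = np.asarray(lattice.shape)
    if clamp:
        # shift stencils at domain edges inside; the resulting weights
        # extrapolate linearly, which stays exact on affine fields
        for axis in range(3):
            if periodic_axis != axis:
                np.clip(base[:, axis], 0, shape[axis] - 2, out=base[:, axis])
    frac = r - base
    offs = np.array(
        [[0, 0, 0], [0, 0, 1], [0, 1, 0], [0, 1, 1],
         [1, 0, 0], [1, 0, 1], [1, 1, 0], [1, 1, 1]]
    )
    idx = base[:, None, :] + offs[None, :, :]
    for axis in range(3):
        if periodic_axis == axis:
            idx[..., axis] %= shape[axis]
        else:
            if np.any(idx[..., axis] < 0) or np.any(idx[..., axis] >= shape[axis]):
                raise ValueError("interpolation stencil leaves the lattice")
    w = np.ones((len(r), 8))
    for k, off in enumerate(offs):
        for axis in range(3):
            f = frac[:, axis]
            w[:, k] *= f if off[axis] == 1 else (1.0 - f)
    flat = (idx[..., 0] * shape[1] + idx[..., 1]) * shape[2] + idx[..., 2]
    return flat, w


def build_ghost_map(
    labels: DomainLabels,
    surface,
    periodic_axis: int | None = None,
    grad_eps: float | None = None,
) -> GhostNodeMap:
    """Boundary intercepts, image points, and trilinear weights for all ghosts.

    The BI is found by stepping along the distance-field gradient; the IP is
    the mirror of the GN across the BI.  If the IP lands outside the fluid
    (thin-gap geometry) the mirror distance is shrunk until it is inside,
    with a floor of half a cell; such entries are flagged.
    """
    lattice = labels.lattice
    sdf = _surface_sdf(surface)
    h = lattice.h
    eps = grad_eps if grad_eps is not None else 1e-3 * h
    lab3 = labels.labels
    ghost_flat = np.flatnonzero(lab3 == GHOST)
    pts = lattice.points()[ghost_flat]
    d0 = np.asarray(sdf(pts))  # positive outside

    def grad(p):
        g = np.empty_like(p)
        for a in range(3):
            dp = np.zeros(3)
            dp[a] = eps
            g[:, a] = (np.asarray(sdf(p + dp)) - np.asarray(sdf(p - dp))) / (2 * eps)
        n = np.linalg.norm(g, axis=1)
        return g / np.where(n > 0, n, 1.0)[:, None]

    ghat = grad(pts)
    bi = pts - d0[:, None] * ghat
    # one Newton polish of the intercept
    resid = np.asarray(sdf(bi))
    bi = bi - resid[:, None] * grad(bi)
    d_gn = np.linalg.norm(pts - bi, axis=1)
    nhat = (pts - bi) / np.where(d_gn > 0, d_gn, 1.0)[:, None]
    # nodes lying exactly on the wall: mirror along the outward field gradient
    on_wall = d_gn <= 1e-9 * h
    if np.any(on_wall):
        nhat[on_wall] = ghat[on_wall]

    d_ip = d_gn.copy()
    ip = bi - d_ip[:, None] * nhat
    fallback = np.zeros(len(ip), dtype=bool)
    inside = np.asarray(sdf(ip)) < -0.05 * h
    for factor in (0.75, 0.5, 0.375, 0.25):
        if np.all(inside):
            break
        bad = ~inside
        trial = np.maximum(d_gn[bad] * factor, 0.5 * h)
        ip[bad] = bi[bad] - trial[:, None] * nhat[bad]
        d_ip[bad] = trial
        fallback[bad] = True
        inside[bad] = np.asarray(sdf(ip[bad])) < -0.05 * h
    corners, weights = _trilinear(lattice, ip, periodic_axis, clamp=True)
    return GhostNodeMap(lattice, ghost_flat, bi, ip, d_gn, d_ip, corners, weights, fallback)


def ghost_velocity(gmap: GhostNodeMap, u_flat: np.ndarray, u_bi=0.0) -> np.ndarray:
    """Ghost-node values enforcing the wall condition.

    ``u_flat`` is a component field over the full lattice (flat).  For a
    resting wall (u_BI = 0) this reduces to u_GN = -u_IP; with the thin-gap
    fallback the mirror is scaled by the actual distance ratio.
    """
    u_ip = np.einsum("nk,nk->n", gmap.weights, u_flat[gmap.corners])
    ratio = gmap.d_gn / gmap.d_ip
    return (1.0 + ratio) * u_bi - ratio * u_ip


def export_labels_vtk(labels: DomainLabels, path) -> None:
    """Write the fluid/solid/ghost classification as VTK image data."""
    from .io.vtk import write_vtk_image

    lat = labels.lattice
    write_vtk_image(
        path, lat.origin, lat.h,
        labels.labels.reshape(lat.shape).astype(float), name="domain_class",
    )


def ghost_matrix(gmap: GhostNodeMap) -> sp.csr_matrix:
    """Sparse operator mapping full-lattice values to ghost values
    (resting-wall case), one row per ghost node."""
    n = gmap.n_ghost
    ratio = (gmap.d_gn / gmap.d_ip)[:, None]
    rows = np.repeat(np.arange(n), 8)
    cols = gmap.corners.ravel()
    vals = (-ratio * gmap.weights).ravel()
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, gmap.lattice.n_points))
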