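"""Surface gradients of the TAWSS field.

The axial and circumferential TAWSSG components are obtained by stepping
+/- delta_s from each vertex along the local e_a / e_theta directions,
pulling the stepped points back onto the triangulated surface (closest
point), interpolating the TAWSS there (barycentric within the containing
triangle), and applying second-order central differencing.  Steps whose
pullback collapses (surface boundary nearby) fall back to one-sided
differencing and are flagged.  Units: dyne/cm^2/um.
"""
from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .traction import TAWSSField, WSSGField


def _closest_point_on_triangles(p, a, b, c):
    """Vectorized closest point on triangles (Ericson's algorithm).

    All arrays (N, 3); returns (points, barycentric (N, 3))."""
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)
    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2
    u = np.empty(len(p))
    v = np.empty(len(p))
    # region tests, in priority order
    cond_a = (d1 <= 0) & (d2 <= 0)
    cond_b = (d3 >= 0) & (d4 <= d3)
    cond_c = (d6 >= 0) & (d5 <= d6)
    denom_ab = d1 - d3
    cond_ab = (~cond_a) & (~cond_b) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    cond_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    cond_bc = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = 1.0 / (va + vb + vc)
        v_in = vb * denom
        w_in = vc * denom
        t_ab = np.where(denom_ab != 0, d1 / denom_ab, 0.0)
        t_ac = np.where((d2 - d6) != 0, d2 / (d2 - d6), 0.0)
        t_bc = np.where(((d4 - d3) + (d5 - d6)) != 0, (d4 - d3) / ((d4 - d3) + (d5 - d6)), 0.0)
    v[:] = v_in
    u[:] = w_in  # u: weight of c? keep consistent below
    bary = np.stack([1.0 - v_in - w_in, v_in, w_in], axis=1)
    bary[cond_a] = [1.0, 0.0, 0.0]
    bary[cond_b] = [0.0, 1.0, 0.0]
    bary[cond_c] = [0.0, 0.0, 1.0]
    m = cond_ab
    bary[m] = np.stack([1.0 - t_ab[m], t_ab[m], np.zeros(m.sum())], axis=1)
    m = cond_ac & ~(cond_a | cond_b | cond_c | cond_ab)
    bary[m] = np.stack([1.0 - t_ac[m], np.zeros(m.sum()), t_ac[m]], axis=1)
    m = cond_bc & ~(cond_a | cond_b | cond_c | cond_ab | cond_ac)
    bary[m] = np.stack([np.zeros(m.sum()), 1.0 - t_bc[m], t_bc[m]], axis=1)
    pts = bary[:, 0:1] * a + bary[:, 1:2] * b + bary[:, 2:3] * c
    return pts, bary


class SurfaceInterpolator:
    """Closest-point pullback and barycentric interpolation on a wall mesh."""

    def __init__(self, surface, k_candidates: int = 6):
        self.surface = surface
        self.k = k_candidates
        self._vtree = cKDTree(surface.vertices)
        nv = len(surface.vertices)
        # faces incident to each vertex
        incident = [[] for _ in range(nv)]
        for fi, tri in enumerate(surface.triangles):
            for vv in tri:
                incident[vv].append(fi)
        self._incident = incident

    def pullback(self, pts):
        """Closest surface points with interpolation data.

        Returns (points, face_ids, barycentric)."""
        pts = np.atleast_2d(pts)
        _, near = self._vtree.query(pts, k=self.k)
        near = np.atleast_2d(near)
        tris = self.surface.triangles
        verts = self.surface.vertices
        best_d = np.full(len(pts), np.inf)
        best_pt = np.zeros_like(pts)
        best_face = np.zeros(len(pts), dtype=np.int64)
        best_bary = np.zeros((len(pts), 3))
        # candidate faces per query: union of faces incident to k nearest vertices
        for col in range(near.shape[1]):
            vids = near[:, col]
            # group queries by candidate face batches
            max_inc = max((len(self._incident[v]) for v in np.unique(vids)), default=0)
            for slot in range(max_inc):
                fids = np.array(
                    [self._incident[v][slot] if slot < len(self._incident[v]) else -1
                     for v in vids]
                )
                mask = fids >= 0
                if not np.any(mask):
                    continue
                f = fids[mask]
                a, b, c = verts[tris[f, 0]], verts[tris[f, 1]], verts[tris[f, 2]]
                cp, bary = _closest_point_on_triangles(pts[mask], a, b, c)
                d = np.linalg.norm(cp - pts[mask], axis=1)
                rows = np.flatnonzero(mask)
                upd = d < best_d[rows]
                r = rows[upd]
                best_d[r] = d[upd]
                best_pt[r] = cp[upd]
                best_face[r] = f[upd]
                best_bary[r] = bary[upd]
        return best_pt, best_face, best_bary

    def interpolate(self, vertex_field, pts):
        _, faces, bary = self.pullback(pts)
        tri = self.surface.triangles[faces]
        vals = np.asarray(vertex_field)[tri]
        return np.einsum("nk,nk->n", bary, vals)


def wss_gradients(
    tawss: TAWSSField,
    frames,
    surface,
    delta_s: float | None = None,
) -> WSSGField:
    """Axial and circumferential surface gradients of the TAWSS field."""
    field = np.asarray(tawss.tawss if isinstance(tawss, TAWSSField) else tawss)
    if len(field) != len(surface.vertices):
        raise ValueError("TAWSS must be defined on all wall vertices")
    ds = delta_s if delta_s is not None else surface.mean_edge_length()
    interp = SurfaceInterpolator(surface)
    verts = surface.vertices
    out = {}
    flags = np.zeros(len(verts), dtype=bool)
    for name, e in (("axial", frames.e_a), ("circ", frames.e_theta)):
        plus = verts + ds * e
        minus = verts - ds * e
        pp, fp_, bp = interp.pullback(plus)
        pm, fm, bm = interp.pullback(minus)
        vp = np.einsum("nk,nk->n", bp, field[surface.triangles[fp_]])
        vm = np.einsum("nk,nk->n", bm, field[surface.triangles[fm]])
        # effective arc steps after pullback
        dp = np.linalg.norm(pp - verts, axis=1)
        dm = np.linalg.norm(pm - verts, axis=1)
        grad = (vp - vm) / (2.0 * ds)
        # degenerate pullback (boundary): one-sided
        bad_p = dp < 0.25 * ds
        bad_m = dm < 0.25 * ds
        one_sided = bad_p ^ bad_m
        grad[one_sided & bad_m] = (vp[one_sided & bad_m] - field[one_sided & bad_m]) / ds
        grad[one_sided & bad_p] = (field[one_sided & bad_p] - vm[one_sided & bad_p]) / ds
        grad[bad_p & bad_m] = 0.0
        flags |= bad_p | bad_m
        out[name] = grad
    return WSSGField(out["axial"], out["circ"], flags)
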