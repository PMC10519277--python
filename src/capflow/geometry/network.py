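"""Interconnected network surfaces from implicit unions of swept tubes.

Junction regions are produced by re-meshing the zero level set of the
union signed-distance field (marching cubes at the target edge length),
which blends branches of arbitrary angles without interior walls.  A
single-centerline spec short-circuits to the parametric sweep.
"""
from __future__ import annotations

import numpy as np
import trimesh
from scipy.spatial import cKDTree
from skimage import measure

from .centerline import NetworkSpec
from .surface import WallSurface
from .sweep import sweep_surface


def _clip_boundary_ends(verts, faces, ends, inset):
    """Remove faces beyond each boundary-end plane, opening the tube caps."""
    keep = np.ones(len(faces), dtype=bool)
    cent = verts[faces].mean(axis=1)
    for (_, _, pt, tangent, _, _) in ends:
        d = np.einsum("ij,j->i", cent - (pt - inset * tangent), tangent)
        keep &= d < 0.0
    return faces[keep]


def label_vertices(spec: NetworkSpec, verts: np.ndarray, collar: float = 1.0):
    """Per-vertex vessel label by nearest centerline; vertices within
    ``collar`` diameters of a junction point get the junction label -1."""
    samples, labels = [], []
    for c in spec.centerlines:
        cl = c.resample(0.25)
        samples.append(cl.points)
        labels.append(np.full(len(cl.points), c.label))
    samples = np.vstack(samples)
    labels = np.concatenate(labels)
    tree = cKDTree(samples)
    _, idx = tree.query(verts)
    out = labels[idx]
    for j in spec.junctions:
        pos = np.asarray(j.position)
        # collar radius scaled by the largest radius meeting at the junction
        rad = max(
            (spec.by_label(lbl).radii.max() if lbl != "interior" else 0.0)
            for lbl, _ in j.ends
        )
        d = np.linalg.norm(verts - pos, axis=1)
        out = np.where(d < 2.0 * collar * rad, -1, out)
    return out


def build_network(spec: NetworkSpec, target_edge: float) -> WallSurface:
    """Triangulated wall surface of a vessel network.

    Single straight-through specs reduce to :func:`sweep_surface`; anything
    with junctions or obstructions is meshed from the implicit union.
    """
    if len(spec.centerlines) == 1 and not spec.junctions and not spec.obstructions:
        c = spec.centerlines[0]
        m = max(8, int(round(2.0 * np.pi * float(np.mean(c.radii)) / target_edge)))
        surf = sweep_surface(c, m, target_edge)
        surf.network = spec
        return surf

    pts = np.vstack([c.points for c in spec.centerlines])
    rmax = max(float(c.radii.max()) for c in spec.centerlines)
    lo = pts.min(axis=0) - rmax - 3 * target_edge
    hi = pts.max(axis=0) + rmax + 3 * target_edge
    h = target_edge
    ns = np.maximum(((hi - lo) / h).astype(int) + 1, 2)
    xs = [lo[a] + h * np.arange(ns[a]) for a in range(3)]
    X, Y, Z = np.meshgrid(*xs, indexing="ij")
    grid_pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    vol = spec.sdf(grid_pts).reshape(ns)
    if vol.min() >= 0:
        raise ValueError("junction geometry unresolvable: no interior volume")
    verts, faces, _, _ = measure.marching_cubes(vol, level=0.0, spacing=(h, h, h))
    verts = verts + lo
    tm = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    tm.update_faces(tm.nondegenerate_faces(height=1e-8))
    tm.remove_unreferenced_vertices()
    # marching cubes orients normals along the gradient of the field
    # (pointing toward positive sdf = outward) -- keep as is
    faces = _clip_boundary_ends(
        np.asarray(tm.vertices), np.asarray(tm.faces), spec.boundary_ends(),
        inset=1.5 * target_edge,
    )
    tm = trimesh.Trimesh(vertices=tm.vertices, faces=faces, process=False)
    tm.remove_unreferenced_vertices()
    # keep the largest connected component (discards cap fragments)
    comps = tm.split(only_watertight=False)
    if len(comps) > 1:
        tm = max(comps, key=lambda c: len(c.faces))
    verts = np.asarray(tm.vertices)
    surf = WallSurface(
        verts,
        np.asarray(tm.faces),
        vessel_label=label_vertices(spec, verts),
        sdf=spec.sdf,
        network=spec,
    )
    return surf
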