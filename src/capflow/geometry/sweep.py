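"""Swept-tube surface generation.

Circular cross-sections are swept along a centerline trajectory with
parallel-transport frames (no torsion flips at curvature inflections,
unlike Frenet frames).  Rings are spaced so the triangulation is close to
equilateral at the requested target edge length, and every vertex sits on
the exact local radius by construction.
"""
from __future__ import annotations

import numpy as np

from .centerline import Centerline
from .surface import WallSurface


def parallel_transport_frames(points: np.ndarray):
    """Orthonormal frames (t, e1, e2) transported along a polyline."""
    seg = np.diff(points, axis=0)
    t = np.vstack([seg, seg[-1]])
    t = t / np.linalg.norm(t, axis=1)[:, None]
    # smooth tangent at interior nodes
    t[1:-1] = 0.5 * (t[:-2] + t[1:-1])
    t = t / np.linalg.norm(t, axis=1)[:, None]
    e1 = np.empty_like(t)
    ref = np.array([0.0, 0.0, 1.0]) if abs(t[0, 2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e1[0] = np.cross(t[0], ref)
    e1[0] /= np.linalg.norm(e1[0])
    for i in range(1, len(t)):
        v = np.cross(t[i - 1], t[i])
        s = np.linalg.norm(v)
        c = float(np.dot(t[i - 1], t[i]))
        if s < 1e-12:
            e1[i] = e1[i - 1]
        else:
            v = v / s
            # Rodrigues rotation taking t[i-1] to t[i]
            k = e1[i - 1]
            e1[i] = k * c + np.cross(v, k) * s + v * np.dot(v, k) * (1.0 - c)
        # re-orthogonalize against accumulated drift
        e1[i] -= np.dot(e1[i], t[i]) * t[i]
        e1[i] /= np.linalg.norm(e1[i])
    e2 = np.cross(t, e1)
    return t, e1, e2


def sweep_surface(
    centerline: Centerline, angular_samples: int, target_edge: float
) -> WallSurface:
    """Open tube surface swept along a centerline.

    Raises if the sweep would self-intersect (local bend radius smaller
    than the lumen radius) or the centerline is degenerate.
    """
    if angular_samples < 8:
        raise ValueError("angular_samples must be >= 8")
    if target_edge <= 0:
        raise ValueError("target_edge must be positive")
    if np.any(centerline.radii <= target_edge):
        raise ValueError("radius profile must exceed target_edge everywhere")

    ds = target_edge * np.sqrt(3.0) / 2.0
    cl = centerline.resample(ds)
    kappa = cl.curvature()
    # ignore endpoint one-sided estimates; they are noisy
    if len(kappa) > 4 and np.any(kappa[1:-1] * cl.radii[1:-1] >= 1.0):
        i = int(np.argmax(kappa[1:-1] * cl.radii[1:-1])) + 1
        raise ValueError(
            f"self-intersecting sweep: bend radius {1.0 / kappa[i]:.3g} um < "
            f"lumen radius {cl.radii[i]:.3g} um near arclength {cl.arclength[i]:.3g} um"
        )

    t, e1, e2 = parallel_transport_frames(cl.points)
    m = angular_samples
    n = len(cl.points)
    theta0 = 2.0 * np.pi * np.arange(m) / m
    verts = np.empty((n, m, 3))
    for i in range(n):
        # half-step angular offset on alternating rings -> near-equilateral mesh
        th = theta0 + (np.pi / m) * (i % 2)
        ring = (
            cl.points[i]
            + cl.radii[i] * (np.cos(th)[:, None] * e1[i] + np.sin(th)[:, None] * e2[i])
        )
        verts[i] = ring
    tris = []
    for i in range(n - 1):
        for j in range(m):
            a = i * m + j
            b = i * m + (j + 1) % m
            c = (i + 1) * m + j
            d = (i + 1) * m + (j + 1) % m
            if i % 2 == 0:
                tris.append((a, c, b))
                tris.append((b, c, d))
            else:
                tris.append((a, c, d))
                tris.append((a, d, b))
    surf = WallSurface(
        verts.reshape(-1, 3),
        np.asarray(tris, dtype=np.int64),
        vessel_label=np.full(n * m, centerline.label, dtype=np.int64),
        sdf=centerline.sdf,
    )
    # orient outward: triangle normals should point away from the centerline
    p0 = surf.vertices[surf.triangles[:, 0]]
    p1 = surf.vertices[surf.triangles[:, 1]]
    p2 = surf.vertices[surf.triangles[:, 2]]
    cen = (p0 + p1 + p2) / 3.0
    fn = np.cross(p1 - p0, p2 - p0)
    # radial direction approximated via nearest ring center
    ring_idx = np.clip((np.arange(len(surf.triangles)) // (2 * m)), 0, n - 1)
    radial = cen - cl.points[ring_idx]
    if np.mean(np.einsum("ij,ij->i", fn, radial) > 0) < 0.5:
        surf.triangles = surf.triangles[:, [0, 2, 1]]
        surf._tm = None
    return surf
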