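"""Local cylindrical frames on the vessel wall.

At every wall vertex the traction components are expressed in a local
orthonormal triad: the radial direction e_r is the inward surface normal,
the axial direction e_a points along the mean undisturbed flow near the
wall (sampled from a reference velocity field a short distance inside the
lumen, then projected onto the tangent plane), and the circumferential
direction closes the right-handed triad, e_theta = e_a x e_r.  Using the
plasma-only time-averaged field as the reference makes the frames
identical between paired RBC and plasma runs.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class LocalFrames:
    e_a: np.ndarray       # (N, 3) axial (mean-flow) unit vectors
    e_r: np.ndarray       # (N, 3) inward normals
    e_theta: np.ndarray   # (N, 3) circumferential, e_a x e_r
    stagnation: np.ndarray  # (N,) True where the mean-flow fallback was used


def local_frames(
    surface,
    reference_flow,
    *,
    sample_offset: float,
    stagnation_tol: float = 1e-6,
) -> LocalFrames:
    """Build per-vertex frames from a reference near-wall flow.

    ``reference_flow`` is any object with a ``velocity(points) -> (N, 3)``
    or ``velocity_at`` method (an analytic fixture or a solver).  The flow
    is sampled at ``vertex + sample_offset * e_r`` (typically two grid
    cells inside).  Vertices with negligible near-wall flow fall back to
    the nearest centerline tangent and are flagged.
    """
    n_out = surface.outward_normals()
    e_r = -n_out
    pts = surface.vertices + sample_offset * e_r
    vel_fn = getattr(reference_flow, "velocity_at", None) or reference_flow.velocity
    u = np.asarray(vel_fn(pts))
    speed = np.linalg.norm(u, axis=1)
    tol = stagnation_tol * max(speed.max(), 1e-30)
    stag = speed <= tol

    if np.any(stag) and getattr(surface, "network", None) is not None:
        from scipy.spatial import cKDTree

        samples, tangents = [], []
        for c in surface.network.centerlines:
            cl = c.resample(0.5)
            samples.append(cl.points)
            tangents.append(cl.tangents())
        tree = cKDTree(np.vstack(samples))
        tans = np.vstack(tangents)
        _, idx = tree.query(surface.vertices[stag])
        u[stag] = tans[idx]

    # tangential projection
    ut = u - np.einsum("ij,ij->i", u, e_r)[:, None] * e_r
    nt = np.linalg.norm(ut, axis=1)
    bad = nt <= 1e-30
    if np.any(bad):
        # degenerate: build any tangent
        ref = np.where(np.abs(e_r[bad, 2:3]) < 0.9, [[0, 0, 1.0]], [[1.0, 0, 0]])
        ut[bad] = np.cross(e_r[bad], ref)
        nt[bad] = np.linalg.norm(ut[bad], axis=1)
        stag = stag | bad
    e_a = ut / nt[:, None]
    e_theta = np.cross(e_a, e_r)
    return LocalFrames(e_a, e_r, e_theta, stag)
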