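"""Wall traction and WSS from near-wall velocity profiles.

The viscous traction components in the local cylindrical frame are

    t_a = mu_p du_a/dr,  t_theta = mu_p du_theta/dr,  t_r = 2 mu_p du_r/dr,

evaluated at the wall with the plasma viscosity (the calculation sits at
the vessel wall, outside any RBC).  The radial derivative uses one-sided
second-order differencing inward from the surface with the no-slip wall
value: velocities are interpolated at one and two stencil spacings inside,
giving  f'(0) = (4 f(h) - f(2h)) / (2h),  which is exact for profiles
quadratic in the wall distance.  WSS is the magnitude of the traction
vector.  Values are returned in dyne/cm^2.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..units import MU_PLASMA, stress_to_dyne_cm2
from .frames import LocalFrames


@dataclass
class TractionField:
    """Per-wall-vertex traction components and WSS magnitude (dyne/cm^2)."""

    t_a: np.ndarray
    t_theta: np.ndarray
    t_r: np.ndarray
    wss: np.ndarray
    thin_gap: np.ndarray  # True where the stencil spacing was shrunk


@dataclass
class TAWSSField:
    tawss: np.ndarray  # dyne/cm^2


@dataclass
class WSSGField:
    axial: np.ndarray   # dyne/cm^2/um
    circ: np.ndarray    # dyne/cm^2/um
    one_sided: np.ndarray | None = None


def traction(
    flow,
    frames: LocalFrames,
    surface,
    spacing: float,
    mu_p: float = MU_PLASMA,
) -> TractionField:
    """Instantaneous traction at every wall vertex.

    ``flow`` provides ``velocity_at``/``velocity``; ``spacing`` is the
    inward stencil spacing (normally the grid h).  Stencil points that
    would fall outside the fluid (thin gaps) shrink the spacing and are
    flagged.
    """
    vel_fn = getattr(flow, "velocity_at", None) or flow.velocity
    verts = surface.vertices
    e_r = frames.e_r
    s = np.full(len(verts), float(spacing))
    thin = np.zeros(len(verts), dtype=bool)
    sdf = getattr(surface, "sdf", None)
    if sdf is not None:
        for _ in range(3):
            outside = np.asarray(sdf(verts + 2.0 * s[:, None] * e_r)) >= 0.0
            if not np.any(outside):
                break
            s[outside] *= 0.5
            thin |= outside
    u1 = np.asarray(vel_fn(verts + s[:, None] * e_r))
    u2 = np.asarray(vel_fn(verts + 2.0 * s[:, None] * e_r))

    def comp(u, e):
        return np.einsum("ij,ij->i", u, e)

    out = {}
    for name, e, factor in (
        ("t_a", frames.e_a, 1.0),
        ("t_theta", frames.e_theta, 1.0),
        ("t_r", frames.e_r, 2.0),
    ):
        dudr = (4.0 * comp(u1, e) - comp(u2, e)) / (2.0 * s)
        out[name] = stress_to_dyne_cm2(factor * mu_p * dudr)
    wss = np.sqrt(out["t_a"] ** 2 + out["t_theta"] ** 2 + out["t_r"] ** 2)
    return TractionField(out["t_a"], out["t_theta"], out["t_r"], wss, thin)


def time_average(snapshots) -> TAWSSField:
    """Arithmetic mean of instantaneous WSS over uniformly spaced snapshots."""
    snapshots = list(snapshots)
    if not snapshots:
        raise ValueError("need at least one snapshot")
    n = {len(s.wss) for s in snapshots}
    if len(n) != 1:
        raise ValueError("snapshots have inconsistent vertex counts")
    return TAWSSField(np.mean([s.wss for s in snapshots], axis=0))
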