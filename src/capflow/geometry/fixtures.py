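"""Parametric network fixtures and analytic flow fields.

The fixture library encodes the geometric motifs characteristic of
angiogenic microvascular networks -- straight and tortuous capillaries,
torus arcs (curved vessels), Y-bifurcations, microvascular loop triads,
pillar-like obstructions and local bulges -- with diameters restricted to
the 3-40 um microcirculation range.  The analytic flow fixtures provide
closed-form, divergence-free velocity fields (Poiseuille tube, linear
shear, rigid rotation) for exercising the wall-shear-stress pipeline
without running the solver.
"""
from __future__ import annotations

import numpy as np

from .centerline import Centerline, Junction, NetworkSpec

FIXTURE_NAMES = (
    "straight", "tortuous", "torus_arc", "bifurcation", "loop_triad", "pillar", "bulge",
)


def _check_diameter(d):
    if not 3.0 <= d <= 40.0:
        raise ValueError(f"diameter {d} um outside the 3-40 um microvascular range")


def fixture_library(name: str, **params) -> NetworkSpec:
    """Deterministic network specification for a named geometric motif."""
    if name not in FIXTURE_NAMES:
        raise ValueError(f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}")
    return _BUILDERS[name](**params)


def _straight(diameter=8.0, length=40.0, n=17, axis=(0, 0, 1.0), origin=(0, 0, 0)):
    _check_diameter(diameter)
    axis = np.asarray(axis, float) / np.linalg.norm(axis)
    s = np.linspace(0.0, length, n)
    pts = np.asarray(origin, float) + s[:, None] * axis
    c = Centerline(pts, np.full(n, diameter / 2.0), label=0)
    return NetworkSpec(
        [c], [], {(0, "start"): "inlet", (0, "end"): "outlet"},
    )


def _tortuous(diameter=6.0, length=45.0, amplitude=3.0, wavelength=15.0, n=91):
    _check_diameter(diameter)
    z = np.linspace(0.0, length, n)
    x = amplitude * np.sin(2.0 * np.pi * z / wavelength)
    pts = np.column_stack([x, np.zeros_like(z), z])
    c = Centerline(pts, np.full(n, diameter / 2.0), label=0)
    return NetworkSpec([c], [], {(0, "start"): "inlet", (0, "end"): "outlet"})


def _torus_arc(diameter=8.0, bend_radius=20.0, angle=np.pi / 2, n=61):
    _check_diameter(diameter)
    if bend_radius <= diameter / 2.0:
        raise ValueError("bend radius must exceed the lumen radius")
    th = np.linspace(0.0, angle, n)
    pts = np.column_stack(
        [bend_radius * (1.0 - np.cos(th)), np.zeros_like(th), bend_radius * np.sin(th)]
    )
    c = Centerline(pts, np.full(n, diameter / 2.0), label=0)
    return NetworkSpec([c], [], {(0, "start"): "inlet", (0, "end"): "outlet"})


def _bifurcation(
    parent_diameter=12.0,
    daughter_diameter=8.0,
    parent_length=14.0,
    daughter_length=18.0,
    half_angle_deg=22.0,
):
    _check_diameter(parent_diameter)
    _check_diameter(daughter_diameter)
    a = np.deg2rad(half_angle_deg)
    jpt = np.array([0.0, 0.0, parent_length])
    n0, n1 = 8, 10
    z0 = np.linspace(0.0, parent_length, n0)
    parent = Centerline(
        np.column_stack([np.zeros(n0), np.zeros(n0), z0]),
        np.full(n0, parent_diameter / 2.0), label=0,
    )
    t = np.linspace(0.0, daughter_length, n1)
    dirs = [np.array([np.sin(a), 0.0, np.cos(a)]), np.array([-np.sin(a), 0.0, np.cos(a)])]
    daughters = [
        Centerline(jpt + t[:, None] * d, np.full(n1, daughter_diameter / 2.0), label=i + 1)
        for i, d in enumerate(dirs)
    ]
    return NetworkSpec(
        [parent] + daughters,
        [Junction(tuple(jpt), ((0, "end"), (1, "start"), (2, "start")))],
        {
            (0, "start"): "inlet",
            (1, "end"): "outlet",
            (2, "end"): "outlet",
        },
    )


def _loop_triad(diameter=6.0, loop_length=20.0, loop_width=10.0, stub_length=8.0):
    """Three vessels forming a closed loop between two junctions, with an
    inlet stub into the first junction and an outlet stub off the second."""
    _check_diameter(diameter)
    r = diameter / 2.0
    j1 = np.array([0.0, 0.0, 0.0])
    j2 = np.array([0.0, 0.0, loop_length])
    # c0: inlet stub -> j1
    n = 9
    c0 = Centerline(
        j1 + np.linspace(-stub_length, 0.0, n)[:, None] * np.array([0, 0, 1.0]),
        np.full(n, r), label=0,
    )
    # c1: left arc j1 -> j2
    th = np.linspace(0.0, np.pi, 31)
    arc = np.column_stack(
        [loop_width / 2.0 * np.sin(th), np.zeros_like(th), loop_length / 2.0 * (1 - np.cos(th))]
    )
    c1 = Centerline(arc, np.full(len(th), r), label=1)
    # c2: right arc j1 -> j2, continuing into the outlet stub
    arc2 = np.column_stack(
        [-loop_width / 2.0 * np.sin(th), np.zeros_like(th), loop_length / 2.0 * (1 - np.cos(th))]
    )
    tail = j2 + np.linspace(0.0, stub_length, 9)[1:, None] * np.array([0, 0, 1.0])
    c2 = Centerline(np.vstack([arc2, tail]), np.full(len(th) + 8, r), label=2)
    return NetworkSpec(
        [c0, c1, c2],
        [
            Junction(tuple(j1), ((0, "end"), (1, "start"), (2, "start"))),
            Junction(tuple(j2), ((1, "end"), ("interior", 2))),
        ],
        {(0, "start"): "inlet", (2, "end"): "outlet"},
    )


def _pillar(diameter=14.0, length=30.0, pillar_diameter=4.0):
    """Widened segment with a transverse pillar-like obstruction through it."""
    _check_diameter(diameter)
    spec = _straight(diameter=diameter, length=length)
    mid = np.array([0.0, 0.0, length / 2.0])
    n = 9
    pillar = Centerline(
        mid + np.linspace(-diameter, diameter, n)[:, None] * np.array([0, 1.0, 0]),
        np.full(n, pillar_diameter / 2.0), label=99,
    )
    spec.obstructions.append(pillar)
    return spec


def _bulge(diameter=8.0, length=40.0, bulge_amplitude=3.0, bulge_width=6.0):
    """Local increase of lumen area along a straight vessel."""
    _check_diameter(diameter)
    n = 81
    z = np.linspace(0.0, length, n)
    r = diameter / 2.0 + bulge_amplitude * np.exp(-((z - length / 2.0) ** 2) / (2 * bulge_width**2))
    c = Centerline(np.column_stack([np.zeros(n), np.zeros(n), z]), r, label=0)
    return NetworkSpec([c], [], {(0, "start"): "inlet", (0, "end"): "outlet"})


_BUILDERS = {
    "straight": _straight,
    "tortuous": _tortuous,
    "torus_arc": _torus_arc,
    "bifurcation": _bifurcation,
    "loop_triad": _loop_triad,
    "pillar": _pillar,
    "bulge": _bulge,
}


class AnalyticFlow:
    """Closed-form velocity field with a pointwise evaluator."""

    def __init__(self, kind: str, velocity, bounds_check=None):
        self.kind = kind
        self._velocity = velocity
        self._bounds_check = bounds_check

    def velocity(self, pts: np.ndarray) -> np.ndarray:
        return self._velocity(np.atleast_2d(np.asarray(pts, float)))

    def check_grid(self, grid) -> None:
        if self._bounds_check is not None and not self._bounds_check(grid):
            raise ValueError(f"grid does not contain the {self.kind} geometry")


def analytic_flow_fixture(kind: str, **params) -> AnalyticFlow:
    """Exact, divergence-free flow fields for testing the WSS pipeline."""
    if kind == "poiseuille_tube":
        R = params.get("radius", 4.0)
        U = params.get("mean_velocity", 1000.0)  # um/s
        center = np.asarray(params.get("center", (0.0, 0.0)), float)

        def vel(p):
            r2 = (p[:, 0] - center[0]) ** 2 + (p[:, 1] - center[1]) ** 2
            w = np.where(r2 < R * R, 2.0 * U * (1.0 - r2 / R**2), 0.0)
            out = np.zeros_like(p)
            out[:, 2] = w
            return out

        def check(grid):
            lo, hi = np.asarray(grid.origin), grid.upper
            return (lo[0] <= center[0] - R and hi[0] >= center[0] + R
                    and lo[1] <= center[1] - R and hi[1] >= center[1] + R)

        return AnalyticFlow(kind, vel, check)
    if kind == "linear_shear_halfspace":
        rate = params.get("rate", 100.0)  # 1/s
        z0 = params.get("wall_height", 0.0)

        def vel(p):
            out = np.zeros_like(p)
            out[:, 0] = rate * (p[:, 2] - z0)
            return out

        return AnalyticFlow(kind, vel)
    if kind == "rigid_rotation":
        omega = np.asarray(params.get("omega", (0.0, 0.0, 1.0)), float)
        center = np.asarray(params.get("center", (0.0, 0.0, 0.0)), float)

        def vel(p):
            return np.cross(omega, p - center)

        return AnalyticFlow(kind, vel)
    raise ValueError(
        "unknown analytic flow kind; choose poiseuille_tube, "
        "linear_shear_halfspace or rigid_rotation"
    )
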