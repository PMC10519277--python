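"""High-level orchestration: geometry -> flow -> WSS -> statistics.

These helpers wire the package's modules together for the common study
layouts: plasma-only steady flow through a synthetic network driven by an
inlet flux (with outlets at reference pressure), paired gamma-scaled runs,
and the WSS/TAWSS/TAWSSG analysis chain on the wall mesh.  The CLI is a
thin wrapper around these functions.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import EulerianGrid
from .flow import StokesSolver, FluidParams
from .geometry import NetworkSpec, WallSurface, build_network, fixture_library
from .netstats import vessel_aggregate
from .wss import local_frames, traction, time_average, wss_gradients


def network_grid(spec: NetworkSpec, h: float, lateral_margin: float = 1.6) -> EulerianGrid:
    """Cell grid covering a network whose inlet sits on the z = 0 plane
    and whose outlets reach the upper z face."""
    pts = np.vstack([c.points for c in spec.centerlines])
    rmax = max(float(c.radii.max()) for c in spec.centerlines)
    lo = pts.min(axis=0) - rmax - lateral_margin
    hi = pts.max(axis=0) + rmax + lateral_margin
    zlo = 0.0
    zhi = pts[:, 2].max()
    nx = int(np.ceil((hi[0] - lo[0]) / h))
    ny = int(np.ceil((hi[1] - lo[1]) / h))
    nz = int(np.floor((zhi - zlo) / h))
    return EulerianGrid((lo[0], lo[1], zlo), h, (nx, ny, nz))


def parabolic_inlet(spec: NetworkSpec, mean_velocity: float, gamma: float = 1.0):
    """Parabolic axial inflow profile on the (single) inlet cross-section."""
    inlets = [e for e in spec.boundary_ends() if e[5] == "inlet"]
    if len(inlets) != 1:
        raise ValueError("parabolic_inlet expects exactly one inlet")
    _, _, pt, _, radius, _ = inlets[0]

    def profile(x, y):
        r2 = (x - pt[0]) ** 2 + (y - pt[1]) ** 2
        return gamma * np.where(
            r2 < radius**2, 2.0 * mean_velocity * (1.0 - r2 / radius**2), 0.0
        )

    return profile


@dataclass
class PlasmaRun:
    solver: StokesSolver
    surface: WallSurface
    grid: EulerianGrid
    gamma: float


def plasma_steady_flow(
    surface: WallSurface,
    grid: EulerianGrid,
    mean_inlet_velocity: float,
    *,
    gamma: float = 1.0,
    params: FluidParams = FluidParams(),
    dt: float = 1e-3,
    max_steps: int = 400,
    tol: float = 1e-12,
) -> PlasmaRun:
    """Steady plasma-only Stokes flow with an imposed inlet flow rate.

    The scale-invariant convergence test makes paired gamma runs take the
    same iteration count, so their velocity fields differ by exactly the
    flow-rate factor (Stokes linearity)."""
    spec = surface.network
    if spec is None:
        raise ValueError("surface must carry its network spec")
    solver = StokesSolver(
        grid,
        surface.sdf or surface,
        dt=dt,
        params=params,
        periodic_z=False,
        inlet=parabolic_inlet(spec, mean_inlet_velocity, gamma),
        mu0=params.mu_p,
    )
    solver.solve_steady(tol=tol, max_steps=max_steps)
    return PlasmaRun(solver, surface, grid, gamma)


@dataclass
class WSSAnalysis:
    frames: object
    tawss: object
    wssg: object
    table: object  # per-vessel statistics DataFrame
    snapshots: list


def wss_analysis(
    surface: WallSurface,
    flows,
    h: float,
    reference_flow=None,
    mu_p: float | None = None,
) -> WSSAnalysis:
    """Traction/TAWSS/TAWSSG and per-vessel statistics from flow snapshots.

    ``flows`` is a single flow provider or a list of snapshot providers
    (anything with ``velocity_at``/``velocity``).  ``reference_flow``
    defaults to the first snapshot (for plasma-only runs the steady field
    is its own mean undisturbed flow).
    """
    if not isinstance(flows, (list, tuple)):
        flows = [flows]
    ref = reference_flow if reference_flow is not None else flows[0]
    frames = local_frames(surface, ref, sample_offset=2.0 * h)
    kw = {} if mu_p is None else {"mu_p": mu_p}
    snaps = [traction(f, frames, surface, spacing=h, **kw) for f in flows]
    tawss = time_average(snaps)
    wssg = wss_gradients(tawss, frames, surface)
    table = vessel_aggregate(tawss, wssg, surface)
    return WSSAnalysis(frames, tawss, wssg, table, snaps)


def bifurcation_gamma_study(
    h: float = 0.6,
    target_edge: float = 0.6,
    mean_inlet_velocity: float = 800.0,
    gammas=(1.0, 2.0),
    fixture_params: dict | None = None,
) -> dict:
    """Plasma-only gamma-scaling study on the Y-bifurcation fixture.

    Returns per-gamma :class:`WSSAnalysis` tables keyed by gamma.  Used to
    verify that imposed-flow scaling propagates proportionally to the
    per-vessel TAWSS (creeping-flow linearity).
    """
    spec = fixture_library("bifurcation", **(fixture_params or {}))
    surface = build_network(spec, target_edge)
    grid = network_grid(spec, h)
    out = {}
    for g in gammas:
        run = plasma_steady_flow(surface, grid, mean_inlet_velocity, gamma=g)
        out[g] = wss_analysis(surface, run.solver, h)
    return out
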