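import numpy as np
import pytest

from capflow.geometry import analytic_flow_fixture, build_network, fixture_library


@pytest.fixture(scope="session")
def straight_tube_surface():
    """Swept straight tube, R = 4 um, L = 40 um, labeled vertices."""
    spec = fixture_library("straight", diameter=8.0, length=40.0)
    return build_network(spec, 0.5)


@pytest.fixture(scope="session")
def poiseuille_flow():
    """Analytic Poiseuille field, R = 4 um, U_mean = 1 mm/s."""
    return analytic_flow_fixture("poiseuille_tube", radius=4.0, mean_velocity=1000.0)


@pytest.fixture(scope="session")
def tube_frames(straight_tube_surface, poiseuille_flow):
    from capflow.wss import local_frames

    return local_frames(straight_tube_surface, poiseuille_flow, sample_offset=1.0)


@pytest.fixture(scope="session")
def periodic_tube_solver():
    """Plasma-only periodic tube solver at steady Poiseuille flow
    (R = 4 um, h = 0.5 um, pseudo-shear 200 1/s)."""
    from capflow.flow import FluidParams, StokesSolver, poiseuille_body_force
    from capflow.studies import tube_grid, tube_sdf

    grid = tube_grid(4.0, 0.5, 10.0, margin=1.5)
    fp = FluidParams()
    solver = StokesSolver(
        grid, tube_sdf(4.0), dt=1e-4, params=fp, periodic_z=True, mu0=fp.mu_p
    )
    solver.solve_steady(
        body_force=(0.0, 0.0, poiseuille_body_force(200.0, 4.0)), max_steps=300
    )
    return solver


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230829)


@pytest.fixture(scope="session")
def torus_flow_asymmetry():
    """Plasma flow through a curved (torus-arc) vessel: mean TAWSS on the
    inner (higher-curvature) and outer halves of the bend."""
    from capflow.flow import FluidParams, StokesSolver
    from capflow.grid import EulerianGrid
    from capflow.pipeline import parabolic_inlet, wss_analysis

    spec = fixture_library("torus_arc", diameter=8.0, bend_radius=16.0,
                           angle=np.deg2rad(40.0))
    surf = build_network(spec, 0.6)
    pts = np.vstack([c.points for c in spec.centerlines])
    h = 0.6
    lo = pts.min(axis=0) - 6.0
    hi = pts.max(axis=0) + 6.0
    nz = int(np.floor(pts[:, 2].max() / h))
    grid = EulerianGrid((lo[0], lo[1], 0.0), h,
                        (int((hi[0] - lo[0]) / h), int((hi[1] - lo[1]) / h), nz))
    fp = FluidParams()
    solver = StokesSolver(grid, surf.sdf, dt=1e-3, params=fp, periodic_z=False,
                          inlet=parabolic_inlet(spec, 600.0), mu0=fp.mu_p)
    solver.solve_steady(max_steps=200)
    res = wss_analysis(surf, solver, h)
    center = np.array([16.0, 0.0])
    v = surf.vertices
    z = v[:, 2]
    mid = (z > 4.0) & (z < pts[:, 2].max() - 4.0)
    d = np.linalg.norm(v[:, [0, 1]] - center, axis=1)
    inner = float(res.tawss.tawss[mid & (d < 16.0)].mean())
    outer = float(res.tawss.tawss[mid & (d > 16.0)].mean())
    return inner, outer


@pytest.fixture(scope="session")
def gamma_scaling_result():
    from capflow.studies import gamma_scaling_case

    return gamma_scaling_case()


@pytest.fixture(scope="session")
def rbc_vs_plasma_result():
    from capflow.studies import rbc_vs_plasma_tube_case

    return rbc_vs_plasma_tube_case()


@pytest.fixture(scope="session")
def area_conservation_result():
    from capflow.studies import area_conservation_case

    return area_conservation_case()
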