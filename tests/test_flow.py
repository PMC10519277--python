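"""Flow solver and immersed-boundary transfer: delta-kernel properties,
indicator/viscosity fields, Stokes accuracy and linearity, projection
divergence, and the coupled simulation loop."""
import numpy as np
import pytest

from capflow.grid import EulerianGrid, PointLattice
from capflow.flow import (
    FluidParams,
    SimulationConfig,
    Simulation,
    StokesSolver,
    interpolate_field,
    poiseuille_body_force,
    pseudo_shear_rate,
    spread_forces,
    update_indicator,
    viscosity_field,
)
from capflow.membrane import MaterialParams, biconcave_shape, make_membrane_mesh
from capflow.studies import tube_grid, tube_sdf
from capflow.units import CP, MU_PLASMA


@pytest.fixture(scope="module")
def free_lattice():
    return PointLattice((0.0, 0.0, 0.0), 0.5, (16, 16, 16))


class TestDeltaKernel:
    def test_partition_of_unity(self, free_lattice, rng):
        """Total spread force equals the input force (conservation)."""
        pts = rng.uniform(2.0, 5.5, size=(20, 3))
        vals = rng.standard_normal(20)
        out = spread_forces(pts, vals, free_lattice, periodic_z=False)
        assert out.sum() * free_lattice.h**3 == pytest.approx(vals.sum(), rel=1e-13)

    def test_opposite_forces_cancel(self, free_lattice):
        pts = np.array([[3.0, 3.0, 3.0], [3.0, 3.0, 3.0]])
        out = spread_forces(pts, np.array([1.0, -1.0]), free_lattice)
        assert np.abs(out).max() == 0.0

    def test_interpolation_constant_and_linear(self, free_lattice, rng):
        pts = rng.uniform(2.0, 5.5, size=(30, 3))
        const = np.full(free_lattice.shape, 7.5)
        assert np.allclose(interpolate_field(pts, const, free_lattice), 7.5)
        # first-moment property makes linear fields exact
        coef = rng.standard_normal(3)
        lin = (free_lattice.points() @ coef).reshape(free_lattice.shape)
        got = interpolate_field(pts, lin, free_lattice)
        assert np.allclose(got, pts @ coef, rtol=1e-12, atol=1e-10)

    def test_spread_interpolate_adjoint(self, free_lattice, rng):
        """<spread(f), u> h^3 = <f, interp(u)> to round-off."""
        pts = rng.uniform(2.0, 5.5, size=(15, 3))
        f = rng.standard_normal(15)
        u = rng.standard_normal(free_lattice.shape)
        lhs = np.sum(spread_forces(pts, f, free_lattice) * u) * free_lattice.h**3
        rhs = np.sum(f * interpolate_field(pts, u, free_lattice))
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_edge_support_rejected(self, free_lattice):
        with pytest.raises(ValueError, match="kernel support"):
            spread_forces(np.array([[0.2, 3.0, 3.0]]), np.ones(1), free_lattice)


class TestIndicator:
    def test_empty_suspension(self, free_lattice):
        assert np.all(update_indicator([], free_lattice) == 0.0)

    def test_sphere_volume_and_interior(self):
        lat = PointLattice((-3.0, -3.0, -3.0), 0.25, (25, 25, 25))
        sphere = make_membrane_mesh(3)
        sphere.vertices = 2.0 * sphere.vertices
        I = update_indicator([sphere], lat)
        vol = I.sum() * 0.25**3
        assert vol == pytest.approx(4 * np.pi / 3 * 8.0, rel=0.05)
        centre = I[12, 12, 12]
        assert centre == pytest.approx(1.0, abs=1e-6)

    def test_viscosity_blend_values(self):
        assert viscosity_field(0.0) == pytest.approx(1.2 * CP)
        assert viscosity_field(1.0) == pytest.approx(6.0 * CP)
        assert viscosity_field(0.5) == pytest.approx(3.6 * CP)
        with pytest.raises(ValueError):
            viscosity_field(0.5, mu_p=2.0 * CP, mu_c=1.0 * CP)


class TestStokes:
    def test_poiseuille_profile(self, periodic_tube_solver):
        """Steady tube flow matches the Poiseuille parabola within 2%."""
        s = periodic_tube_solver
        w = s.full_component("w")
        lat = s.lattices["w"]
        pts = lat.points().reshape(lat.shape + (3,))
        r2 = pts[..., 0] ** 2 + pts[..., 1] ** 2
        U = 200.0 * 8.0  # pseudo-shear * diameter
        exact = np.where(r2 < 16.0, 2 * U * (1 - r2 / 16.0), 0.0)
        fluid = (s.labels["w"].labels == 0).reshape(w.shape)
        err = np.linalg.norm((w - exact)[fluid]) / np.linalg.norm(exact[fluid])
        assert err < 0.02

    def test_divergence_free(self, periodic_tube_solver):
        s = periodic_tube_solver
        umax = np.abs(s.state["w"]).max()
        assert np.abs(s.divergence()).max() < 1e-8 * umax / s.grid.h

    def test_drive_linearity(self):
        """Doubling the drive exactly doubles the plasma velocity field."""
        grid = tube_grid(3.0, 0.5, 6.0)
        fp = FluidParams()
        bf = poiseuille_body_force(100.0, 3.0)
        fields = []
        for fac in (1.0, 2.0):
            s = StokesSolver(grid, tube_sdf(3.0), dt=1e-4, params=fp,
                             periodic_z=True, mu0=fp.mu_p)
            for _ in range(40):
                s.step(body_force=(0.0, 0.0, fac * bf))
            fields.append(np.concatenate([s.state[c] for c in ("u", "v", "w")]))
        assert np.allclose(fields[1], 2.0 * fields[0], rtol=1e-12, atol=1e-9)

    def test_unforced_flow_decays(self):
        grid = tube_grid(3.0, 0.5, 6.0)
        fp = FluidParams()
        s = StokesSolver(grid, tube_sdf(3.0), dt=1e-4, params=fp,
                         periodic_z=True, mu0=fp.mu_p)
        rng = np.random.default_rng(0)
        for c in ("u", "v", "w"):
            s.state[c] = rng.standard_normal(len(s.state[c]))
        before = max(np.abs(s.state[c]).max() for c in ("u", "v", "w"))
        for _ in range(10):
            s.step()
        after = max(np.abs(s.state[c]).max() for c in ("u", "v", "w"))
        assert after < 1e-3 * before


class TestSimulation:
    def test_zero_steps_echo_initial_state(self):
        grid = tube_grid(4.0, 0.5, 8.0)
        cfg = SimulationConfig(grid=grid, surface=tube_sdf(4.0), periodic_z=True,
                               t_end=0.0, dt=1e-5)
        rbc = biconcave_shape(make_membrane_mesh(2), 7.8)
        rbc.vertices[:, 2] += 4.0
        rbc.set_reference(rbc.vertices)
        x0 = rbc.vertices.copy()
        sim = Simulation(cfg, [rbc]).run()
        assert sim.step_count == 0
        assert np.array_equal(sim.membranes[0].vertices, x0)

    def test_checkpoint_restart_bit_identical(self, tmp_path):
        """Restarting from a checkpoint continues the identical trajectory."""
        grid = tube_grid(4.0, 0.5, 8.0)
        bf = poiseuille_body_force(100.0, 4.0)

        def build():
            cfg = SimulationConfig(
                grid=grid, surface=tube_sdf(4.0), periodic_z=True,
                body_force=(0.0, 0.0, bf), t_end=1.0, dt=2e-5,
                material=MaterialParams(),
                fluid=FluidParams(mu_c=MU_PLASMA),  # no refactorization needed
                indicator_every=10**9,
            )
            rbc = biconcave_shape(make_membrane_mesh(2), 7.8)
            rbc.vertices[:, 2] += 4.0
            rbc.set_reference(rbc.vertices)
            return Simulation(cfg, [rbc])

        a = build()
        for _ in range(10):
            a.step()
        a.save_checkpoint(tmp_path / "ck.h5")
        for _ in range(10):
            a.step()
        b = build()
        b.load_checkpoint(tmp_path / "ck.h5")
        for _ in range(10):
            b.step()
        assert np.array_equal(a.membranes[0].vertices, b.membranes[0].vertices)
        for c in ("u", "v", "w"):
            assert np.array_equal(a.solver.state[c], b.solver.state[c])

    def test_pseudo_shear_helper(self):
        assert pseudo_shear_rate(1600.0, 8.0) == pytest.approx(200.0)


class TestInjection:
    def test_zero_target_no_injection(self, rng):
        from capflow.flow import InletFeeder, inject_rbcs

        feeder = InletFeeder(level=2)
        out, hct = inject_rbcs([], feeder, 0.0, inlet_z=0.0, outlet_z=40.0,
                               tube_radius=5.0, rng=rng)
        assert out == [] and hct == 0.0

    def test_target_clamped_to_physiological_range(self, rng):
        from capflow.flow import InletFeeder, inject_rbcs

        feeder = InletFeeder(level=2)
        with pytest.warns(UserWarning, match="clamped"):
            inject_rbcs([], feeder, 0.05, inlet_z=0.0, outlet_z=40.0,
                        tube_radius=5.0, rng=rng)

    def test_windowed_hematocrit_under_advection(self, rng):
        """Kinematic check: injecting into a D = 10 um tube while advecting
        at constant speed holds the windowed hematocrit near target."""
        from capflow.flow import InletFeeder, inject_rbcs

        feeder = InletFeeder(level=2)
        membranes = []
        hcts = []
        dt, speed = 1e-3, 2000.0
        for step in range(260):
            membranes, hct = inject_rbcs(
                membranes, feeder, 0.24, inlet_z=0.0, outlet_z=60.0,
                tube_radius=5.0, rng=rng, window=20.0,
            )
            for m in membranes:
                m.vertices[:, 2] += speed * dt
            if step > 60:
                hcts.append(hct)
        mean_hct = np.mean(hcts)
        assert 0.18 <= mean_hct <= 0.30


class TestViscousDecomposition:
    def test_implicit_plus_transpose_equals_full_stress(self, rng):
        """The implicit per-component matrix plus the explicit cross-term
        remainder reproduce the full variable-viscosity stress divergence
        (independent array-stencil operator) to machine precision."""
        from capflow.flow.stokes import StokesSolver, explicit_viscous, transpose_viscous

        grid = tube_grid(4.0, 0.5, 8.0)
        fp = FluidParams()
        s = StokesSolver(grid, tube_sdf(4.0), dt=2e-6, params=fp, periodic_z=True)
        pts = s.p_lattice.points()
        d = np.linalg.norm(pts - np.array([0.0, 0.0, 4.0]), axis=1) - 2.0
        I = (0.5 * (1.0 - np.tanh(d / 0.35))).reshape(s.p_lattice.shape)
        mu = viscosity_field(I)
        for c in ("u", "v", "w"):
            s.state[c] = rng.standard_normal(len(s.state[c]))
        fields = {c: s.full_component(c) for c in ("u", "v", "w")}
        Tt = transpose_viscous(fields["u"], fields["v"], fields["w"],
                               s._padded_mu(mu), grid.h, True)
        full = explicit_viscous(fields["u"], fields["v"], fields["w"],
                                mu, grid.h, True)
        for ci, c in enumerate(("u", "v", "w")):
            lap = s._viscous_matrix_variable(c, mu)
            impl = (lap @ (s.S[c] @ s.state[c] + s.s0[c])).reshape(
                s.lattices[c].shape
            )
            tot = impl + Tt[ci]
            lat_pts = s.lattices[c].points().reshape(s.lattices[c].shape + (3,))
            rr = np.sqrt(lat_pts[..., 0] ** 2 + lat_pts[..., 1] ** 2)
            m = rr < 2.6  # interior, away from the wall stencils
            err = np.abs((tot - full[ci])[m]).max() / np.abs(full[ci][m]).max()
            assert err < 1e-12
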