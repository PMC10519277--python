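"""WSS pipeline: local cylindrical frames, one-sided traction stencils,
time averaging, and surface gradients, checked against closed forms."""
import numpy as np
import pytest

from capflow.geometry import analytic_flow_fixture, build_network, fixture_library
from capflow.units import MU_PLASMA, stress_to_dyne_cm2
from capflow.wss import (
    TAWSSField,
    local_frames,
    time_average,
    traction,
    wss_gradients,
)


class TestFrames:
    def test_straight_tube_geometry(self, straight_tube_surface, tube_frames):
        """At (R, 0, z) with +z flow: e_a = z, e_r = -x, e_theta = -y."""
        surf = straight_tube_surface
        i = int(np.argmin(np.linalg.norm(surf.vertices[:, :2] - [4.0, 0.0], axis=1)))
        assert tube_frames.e_a[i] == pytest.approx([0, 0, 1], abs=1e-9)
        assert tube_frames.e_r[i] == pytest.approx([-1, 0, 0], abs=1e-9)
        assert tube_frames.e_theta[i] == pytest.approx([0, -1, 0], abs=1e-9)

    def test_orthonormal_right_handed(self, tube_frames):
        for a, b in (("e_a", "e_r"), ("e_a", "e_theta"), ("e_r", "e_theta")):
            dots = np.einsum(
                "ij,ij->i", getattr(tube_frames, a), getattr(tube_frames, b)
            )
            assert np.abs(dots).max() < 1e-12
        cross = np.cross(tube_frames.e_a, tube_frames.e_r)
        assert np.allclose(cross, tube_frames.e_theta, atol=1e-12)

    def test_flow_reversal_flips_tangential_axes(self, straight_tube_surface):
        fwd = analytic_flow_fixture("poiseuille_tube", radius=4.0, mean_velocity=1000.0)

        class Reversed:
            def velocity(self, p):
                return -fwd.velocity(p)

        f1 = local_frames(straight_tube_surface, fwd, sample_offset=1.0)
        f2 = local_frames(straight_tube_surface, Reversed(), sample_offset=1.0)
        assert np.allclose(f2.e_a, -f1.e_a)
        assert np.allclose(f2.e_theta, -f1.e_theta)
        assert np.allclose(f2.e_r, f1.e_r)

    def test_stagnation_fallback_flags(self, straight_tube_surface):
        class Quiescent:
            def velocity(self, p):
                return np.zeros_like(p)

        f = local_frames(straight_tube_surface, Quiescent(), sample_offset=1.0)
        assert f.stagnation.all()
        # fallback still yields orthonormal frames
        assert np.allclose(np.linalg.norm(f.e_a, axis=1), 1.0)


class TestTraction:
    def test_poiseuille_wall_shear(self, straight_tube_surface, tube_frames,
                                   poiseuille_flow):
        """tau_w = 4 mu U / R = 12 dyne/cm^2, uniform within 3%."""
        tf = traction(poiseuille_flow, tube_frames, straight_tube_surface, spacing=0.5)
        assert np.abs(tf.wss - 12.0).max() / 12.0 < 0.03
        # axial dominance: |t_a| >> |t_theta|, |t_r|
        assert np.abs(tf.t_a).mean() > 1e3 * np.abs(tf.t_theta).mean()
        assert np.abs(tf.t_a).mean() > 1e2 * np.abs(tf.t_r).mean()
        assert np.all(tf.wss >= np.abs(tf.t_a) - 1e-12)

    def test_quiescent_fluid_zero_traction(self, straight_tube_surface, tube_frames):
        class Quiescent:
            def velocity(self, p):
                return np.zeros_like(p)

        tf = traction(Quiescent(), tube_frames, straight_tube_surface, spacing=0.5)
        assert np.abs(tf.wss).max() == 0.0

    def test_linear_shear_exact(self):
        """Stencil exact on fields linear in wall distance:
        WSS = mu_p * 100/s = 1.2 dyne/cm^2 to machine precision."""
        spec = fixture_library("straight", diameter=10.0, length=20.0)
        surf = build_network(spec, 0.6)

        class TubeShear:
            # axial flow increasing linearly with distance from the wall
            def velocity(self, p):
                r = np.sqrt(p[:, 0] ** 2 + p[:, 1] ** 2)
                out = np.zeros_like(p)
                out[:, 2] = 100.0 * np.clip(5.0 - r, 0.0, None)
                return out

        frames = local_frames(surf, TubeShear(), sample_offset=1.0)
        tf = traction(TubeShear(), frames, surf, spacing=0.5)
        expected = stress_to_dyne_cm2(MU_PLASMA * 100.0)
        # stencil error is zero; the residual comes from faceted vertex
        # normals deviating from the exact radial direction by O(dtheta^2)
        assert np.abs(tf.wss - expected).max() < 1e-3 * expected

    def test_quadratic_convergence_on_cubic_profile(self, straight_tube_surface,
                                                    tube_frames):
        """One-sided stencil is second order: error on a cubic profile
        shrinks ~4x when the spacing halves."""
        class Cubic:
            def velocity(self, p):
                r = np.sqrt(p[:, 0] ** 2 + p[:, 1] ** 2)
                s = np.clip(4.0 - r, 0.0, None)
                out = np.zeros_like(p)
                out[:, 2] = 100.0 * s + 30.0 * s**3
                return out

        exact = stress_to_dyne_cm2(MU_PLASMA * 100.0)
        errs = []
        for hh in (0.4, 0.2):
            tf = traction(Cubic(), tube_frames, straight_tube_surface, spacing=hh)
            errs.append(np.abs(tf.wss - exact).max())
        assert errs[0] / errs[1] > 3.0


class TestTimeAverage:
    def test_single_and_alternating(self, straight_tube_surface, tube_frames,
                                    poiseuille_flow):
        tf = traction(poiseuille_flow, tube_frames, straight_tube_surface, spacing=0.5)
        single = time_average([tf])
        assert np.array_equal(single.tawss, tf.wss)
        import copy

        tf2 = copy.deepcopy(tf)
        tf2.wss = tf.wss + 10.0
        avg = time_average([tf, tf2])
        assert np.allclose(avg.tawss, tf.wss + 5.0)
        # idempotent on steady fields
        many = time_average([tf] * 7)
        assert np.allclose(many.tawss, tf.wss)

    def test_vertex_count_mismatch(self, straight_tube_surface, tube_frames,
                                   poiseuille_flow):
        import copy

        tf = traction(poiseuille_flow, tube_frames, straight_tube_surface, spacing=0.5)
        bad = copy.deepcopy(tf)
        bad.wss = bad.wss[:-5]
        with pytest.raises(ValueError, match="inconsistent"):
            time_average([tf, bad])

    def test_empty(self):
        with pytest.raises(ValueError):
            time_average([])


class TestGradients:
    def test_uniform_field_zero_gradient(self, straight_tube_surface, tube_frames):
        g = wss_gradients(TAWSSField(np.full(len(straight_tube_surface.vertices), 9.0)),
                          tube_frames, straight_tube_surface)
        assert np.abs(g.axial).max() < 1e-10
        assert np.abs(g.circ).max() < 1e-10

    def test_linear_axial_field(self, straight_tube_surface, tube_frames):
        z = straight_tube_surface.vertices[:, 2]
        g = wss_gradients(TAWSSField(3.0 * z), tube_frames, straight_tube_surface)
        inner = (z > 3) & (z < 37)
        assert np.abs(g.axial[inner] - 3.0).max() / 3.0 < 0.02
        assert np.abs(g.circ[inner]).max() < 0.02 * 3.0

    def test_azimuthal_harmonic_field(self, straight_tube_surface, tube_frames):
        """TAWSS = a cos(m theta): max circumferential gradient = a m / R."""
        v = straight_tube_surface.vertices
        th = np.arctan2(v[:, 1], v[:, 0])
        a, m = 5.0, 3
        g = wss_gradients(TAWSSField(a * np.cos(m * th)), tube_frames,
                          straight_tube_surface)
        inner = (v[:, 2] > 3) & (v[:, 2] < 37)
        peak = np.abs(g.circ[inner]).max()
        assert peak == pytest.approx(a * m / 4.0, rel=0.05)
        assert np.abs(g.axial[inner]).max() < 0.05 * a * m / 4.0


def test_curved_tube_high_curvature_side_elevated(torus_flow_asymmetry):
    """Plasma flow through a torus-arc vessel: TAWSS is skewed toward the
    inner (higher-curvature) side of the bend."""
    inner, outer = torus_flow_asymmetry
    assert inner > 1.05 * outer
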