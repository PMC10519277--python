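"""RBC membrane meshes and mechanics: construction invariants, the
Skalak/bending energy closed forms, and exactness of the force assembly
(forces must be the analytic gradient of the discrete energy)."""
import numpy as np
import pytest

from capflow.membrane import (
    MaterialParams,
    area_volume,
    biconcave_shape,
    elastic_energy,
    make_membrane_mesh,
    mean_curvature,
    membrane_forces,
    strain_invariants,
    total_energy,
)
from capflow.membrane.mechanics import element_invariants


@pytest.mark.parametrize(
    "level,faces,verts",
    [(0, 20, 12), (2, 320, 162), (4, 5120, 2562)],
)
def test_icosphere_counts(level, faces, verts):
    m = make_membrane_mesh(level)
    assert m.n_faces == faces
    assert m.n_vertices == verts
    # Euler closed-surface relation V = F/2 + 2
    assert m.n_vertices == m.n_faces // 2 + 2


def test_sphere_area_volume_converge():
    m = make_membrane_mesh(4)
    a, v = area_volume(m)
    assert abs(a - 4 * np.pi) / (4 * np.pi) < 2e-3
    assert abs(v - 4 * np.pi / 3) / (4 * np.pi / 3) < 3e-3


def test_volume_sign_flips_with_orientation():
    m = make_membrane_mesh(2)
    _, v = area_volume(m)
    flipped = make_membrane_mesh(2)
    flipped.faces = flipped.faces[:, [0, 2, 1]]
    _, v2 = area_volume(flipped)
    assert v > 0 and v2 == pytest.approx(-v)


def test_area_volume_rigid_motion_invariant(rng):
    m = make_membrane_mesh(2)
    a0, v0 = area_volume(m)
    m.vertices = m.vertices + np.array([3.0, -2.0, 7.0])
    a1, v1 = area_volume(m)
    assert a1 == pytest.approx(a0) and v1 == pytest.approx(v0)


def test_biconcave_geometry():
    bc = biconcave_shape(make_membrane_mesh(4), 7.8)
    a, v = area_volume(bc)
    assert a == pytest.approx(134.1, rel=0.02)
    assert v == pytest.approx(94.1, rel=0.02)
    # doubling the diameter scales area x4, volume x8
    bc2 = biconcave_shape(make_membrane_mesh(3), 15.6)
    bc1 = biconcave_shape(make_membrane_mesh(3), 7.8)
    a2, v2 = area_volume(bc2)
    a1, v1 = area_volume(bc1)
    assert a2 / a1 == pytest.approx(4.0, rel=1e-12)
    assert v2 / v1 == pytest.approx(8.0, rel=1e-12)


def test_strain_invariants_closed_forms():
    assert strain_invariants(1.0, 1.0) == (0.0, 0.0)
    I1, I2 = strain_invariants(1.2, 1.0 / 1.2)
    assert I1 == pytest.approx(1.2**2 + 1.2**-2 - 2.0)
    assert I2 == pytest.approx(0.0, abs=1e-14)
    _, I2 = strain_invariants(1.1, 1.1)
    assert I2 == pytest.approx(1.1**4 - 1.0)
    with pytest.raises(ValueError):
        strain_invariants(-1.0, 1.0)


def test_element_invariants_under_uniform_stretch():
    m = biconcave_shape(make_membrane_mesh(2), 7.8)
    I1, I2 = element_invariants(m)
    assert np.abs(I1).max() < 1e-12 and np.abs(I2).max() < 1e-12
    m.vertices = 1.1 * m.vertices  # uniform 3D dilation: l1 = l2 = 1.1
    I1, I2 = element_invariants(m)
    assert I1 == pytest.approx(np.full_like(I1, 2 * 1.1**2 - 2), rel=1e-10)
    assert I2 == pytest.approx(np.full_like(I2, 1.1**4 - 1), rel=1e-10)


def test_elastic_energy_rest_and_dilation_scaling():
    p = MaterialParams()
    m = biconcave_shape(make_membrane_mesh(2), 7.8)
    # zero at rest up to round-off of the O(Gs * A) energy scale
    assert elastic_energy(m, p) == pytest.approx(0.0, abs=1e-12 * p.Gs * 134.0)
    # under uniform dilation the C I2^2 term dominates for large C
    m.vertices = 1.05 * m.vertices
    e_c100 = elastic_energy(m, p)
    e_c1000 = elastic_energy(m, MaterialParams(C=1000.0))
    assert e_c1000 / e_c100 == pytest.approx(10.0, rel=0.15)


def test_forces_zero_at_rest_and_pure_translation():
    p = MaterialParams()
    m = biconcave_shape(make_membrane_mesh(2), 7.8)
    f = membrane_forces(m, p)
    tol = 1e-12 * p.Gs  # round-off of the O(Gs) force scale
    assert np.abs(f).max() == pytest.approx(0.0, abs=tol)
    m.vertices = m.vertices + np.array([1.0, 2.0, -3.0])
    assert np.abs(membrane_forces(m, p)).max() == pytest.approx(0.0, abs=tol)


def test_forces_zero_under_rigid_rotation(rng):
    p = MaterialParams()
    m = biconcave_shape(make_membrane_mesh(2), 7.8)
    th = 0.7
    Rz = np.array(
        [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]]
    )
    m.vertices = m.vertices @ Rz.T
    f = membrane_forces(m, p)
    scale = p.Gs * 0.27  # typical vertex force scale at O(1) strain
    assert np.abs(f).max() / scale < 1e-9


@pytest.mark.parametrize("level", [1, 2, 3])
def test_forces_match_energy_gradient(level, rng):
    """Force/energy consistency: vertex forces equal the central-difference
    gradient of the total energy to 1e-4 relative, at three mesh levels."""
    p = MaterialParams()
    m = biconcave_shape(make_membrane_mesh(level), 7.8)
    m.vertices = m.vertices + 0.05 * rng.standard_normal(m.vertices.shape)
    f = membrane_forces(m, p)
    scale = np.abs(f).max()
    eps = 1e-5
    idx = rng.choice(m.n_vertices, 6, replace=False)
    for i in idx:
        for d in range(3):
            mp = m.copy()
            mp.vertices[i, d] += eps
            mm = m.copy()
            mm.vertices[i, d] -= eps
            fd = -(total_energy(mp, p) - total_energy(mm, p)) / (2 * eps)
            assert abs(fd - f[i, d]) / scale < 1e-4


def test_inflated_sphere_forces_radial_and_uniform():
    p = MaterialParams(kb=0.0)
    m = make_membrane_mesh(3)
    m.vertices = 4.0 * m.vertices
    m.set_reference()
    m.vertices = 1.1 * m.vertices
    f = membrane_forces(m, p)
    mag = np.linalg.norm(f, axis=1)
    rhat = m.vertices / np.linalg.norm(m.vertices, axis=1)[:, None]
    align = np.abs(np.einsum("ij,ij->i", f, rhat)) / mag
    assert align.min() > 0.9999
    # near-uniform magnitude (vertex areas differ slightly on an icosphere)
    assert mag.std() / mag.mean() < 0.15


def test_net_force_and_torque_vanish(rng):
    p = MaterialParams()
    m = biconcave_shape(make_membrane_mesh(2), 7.8)
    m.vertices = m.vertices + 0.1 * rng.standard_normal(m.vertices.shape)
    f = membrane_forces(m, p)
    scale = np.abs(f).sum()
    assert np.linalg.norm(f.sum(axis=0)) / scale < 1e-12
    torque = np.cross(m.vertices, f).sum(axis=0)
    assert np.linalg.norm(torque) / (scale * 4.0) < 1e-12


@pytest.mark.parametrize("level,tol", [(2, 0.02), (3, 0.006), (4, 0.002)])
def test_sphere_mean_curvature_converges(level, tol):
    m = make_membrane_mesh(level)
    m.vertices = 2.0 * m.vertices  # R = 2 -> kappa = 0.5
    k = mean_curvature(m)
    assert abs(k.mean() - 0.5) / 0.5 < tol


def test_degenerate_element_diagnostic():
    p = MaterialParams()
    m = biconcave_shape(make_membrane_mesh(1), 7.8)
    # collapse one triangle onto a line
    tri = m.faces[0]
    m.vertices[tri[2]] = 0.5 * (m.vertices[tri[0]] + m.vertices[tri[1]])
    with pytest.raises(FloatingPointError, match="element"):
        membrane_forces(m, p)


def test_material_params_validation():
    with pytest.raises(ValueError):
        MaterialParams(C=0.5)
    with pytest.raises(ValueError):
        MaterialParams(Gs=-1.0)


# ---------------------------------------------------------------- properties
from hypothesis import given, settings, strategies as st


@settings(derandomize=True, max_examples=50, deadline=None)
@given(
    l1=st.floats(0.3, 3.0, allow_nan=False),
    l2=st.floats(0.3, 3.0, allow_nan=False),
)
def test_strain_invariant_identities(l1, l2):
    """I1 + 2 >= 2 sqrt(I2 + 1) (AM-GM on the squared stretches), with
    equality iff the stretch is isotropic; both invariants vanish only at
    the identity."""
    I1, I2 = strain_invariants(l1, l2)
    assert I1 + 2.0 >= 2.0 * np.sqrt(I2 + 1.0) - 1e-12
    if abs(l1 - l2) < 1e-12:
        assert I1 + 2.0 == pytest.approx(2.0 * np.sqrt(I2 + 1.0))
    # I2 + 1 = (l1 l2)^2 exactly
    assert I2 + 1.0 == pytest.approx((l1 * l2) ** 2, rel=1e-12)


@settings(derandomize=True, max_examples=20, deadline=None)
@given(scale=st.floats(0.8, 1.25), seed=st.integers(0, 10**6))
def test_energy_nonnegative_and_rotation_invariant(scale, seed):
    """Total energy is non-negative for arbitrary deformations and exactly
    invariant under rigid rotation of the deformed state."""
    p = MaterialParams()
    m = biconcave_shape(make_membrane_mesh(1), 7.8)
    r = np.random.default_rng(seed)
    m.vertices = scale * m.vertices + 0.1 * r.standard_normal(m.vertices.shape)
    e = total_energy(m, p)
    assert e >= 0.0
    th = r.uniform(0, 2 * np.pi)
    Rz = np.array(
        [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]]
    )
    m2 = m.copy()
    m2.vertices = m.vertices @ Rz.T
    assert total_energy(m2, p) == pytest.approx(e, rel=1e-9)
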