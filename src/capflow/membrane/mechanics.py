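"""Membrane elastic and bending mechanics.

Elastic response follows the Skalak strain-energy function

    W_s = (G_s / 4) [ (I1^2 + 2 I1 - 2 I2) + C I2^2 ],

with strain invariants I1 = l1^2 + l2^2 - 2 and I2 = l1^2 l2^2 - 1 built
from the in-plane principal stretches of each element relative to its
reference configuration.  The dilatation constant C (default 100) renders
the membrane nearly area-incompressible.

The energy is discretized with constant-strain triangles: the invariants of
an element are functions of its current edge metric expressed in reference
element coordinates, so the energy is a smooth function of vertex positions
and the nodal forces returned by :func:`membrane_forces` are its exact
negative gradient.  Bending uses an edge-hinge discretization of the
Helfrich curvature energy (dihedral-angle deviations from the stress-free
rest shape), again with exact analytic gradients; see docs/methods.md for
the relation to the continuum form and the choice of hinge weights.
Rigid-body translations and rotations are exact zero-energy modes of both
terms.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..units import GS_DEFAULT, KB_DEFAULT, C_DILATATION, LAMBDA_VISCOSITY
from .mesh import MembraneMesh

#: hinge-weight normalization: with weights 3 l^2 / (A1 + A2) and this
#: prefactor the discrete energy of a finely triangulated sphere with flat
#: rest angles reproduces the Helfrich value 8 pi k_b to within about 1.5%
#: (calibration of the discretization, see docs/methods.md)
HINGE_PREFACTOR = 1.0


@dataclass(frozen=True)
class MaterialParams:
    """RBC membrane material constants (internal um-s-pg units)."""

    Gs: float = GS_DEFAULT          # membrane shear elasticity, pg/s^2
    C: float = C_DILATATION         # area-dilatation penalty, dimensionless
    kb: float = KB_DEFAULT          # bending modulus, pg um^2/s^2
    viscosity_ratio: float = LAMBDA_VISCOSITY

    def __post_init__(self):
        if self.Gs <= 0 or self.kb < 0:
            raise ValueError("material moduli must be positive")
        if self.C < 1:
            raise ValueError("dilatation constant C must be >= 1")


def strain_invariants(lambda1: float, lambda2: float) -> tuple:
    """Skalak invariants from in-plane principal stretches."""
    l1, l2 = np.asarray(lambda1, float), np.asarray(lambda2, float)
    if np.any(l1 <= 0) or np.any(l2 <= 0):
        raise ValueError("principal stretches must be positive")
    return l1**2 + l2**2 - 2.0, (l1 * l2) ** 2 - 1.0


def _reference_element_data(mesh: MembraneMesh):
    """Per-element reference metric inverse and reference areas (cached)."""
    cache = mesh._ref_cache
    if "elastic" in cache:
        return cache["elastic"]
    X = mesh.ref_vertices
    if X is None:
        raise ValueError("reference configuration not set")
    f = mesh.faces
    e1 = X[f[:, 1]] - X[f[:, 0]]
    e2 = X[f[:, 2]] - X[f[:, 0]]
    a0 = np.einsum("ij,ij->i", e1, e1)
    b0 = np.einsum("ij,ij->i", e1, e2)
    c0 = np.einsum("ij,ij->i", e2, e2)
    det0 = a0 * c0 - b0 * b0  # = (2 A_ref)^2
    if np.any(det0 <= 0):
        raise ValueError("degenerate reference element")
    area0 = 0.5 * np.sqrt(det0)
    # M = Dref^-1 Dref^-T expressed through the reference edge Gram matrix:
    # M = adj(G0) / det(G0) with G0 = [[a0, b0], [b0, c0]]
    m11 = c0 / det0
    m12 = -b0 / det0
    m22 = a0 / det0
    cache["elastic"] = (m11, m12, m22, det0, area0)
    return cache["elastic"]


def _edge_metric(verts, faces):
    d1 = verts[faces[:, 1]] - verts[faces[:, 0]]
    d2 = verts[faces[:, 2]] - verts[faces[:, 0]]
    a = np.einsum("ij,ij->i", d1, d1)
    b = np.einsum("ij,ij->i", d1, d2)
    c = np.einsum("ij,ij->i", d2, d2)
    return d1, d2, a, b, c


def element_invariants(mesh: MembraneMesh):
    """Per-element Skalak invariants (I1, I2) of the current configuration."""
    m11, m12, m22, det0, _ = _reference_element_data(mesh)
    _, _, a, b, c = _edge_metric(mesh.vertices, mesh.faces)
    I1 = m11 * a + 2.0 * m12 * b + m22 * c - 2.0
    I2 = (a * c - b * b) / det0 - 1.0
    return I1, I2


def elastic_energy(mesh: MembraneMesh, params: MaterialParams) -> float:
    """Skalak strain energy integrated over the reference surface."""
    I1, I2 = element_invariants(mesh)
    *_, area0 = _reference_element_data(mesh)
    W = 0.25 * params.Gs * ((I1**2 + 2.0 * I1 - 2.0 * I2) + params.C * I2**2)
    return float(np.sum(W * area0))


def _elastic_forces(mesh: MembraneMesh, params: MaterialParams, out: np.ndarray):
    m11, m12, m22, det0, area0 = _reference_element_data(mesh)
    f = mesh.faces
    d1, d2, a, b, c = _edge_metric(mesh.vertices, f)
    I1 = m11 * a + 2.0 * m12 * b + m22 * c - 2.0
    I2 = (a * c - b * b) / det0 - 1.0
    if np.any(a * c - b * b <= 1e-12 * det0):
        bad = int(np.argmin(a * c - b * b))
        raise FloatingPointError(f"membrane element {bad} degenerated (near-zero area)")
    g = 0.25 * params.Gs * area0
    dW_dI1 = g * (2.0 * I1 + 2.0)
    dW_dI2 = g * (-2.0 + 2.0 * params.C * I2)
    # chain rule through the edge Gram entries (a, b, c)
    dE_da = dW_dI1 * m11 + dW_dI2 * (c / det0)
    dE_db = dW_dI1 * (2.0 * m12) + dW_dI2 * (-2.0 * b / det0)
    dE_dc = dW_dI1 * m22 + dW_dI2 * (a / det0)
    g1 = 2.0 * dE_da[:, None] * d1 + dE_db[:, None] * d2   # dE/dx1
    g2 = 2.0 * dE_dc[:, None] * d2 + dE_db[:, None] * d1   # dE/dx2
    g0 = -(g1 + g2)
    np.add.at(out, f[:, 0], -g0)
    np.add.at(out, f[:, 1], -g1)
    np.add.at(out, f[:, 2], -g2)


def _hinge_reference_data(mesh: MembraneMesh):
    cache = mesh._ref_cache
    if "hinge" in cache:
        return cache["hinge"]
    hinges = mesh.build_hinges()
    theta0 = _dihedral_angles(mesh.ref_vertices, hinges)
    X = mesh.ref_vertices
    e_len = np.linalg.norm(X[hinges[:, 1]] - X[hinges[:, 0]], axis=1)
    aA = 0.5 * np.linalg.norm(
        np.cross(X[hinges[:, 1]] - X[hinges[:, 0]], X[hinges[:, 2]] - X[hinges[:, 0]]), axis=1
    )
    aB = 0.5 * np.linalg.norm(
        np.cross(X[hinges[:, 3]] - X[hinges[:, 0]], X[hinges[:, 1]] - X[hinges[:, 0]]), axis=1
    )
    weights = 3.0 * e_len**2 / (aA + aB)
    cache["hinge"] = (theta0, weights)
    return cache["hinge"]


def _hinge_geometry(verts, hinges):
    x0 = verts[hinges[:, 0]]
    x1 = verts[hinges[:, 1]]
    x2 = verts[hinges[:, 2]]
    x3 = verts[hinges[:, 3]]
    e = x1 - x0
    elen = np.linalg.norm(e, axis=1)
    nA = np.cross(e, x2 - x0)
    nB = np.cross(x3 - x0, e)
    return x0, x1, x2, x3, e, elen, nA, nB


def _dihedral_angles(verts, hinges):
    """Signed dihedral angle per hinge; zero for coplanar faces."""
    _, _, _, _, e, elen, nA, nB = _hinge_geometry(verts, hinges)
    nAu = nA / np.linalg.norm(nA, axis=1)[:, None]
    nBu = nB / np.linalg.norm(nB, axis=1)[:, None]
    cos = np.einsum("ij,ij->i", nAu, nBu)
    sin = np.einsum("ij,ij->i", np.cross(nAu, nBu), e) / elen
    return np.arctan2(sin, cos)


def bending_energy(mesh: MembraneMesh, params: MaterialParams) -> float:
    """Hinge-discretized Helfrich bending energy relative to the rest shape."""
    theta0, w = _hinge_reference_data(mesh)
    theta = _dihedral_angles(mesh.vertices, mesh.hinges)
    return float(0.5 * HINGE_PREFACTOR * params.kb * np.sum(w * (theta - theta0) ** 2))


def _bending_forces(mesh: MembraneMesh, params: MaterialParams, out: np.ndarray):
    theta0, w = _hinge_reference_data(mesh)
    hinges = mesh.hinges
    x0, x1, x2, x3, e, elen, nA, nB = _hinge_geometry(mesh.vertices, hinges)
    nA2 = np.einsum("ij,ij->i", nA, nA)
    nB2 = np.einsum("ij,ij->i", nB, nB)
    nAu = nA / np.sqrt(nA2)[:, None]
    nBu = nB / np.sqrt(nB2)[:, None]
    cos = np.einsum("ij,ij->i", nAu, nBu)
    sin = np.einsum("ij,ij->i", np.cross(nAu, nBu), e) / elen
    theta = np.arctan2(sin, cos)
    ehat = e / elen[:, None]
    fA = (nA / nA2[:, None])
    fB = (nB / nB2[:, None])
    # exact gradients of the dihedral angle w.r.t. the four stencil vertices
    g2 = -elen[:, None] * fA
    g3 = -elen[:, None] * fB
    cA0 = np.einsum("ij,ij->i", x2 - x1, ehat)
    cB0 = np.einsum("ij,ij->i", x3 - x1, ehat)
    cA1 = np.einsum("ij,ij->i", x2 - x0, ehat)
    cB1 = np.einsum("ij,ij->i", x3 - x0, ehat)
    g0 = -cA0[:, None] * fA - cB0[:, None] * fB
    g1 = cA1[:, None] * fA + cB1[:, None] * fB
    coef = (HINGE_PREFACTOR * params.kb * w * (theta - theta0))[:, None]
    np.add.at(out, hinges[:, 0], -coef * g0)
    np.add.at(out, hinges[:, 1], -coef * g1)
    np.add.at(out, hinges[:, 2], -coef * g2)
    np.add.at(out, hinges[:, 3], -coef * g3)


def total_energy(mesh: MembraneMesh, params: MaterialParams) -> float:
    return elastic_energy(mesh, params) + bending_energy(mesh, params)


def membrane_forces(mesh: MembraneMesh, params: MaterialParams) -> np.ndarray:
    """Per-vertex membrane forces (pg um / s^2).

    Exact negative gradient of the total discrete energy (Skalak elastic +
    hinge Helfrich bending) with respect to vertex positions.  Net force
    and net torque over a closed membrane vanish to round-off because the
    energy is invariant under rigid-body motion.
    """
    out = np.zeros_like(mesh.vertices)
    _elastic_forces(mesh, params, out)
    if params.kb > 0:
        _bending_forces(mesh, params, out)
    return out


def element_state(mesh: MembraneMesh, params: MaterialParams | None = None) -> dict:
    """Diagnostic per-element/per-vertex state of the current configuration."""
    from .mesh import mean_curvature, area_volume

    I1, I2 = element_invariants(mesh)
    lam_sq_sum = I1 + 2.0
    lam_sq_prod = I2 + 1.0
    disc = np.clip(lam_sq_sum**2 - 4.0 * lam_sq_prod, 0.0, None)
    l1 = np.sqrt(0.5 * (lam_sq_sum + np.sqrt(disc)))
    l2 = np.sqrt(np.clip(0.5 * (lam_sq_sum - np.sqrt(disc)), 0.0, None))
    area, volume = area_volume(mesh)
    return {
        "I1": I1,
        "I2": I2,
        "lambda1": l1,
        "lambda2": l2,
        "mean_curvature": mean_curvature(mesh),
        "area": area,
        "volume": volume,
    }
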