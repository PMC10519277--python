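"""Variable-viscosity unsteady Stokes flow on a staggered grid with
ghost-node wall enforcement.

Momentum is advanced with an incremental pressure-correction projection:

    (rho/dt) (u* - u^n) = -G p^n + mu0 L u* + f
    L_p phi = D u* / (dt/rho),   u^{n+1} = u* - (dt/rho) G phi,  p += phi

where f collects spread membrane forces, the explicit cross-component part
of the variable-viscosity stress, and any body-force drive.  The viscous
operator L is treated implicitly per component with the local viscosity
field (all second derivatives of the component itself, own-axis
coefficient doubled) and is refactorized whenever the viscosity field is
re-installed via :meth:`StokesSolver.set_viscosity`; only the transpose
remainder sum_{j != i} d_j(mu d_i u_j) is explicit.  Uniform-viscosity
(plasma-only) runs use the plain constant-coefficient Laplacian.

Velocities live on cell faces (MAC layout), pressure at cell centers; the
wall condition u_GN = -u_IP is folded into every operator through a sparse
ghost-response matrix, so the implicit solves and the projection see the
walls exactly.  Operators are factorized with sparse LU behind a
band-minimizing permutation, making each step a handful of
back-substitutions.  The projection operator is the exact composition
divergence * ghost-response * gradient, so the discrete divergence at
fluid cells vanishes to solver precision after each step.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu, spsolve

from ..grid import EulerianGrid
from ..units import MU_PLASMA, RHO, LAMBDA_VISCOSITY
from ..walls import classify_nodes, build_ghost_map, ghost_matrix, FLUID
from . import kernels

COMPONENTS = ("u", "v", "w")


@dataclass(frozen=True)
class FluidParams:
    """Newtonian two-fluid parameters (internal um-s-pg units)."""

    rho: float = RHO
    mu_p: float = MU_PLASMA
    mu_c: float = LAMBDA_VISCOSITY * MU_PLASMA

    def __post_init__(self):
        if not (self.mu_c >= self.mu_p > 0 and self.rho > 0):
            raise ValueError("need mu_c >= mu_p > 0 and rho > 0")


@dataclass
class FlowState:
    """Full-lattice velocity fields (one 3D array per MAC component),
    pressure at cell centers, and simulation time."""

    u: np.ndarray
    v: np.ndarray
    w: np.ndarray
    p: np.ndarray
    t: float


def _flat(shape, i, j, k):
    return (i * shape[1] + j) * shape[2] + k


class _PermLU:
    """Sparse LU behind a band-minimizing symmetric permutation.

    Grid unknowns are pre-ordered with the slowest axis last, which cuts
    SuperLU fill roughly in half on these lattice operators; SymmetricMode
    with diagonal pivoting exploits the near-symmetry."""

    def __init__(self, A, order):
        self.order = order
        self.inv = np.argsort(order)
        Ap = A.tocsr()[order, :][:, order].tocsc()
        self.lu = splu(
            Ap,
            permc_spec="MMD_AT_PLUS_A",
            diag_pivot_thresh=0.0,
            options=dict(SymmetricMode=True),
        )

    def solve(self, b):
        return self.lu.solve(b[self.order])[self.inv]


def _band_order(unknown_flat, shape):
    i, j, k = np.unravel_index(unknown_flat, shape)
    return np.lexsort((i, j, k))


class StokesSolver:
    """Unsteady Stokes stepper for one fixed lumen geometry.

    Parameters
    ----------
    grid : EulerianGrid
        Cell decomposition of the computational box.
    surface : WallSurface or callable
        Lumen wall (signed distance negative inside).
    dt : float
        Time step (fixed for the life of the solver; operators are
        factorized once).
    params : FluidParams
    periodic_z : bool
        Axially periodic domain (body-force driven); otherwise the lower z
        face is an inlet (prescribed axial velocity profile) and the upper
        z face a traction-free outlet at reference pressure zero.
    inlet : callable (x, y) -> axial velocity, required for non-periodic.
    mu0 : float
        Constant implicit viscosity of the split; defaults to mu_c.
    """

    def __init__(
        self,
        grid: EulerianGrid,
        surface,
        *,
        dt: float,
        params: FluidParams = FluidParams(),
        periodic_z: bool = False,
        inlet=None,
        mu0: float | None = None,
    ):
        self.grid = grid
        self.surface = surface
        self.dt = float(dt)
        self.params = params
        self.periodic_z = bool(periodic_z)
        self.mu0 = params.mu_c if mu0 is None else float(mu0)
        if not periodic_z and inlet is None:
            raise ValueError("non-periodic domain requires an inlet profile")

        self.lattices = {
            "u": grid.face_lattice(0),
            "v": grid.face_lattice(1),
            "w": grid.face_lattice(2, periodic=periodic_z),
        }
        self.p_lattice = grid.cell_centers()
        self.labels = {}
        self.gmaps = {}
        self.known_mask = {}
        self.known_vals = {}
        self.unknown_idx = {}
        paxis = 2 if periodic_z else None
        for c, lat in self.lattices.items():
            lab = classify_nodes(lat, surface, periodic_axis=paxis)
            self.labels[c] = lab
            self.gmaps[c] = build_ghost_map(lab, surface, periodic_axis=paxis)
            known = np.zeros(lat.n_points, dtype=bool)
            vals = np.zeros(lat.n_points)
            if c == "w" and not periodic_z:
                shp = lat.shape
                pts = lat.points().reshape(shp + (3,))
                fluid3 = (lab.labels == FLUID).reshape(shp)
                kmask = np.zeros(shp, dtype=bool)
                kmask[:, :, 0] = fluid3[:, :, 0]
                known = kmask.ravel()
                xy = pts[:, :, 0, :2].reshape(-1, 2)
                vals3 = np.zeros(shp)
                vals3[:, :, 0] = np.asarray(inlet(xy[:, 0], xy[:, 1])).reshape(shp[0], shp[1])
                vals3[:, :, 0][~fluid3[:, :, 0]] = 0.0
                vals = vals3.ravel()
            self.known_mask[c] = known
            self.known_vals[c] = vals
            self.unknown_idx[c] = np.flatnonzero((lab.labels == FLUID) & ~known)

        plab = classify_nodes(self.p_lattice, surface, periodic_axis=paxis)
        self.p_fluid = np.flatnonzero(plab.labels == FLUID)
        self.p_labels = plab

        self._assemble()
        nu = {c: len(self.unknown_idx[c]) for c in COMPONENTS}
        self.state = {c: np.zeros(nu[c]) for c in COMPONENTS}
        self.pressure = np.zeros(len(self.p_fluid))
        self.t = 0.0

    # ------------------------------------------------------------------ setup
    def _ghost_response(self, c):
        """Ghost values as an affine function of the unknown vector."""
        lat = self.lattices[c]
        gmap = self.gmaps[c]
        n_full = lat.n_points
        Gm = ghost_matrix(gmap)  # n_ghost x n_full
        unk = self.unknown_idx[c]
        known = self.known_mask[c]
        gcols = np.zeros(n_full, dtype=bool)
        gcols[gmap.ghost_flat] = True
        col_is_ghost = gcols
        # split columns
        M_unk = Gm[:, unk]
        aff = Gm[:, known.nonzero()[0]] @ self.known_vals[c][known]
        Mgg_full = Gm[:, col_is_ghost.nonzero()[0]]
        # reorder ghost columns to ghost ordering
        order = np.argsort(gmap.ghost_flat)
        # ghost_flat sorted already by construction of flatnonzero
        Mgg = Mgg_full
        n_g = gmap.n_ghost
        A = sp.eye(n_g, format="csc") - Mgg.tocsc()
        resp = spsolve(A, sp.hstack([M_unk.tocsc(), sp.csc_matrix(aff[:, None])]))
        resp = sp.csc_matrix(resp)
        S_ghost = resp[:, :-1]
        aff_ghost = np.asarray(resp[:, -1].todense()).ravel()
        return S_ghost.tocsr(), aff_ghost

    def _build_S(self, c):
        """Full-lattice response: full = S @ unknowns + s0."""
        lat = self.lattices[c]
        n_full = lat.n_points
        unk = self.unknown_idx[c]
        rows = [sp.csr_matrix(
            (np.ones(len(unk)), (unk, np.arange(len(unk)))), shape=(n_full, len(unk))
        )]
        s0 = np.zeros(n_full)
        s0[self.known_mask[c]] = self.known_vals[c][self.known_mask[c]]
        gmap = self.gmaps[c]
        if gmap.n_ghost:
            Sg, aff_g = self._ghost_response(c)
            lift = sp.csr_matrix(
                (np.ones(gmap.n_ghost), (gmap.ghost_flat, np.arange(gmap.n_ghost))),
                shape=(n_full, gmap.n_ghost),
            )
            rows.append(lift @ Sg)
            s0 = s0 + lift @ aff_g
        S = rows[0] if len(rows) == 1 else (rows[0] + rows[1])
        return S.tocsr(), s0

    def _laplacian_full(self, c):
        lat = self.lattices[c]
        shape = lat.shape
        n = lat.n_points
        h2 = lat.h**2
        I, J, V = [], [], []
        idx3 = np.arange(n).reshape(shape)
        diag = np.zeros(n)
        for axis in range(3):
            for side in (-1, 1):
                src = idx3
                nb = np.roll(idx3, -side, axis=axis)
                valid = np.ones(shape, dtype=bool)
                sl = [slice(None)] * 3
                sl[axis] = -1 if side == 1 else 0
                edge = tuple(sl)
                if axis == 2 and self.periodic_z:
                    pass  # wrap is correct
                else:
                    valid[edge] = False
                I.append(src[valid].ravel())
                J.append(nb[valid].ravel())
                V.append(np.full(valid.sum(), 1.0 / h2))
                diag -= 1.0 / h2 * np.ones(n)
                # boundary closures on the z axis for non-periodic domains
                if not (axis == 2 and self.periodic_z):
                    edge_idx = idx3[edge].ravel()
                    if axis == 2 and not self.periodic_z:
                        if c in ("u", "v"):
                            if side == -1:
                                # inlet plane: no-slip for transverse components
                                diag[edge_idx] -= 1.0 / h2
                            else:
                                # outlet: zero gradient
                                diag[edge_idx] += 1.0 / h2
                        else:  # w
                            if side == 1:
                                # virtual node beyond outlet face: zero gradient
                                diag[edge_idx] += 1.0 / h2
                            # side == -1 is the inlet face layer itself (known)
                    # lateral edges: neighbors outside are solid; drop (0)
        diag_m = sp.csr_matrix((diag, (np.arange(n), np.arange(n))), shape=(n, n))
        off = sp.csr_matrix(
            (np.concatenate(V), (np.concatenate(I), np.concatenate(J))), shape=(n, n)
        )
        return diag_m + off

    def _padded_mu(self, mu_cells):
        """Cell viscosities padded by one layer (plasma outside, wrap in z)."""
        nx, ny, nz = self.grid.shape
        MU = np.full((nx + 2, ny + 2, nz + 2), self.params.mu_p)
        MU[1:-1, 1:-1, 1:-1] = mu_cells
        if self.periodic_z:
            MU[1:-1, 1:-1, 0] = mu_cells[:, :, -1]
            MU[1:-1, 1:-1, -1] = mu_cells[:, :, 0]
        return MU

    def _viscous_matrix_variable(self, c, mu_cells):
        """Implicit part of the variable-viscosity stress divergence for one
        component: sum_j d_j(mu d_j u_c) + d_c(mu d_c u_c) -- i.e. the full
        second-derivative terms including the doubled own-axis coefficient.
        The remaining cross-component terms are handled explicitly."""
        lat = self.lattices[c]
        S = lat.shape
        n = lat.n_points
        h2 = lat.h**2
        sc = COMPONENTS.index(c)
        MUp = self._padded_mu(mu_cells)
        idx3 = np.arange(n).reshape(S)
        I, J, V = [], [], []
        diag = np.zeros(n)
        for a in range(3):
            periodic_link = a == 2 and self.periodic_z
            n_links = S[a] if periodic_link else S[a] - 1
            # link viscosity coefficients
            if a == sc:
                sl = [slice(1, S[ax] + 1) for ax in range(3)]
                sl[a] = slice(1, n_links + 1)
                C = 2.0 * MUp[tuple(sl)]
            else:
                C = 0.0
                for da in (0, 1):
                    for ds in (0, 1):
                        sl = [None, None, None]
                        for ax in range(3):
                            if ax == a:
                                sl[ax] = slice(1 + da, 1 + da + n_links)
                            elif ax == sc:
                                sl[ax] = slice(ds, ds + S[ax])
                            else:
                                sl[ax] = slice(1, S[ax] + 1)
                        C = C + MUp[tuple(sl)]
                C = 0.25 * C
            src_sl = [slice(None)] * 3
            src_sl[a] = slice(0, n_links)
            n1 = idx3[tuple(src_sl)].ravel()
            if periodic_link:
                n2 = np.roll(idx3, -1, axis=a).ravel()
            else:
                nb_sl = [slice(None)] * 3
                nb_sl[a] = slice(1, n_links + 1)
                n2 = idx3[tuple(nb_sl)].ravel()
            w = (C / h2).ravel()
            I.extend([n1, n2])
            J.extend([n2, n1])
            V.extend([w, w])
            np.add.at(diag, n1, -w)
            np.add.at(diag, n2, -w)
        # inlet-plane mirror closure for transverse components
        if not self.periodic_z and c in ("u", "v"):
            edge = idx3[:, :, 0].ravel()
            diag[edge] -= 2.0 * self.params.mu_p / h2
        M = sp.csr_matrix(
            (np.concatenate(V), (np.concatenate(I), np.concatenate(J))), shape=(n, n)
        )
        return M + sp.csr_matrix((diag, (np.arange(n), np.arange(n))), shape=(n, n))

    def set_viscosity(self, mu_cells):
        """(Re)build and factorize the implicit momentum operators.

        ``mu_cells`` is the cell-centered viscosity field, or None for
        uniform plasma (constant-coefficient Laplacian path).  Called on
        every indicator refresh; the projection operators are unaffected.
        """
        rho, dt = self.params.rho, self.dt
        self._mu_var = None if mu_cells is None else np.asarray(mu_cells)
        self.lap_aff = {}
        self.A_lu = {}
        for c in COMPONENTS:
            if mu_cells is None:
                lap = self.mu0 * self._laplacian_full(c)
            else:
                lap = self._viscous_matrix_variable(c, mu_cells)
            unk = self.unknown_idx[c]
            lap_s = (lap @ self.S[c]).tocsr()
            self.lap_aff[c] = np.asarray(lap @ self.s0[c])[unk]
            A = sp.eye(len(unk), format="csc") * (rho / dt) - lap_s[unk].tocsc()
            if not hasattr(self, "_orders"):
                self._orders = {}
            if c not in self._orders:
                self._orders[c] = _band_order(unk, self.lattices[c].shape)
            self.A_lu[c] = _PermLU(A, self._orders[c])

    def _divergence_ops(self):
        """D_c: fluid-cell divergence rows over full component lattices."""
        shape = self.grid.shape
        nx, ny, nz = shape
        cells = np.unravel_index(self.p_fluid, shape)
        i, j, k = cells
        rows = np.arange(len(self.p_fluid))
        h = self.grid.h
        D = {}
        lu = self.lattices["u"].shape
        D["u"] = sp.csr_matrix(
            (
                np.concatenate([np.full(len(rows), 1 / h), np.full(len(rows), -1 / h)]),
                (
                    np.concatenate([rows, rows]),
                    np.concatenate([_flat(lu, i + 1, j, k), _flat(lu, i, j, k)]),
                ),
            ),
            shape=(len(rows), self.lattices["u"].n_points),
        )
        lv = self.lattices["v"].shape
        D["v"] = sp.csr_matrix(
            (
                np.concatenate([np.full(len(rows), 1 / h), np.full(len(rows), -1 / h)]),
                (
                    np.concatenate([rows, rows]),
                    np.concatenate([_flat(lv, i, j + 1, k), _flat(lv, i, j, k)]),
                ),
            ),
            shape=(len(rows), self.lattices["v"].n_points),
        )
        lw = self.lattices["w"].shape
        khi = (k + 1) % lw[2] if self.periodic_z else k + 1
        D["w"] = sp.csr_matrix(
            (
                np.concatenate([np.full(len(rows), 1 / h), np.full(len(rows), -1 / h)]),
                (
                    np.concatenate([rows, rows]),
                    np.concatenate([_flat(lw, i, j, khi), _flat(lw, i, j, k)]),
                ),
            ),
            shape=(len(rows), self.lattices["w"].n_points),
        )
        return D

    def _gradient_ops(self):
        """G_c: pressure gradient at unknown faces (Neumann at walls,
        Dirichlet zero at the outlet plane)."""
        shape = self.grid.shape
        nx, ny, nz = shape
        h = self.grid.h
        p_index = np.full(int(np.prod(shape)), -1, dtype=np.int64)
        p_index[self.p_fluid] = np.arange(len(self.p_fluid))
        G = {}
        for ci, c in enumerate(COMPONENTS):
            lat = self.lattices[c]
            unk = self.unknown_idx[c]
            ii, jj, kk = np.unravel_index(unk, lat.shape)
            rows, cols, vals = [], [], []
            if c == "u":
                hi = np.stack([ii, jj, kk], 1)
                lo = np.stack([ii - 1, jj, kk], 1)
            elif c == "v":
                hi = np.stack([ii, jj, kk], 1)
                lo = np.stack([ii, jj - 1, kk], 1)
            else:
                hi = np.stack([ii, jj, kk], 1)
                lo = np.stack([ii, jj, kk - 1], 1)
                if self.periodic_z:
                    lo[:, 2] %= nz
            for r in range(len(unk)):
                chi, clo = hi[r], lo[r]
                if c == "w" and not self.periodic_z and chi[2] == nz:
                    # outlet face: p = 0 on the boundary face
                    pl = p_index[_flat(shape, *clo)] if np.all(clo >= 0) else -1
                    if pl >= 0:
                        rows.append(r)
                        cols.append(pl)
                        vals.append(-2.0 / h)
                    continue
                ok_hi = np.all(chi >= 0) and chi[0] < nx and chi[1] < ny and chi[2] < nz
                ok_lo = np.all(clo >= 0) and clo[0] < nx and clo[1] < ny and clo[2] < nz
                ph = p_index[_flat(shape, *chi)] if ok_hi else -1
                pl = p_index[_flat(shape, *clo)] if ok_lo else -1
                if ph >= 0 and pl >= 0:
                    rows.extend([r, r])
                    cols.extend([ph, pl])
                    vals.extend([1.0 / h, -1.0 / h])
                # a solid neighbor cell -> homogeneous Neumann -> zero row
            G[c] = sp.csr_matrix(
                (vals, (rows, cols)), shape=(len(unk), len(self.p_fluid))
            )
        return G

    def _assemble(self):
        self.S = {}
        self.s0 = {}
        for c in COMPONENTS:
            S, s0 = self._build_S(c)
            self.S[c], self.s0[c] = S, s0
        self.set_viscosity(None)
        self.D = self._divergence_ops()
        self.G = self._gradient_ops()
        self.DS = {c: (self.D[c] @ self.S[c]).tocsr() for c in COMPONENTS}
        self.d0 = sum(self.D[c] @ self.s0[c] for c in COMPONENTS)
        L = sum((self.DS[c] @ self.G[c]) for c in COMPONENTS).tolil()
        self._pinned = False
        if self.periodic_z:
            # all-Neumann system: pin the first fluid cell's correction
            L[0, :] = 0.0
            L[0, 0] = 1.0
            self._pinned = True
        self.L_lu = _PermLU(
            L.tocsc(), _band_order(self.p_fluid, self.grid.shape)
        )

    # ------------------------------------------------------------------ stepping
    def step(self, forces=None, mu_cells=None, body_force=None):
        """Advance one time step.

        forces : dict of full-lattice 3D force-density arrays per component
        mu_cells : 3D viscosity at cell centers; passing a field here only
            refreshes the implicit operators when it differs from the one
            installed via :meth:`set_viscosity`
        body_force : (3,) uniform driving force density
        """
        rho, dt = self.params.rho, self.dt
        if mu_cells is not None and (
            self._mu_var is None or mu_cells is not self._mu_var
        ):
            self.set_viscosity(mu_cells)
        expl = None
        if self._mu_var is not None:
            expl = transpose_viscous(
                *[self.full_component(c) for c in COMPONENTS],
                self._padded_mu(self._mu_var), self.grid.h, self.periodic_z,
            )
        ustar = {}
        for ci, c in enumerate(COMPONENTS):
            rhs = (rho / dt) * self.state[c] - self.G[c] @ self.pressure
            rhs = rhs + self.lap_aff[c]
            unk = self.unknown_idx[c]
            if forces is not None and forces.get(c) is not None:
                rhs = rhs + forces[c].ravel()[unk]
            if expl is not None:
                rhs = rhs + expl[ci].ravel()[unk]
            if body_force is not None and body_force[ci]:
                rhs = rhs + body_force[ci]
            ustar[c] = self.A_lu[c].solve(rhs)
        rhs_p = sum(self.DS[c] @ ustar[c] for c in COMPONENTS) + self.d0
        if self._pinned:
            rhs_p = rhs_p - rhs_p.mean()
            rhs_p[0] = 0.0
        phi = self.L_lu.solve(rhs_p)
        for c in COMPONENTS:
            self.state[c] = ustar[c] - self.G[c] @ phi
        self.pressure = self.pressure + (rho / dt) * phi
        self.t += dt
        return self

    def solve_steady(self, *, forces=None, mu_cells=None, body_force=None,
                     tol=1e-12, max_steps=400):
        """Iterate to steady state (relative velocity change below tol)."""
        prev = None
        for it in range(max_steps):
            self.step(forces=forces, mu_cells=mu_cells, body_force=body_force)
            cur = np.concatenate([self.state[c] for c in COMPONENTS])
            if prev is not None:
                scale = np.linalg.norm(cur)
                if scale == 0 or np.linalg.norm(cur - prev) <= tol * scale:
                    break
            prev = cur
        return self

    # ------------------------------------------------------------------ access
    def full_component(self, c):
        lat = self.lattices[c]
        full = self.S[c] @ self.state[c] + self.s0[c]
        return full.reshape(lat.shape)

    def flow_state(self) -> FlowState:
        pfull = np.zeros(int(np.prod(self.grid.shape)))
        pfull[self.p_fluid] = self.pressure
        return FlowState(
            self.full_component("u"),
            self.full_component("v"),
            self.full_component("w"),
            pfull.reshape(self.grid.shape),
            self.t,
        )

    def divergence(self):
        """Discrete divergence at fluid cells (1/s)."""
        return sum(self.DS[c] @ self.state[c] for c in COMPONENTS) + self.d0

    def velocity_at(self, pts):
        """Trilinear velocity interpolation (ghost values included)."""
        from ..walls import _trilinear

        pts = np.atleast_2d(pts)
        out = np.empty((len(pts), 3))
        paxis = 2 if self.periodic_z else None
        for ci, c in enumerate(COMPONENTS):
            lat = self.lattices[c]
            full = self.full_component(c).ravel()
            flat, wts = _trilinear(lat, pts, periodic_axis=paxis, clamp=True)
            out[:, ci] = np.einsum("nk,nk->n", wts, full[flat])
        return out

    def interpolate_at(self, pts):
        """Delta-kernel velocity interpolation at membrane vertices."""
        out = np.empty((len(pts), 3))
        for ci, c in enumerate(COMPONENTS):
            out[:, ci] = kernels.interpolate_field(
                pts, self.full_component(c), self.lattices[c], self.periodic_z
            )
        return out

    def spread(self, pts, forces):
        """Spread membrane vertex forces to all component lattices.

        Near the wall part of a vertex's kernel support falls on ghost or
        solid faces, whose entries the momentum solve ignores; each
        vertex's force is rescaled by the kernel weight actually landing
        on fluid faces so the full elastic force acts on the fluid."""
        if not hasattr(self, "_fluid_mask"):
            self._fluid_mask = {
                c: (self.labels[c].labels == FLUID)
                .astype(np.float64)
                .reshape(self.lattices[c].shape)
                for c in COMPONENTS
            }
        out = {}
        for ci, c in enumerate(COMPONENTS):
            wf = kernels.interpolate_field(
                pts, self._fluid_mask[c], self.lattices[c], self.periodic_z
            )
            scaled = forces[:, ci] / np.maximum(wf, 0.25)
            out[c] = kernels.spread_forces(
                pts, scaled, self.lattices[c], self.periodic_z
            )
        return out


def transpose_viscous(U, V, W, MUp, h, periodic_z):
    """Cross-component part of the variable-viscosity stress divergence,
    T_i = sum_{j != i} d_j (mu d_i u_j), on MAC face lattices.

    ``MUp`` is the padded cell viscosity.  Together with the implicit
    per-component operator (which carries all second derivatives of the
    component itself) this completes div[mu (grad u + grad u^T)].
    """
    nx, ny, nz = MUp.shape[0] - 2, MUp.shape[1] - 2, MUp.shape[2] - 2
    nze = nz if periodic_z else nz + 1
    zs0, zs1 = slice(0, nze), slice(1, nze + 1)
    mu_xy = 0.5 * (MUp[:, :-1, 1:-1] + MUp[:, 1:, 1:-1])
    mu_xy = 0.5 * (mu_xy[:-1] + mu_xy[1:])                 # (nx+1, ny+1, nz)
    mu_xz = 0.5 * (MUp[:, 1:-1, zs0] + MUp[:, 1:-1, zs1])
    mu_xz = 0.5 * (mu_xz[:-1] + mu_xz[1:])                 # (nx+1, ny, nze)
    mu_yz = 0.5 * (MUp[1:-1, :, zs0] + MUp[1:-1, :, zs1])
    mu_yz = 0.5 * (mu_yz[:, :-1] + mu_yz[:, 1:])           # (nx, ny+1, nze)

    dvdx = np.zeros((nx + 1, ny + 1, nz))
    dvdx[1:-1, :, :] = np.diff(V, axis=0) / h
    dudy = np.zeros((nx + 1, ny + 1, nz))
    dudy[:, 1:-1, :] = np.diff(U, axis=1) / h
    dwdx = np.zeros((nx + 1, ny, nze))
    dudz = np.zeros((nx + 1, ny, nze))
    dwdy = np.zeros((nx, ny + 1, nze))
    dvdz = np.zeros((nx, ny + 1, nze))
    if periodic_z:
        dwdx[1:-1, :, :] = np.diff(W, axis=0) / h
        dudz[:, :, :] = (U - np.roll(U, 1, axis=2)) / h
        dwdy[:, 1:-1, :] = np.diff(W, axis=1) / h
        dvdz[:, :, :] = (V - np.roll(V, 1, axis=2)) / h
    else:
        dwdx[1:-1, :, :] = np.diff(W, axis=0) / h
        dudz[:, :, 1:-1] = np.diff(U, axis=2) / h
        dwdy[:, 1:-1, :] = np.diff(W, axis=1) / h
        dvdz[:, :, 1:-1] = np.diff(V, axis=2) / h

    def ddz_face(S):
        # d/dz from z-edge stacks onto the component's own lattice
        if periodic_z:
            return (np.roll(S, -1, axis=2) - S) / h
        return np.diff(S, axis=2) / h

    Tu = np.diff(mu_xy * dvdx, axis=1) / h + ddz_face(mu_xz * dwdx)
    Tv = np.diff(mu_xy * dudy, axis=0) / h + ddz_face(mu_yz * dwdy)
    Tw = np.diff(mu_xz * dudz, axis=0) / h + np.diff(mu_yz * dvdz, axis=1) / h
    return Tu, Tv, Tw


def explicit_viscous(U, V, W, mu_delta, h, periodic_z):
    """Full stress divergence div[mu_delta (grad u + grad u^T)] on MAC
    face lattices, assembled entirely from array stencils.

    Not used by the stepper; kept as the independent reference operator
    against which the implicit-matrix + transpose-remainder decomposition
    is verified in the tests.  ``mu_delta`` lives at cell centers and the
    boundary closures zero-pad.
    """
    nx, ny, nz = mu_delta.shape

    def cpad(arr, axes=(0, 1, 2)):
        out = arr
        for ax in axes:
            if ax == 2 and periodic_z:
                lo = np.take(out, [-1], axis=2)
                hi = np.take(out, [0], axis=2)
                out = np.concatenate([lo, out, hi], axis=2)
            else:
                shp = list(out.shape)
                shp[ax] = 1
                z = np.zeros(shp)
                out = np.concatenate([z, out, z], axis=ax)
        return out

    MU = cpad(mu_delta)  # padded cells, index a -> cell a-1

    def ddz(arr):
        if periodic_z:
            return arr - np.roll(arr, 1, axis=2)
        return np.diff(arr, axis=2)

    Tu = np.zeros_like(U)
    Tv = np.zeros_like(V)
    Tw = np.zeros_like(W)

    # --- x momentum -------------------------------------------------------
    Sxx = 2.0 * mu_delta * np.diff(U, axis=0) / h           # at cells
    Tu[1:-1, :, :] += np.diff(Sxx, axis=0) / h
    mu_xy = 0.5 * (MU[:, :-1, 1:-1] + MU[:, 1:, 1:-1])
    mu_xy = 0.5 * (mu_xy[:-1] + mu_xy[1:])                  # (nx+1, ny+1, nz)
    dudy = np.zeros((nx + 1, ny + 1, nz))
    dudy[:, 1:-1, :] = np.diff(U, axis=1) / h
    dvdx = np.zeros((nx + 1, ny + 1, nz))
    dvdx[1:-1, :, :] = np.diff(V, axis=0) / h
    Sxy = mu_xy * (dudy + dvdx)
    Tu += np.diff(Sxy, axis=1) / h
    nze = nz if periodic_z else nz + 1
    zs0, zs1 = slice(0, nze), slice(1, nze + 1)
    mu_xz = 0.5 * (MU[:, 1:-1, zs0] + MU[:, 1:-1, zs1])
    mu_xz = 0.5 * (mu_xz[:-1] + mu_xz[1:])                  # (nx+1, ny, nze)
    dudz = np.zeros((nx + 1, ny, nze))
    dwdx = np.zeros((nx + 1, ny, nze))
    if periodic_z:
        dudz[:, :, :] = (U - np.roll(U, 1, axis=2)) / h
        dwdx[1:-1, :, :] = np.diff(W, axis=0) / h
    else:
        dudz[:, :, 1:-1] = np.diff(U, axis=2) / h
        dwdx[1:-1, :, :] = np.diff(W, axis=0) / h
    Sxz = mu_xz * (dudz + dwdx)
    if periodic_z:
        Tu += (np.roll(Sxz, -1, axis=2) - Sxz) / h
    else:
        Tu += np.diff(Sxz, axis=2) / h

    # --- y momentum -------------------------------------------------------
    Syy = 2.0 * mu_delta * np.diff(V, axis=1) / h
    Tv[:, 1:-1, :] += np.diff(Syy, axis=1) / h
    Tv += np.diff(Sxy, axis=0) / h
    mu_yz = 0.5 * (MU[1:-1, :, zs0] + MU[1:-1, :, zs1])
    mu_yz = 0.5 * (mu_yz[:, :-1] + mu_yz[:, 1:])            # (nx, ny+1, nze)
    dvdz = np.zeros((nx, ny + 1, nze))
    dwdy = np.zeros((nx, ny + 1, nze))
    if periodic_z:
        dvdz[:, :, :] = (V - np.roll(V, 1, axis=2)) / h
        dwdy[:, 1:-1, :] = np.diff(W, axis=1) / h
    else:
        dvdz[:, :, 1:-1] = np.diff(V, axis=2) / h
        dwdy[:, 1:-1, :] = np.diff(W, axis=1) / h
    Syz = mu_yz * (dvdz + dwdy)
    if periodic_z:
        Tv += (np.roll(Syz, -1, axis=2) - Syz) / h
    else:
        Tv += np.diff(Syz, axis=2) / h

    # --- z momentum -------------------------------------------------------
    if periodic_z:
        dWdz = (np.roll(W, -1, axis=2) - W) / h             # at cells
    else:
        dWdz = np.diff(W, axis=2) / h
    Szz = 2.0 * mu_delta * dWdz
    if periodic_z:
        Tw += (Szz - np.roll(Szz, 1, axis=2)) / h
    else:
        Tw[:, :, 1:-1] += np.diff(Szz, axis=2) / h
    Tw += np.diff(Sxz, axis=0) / h
    Tw += np.diff(Syz, axis=1) / h
    return Tu, Tv, Tw
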