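"""Coupled RBC / flow simulation loop.

Orchestrates one fixed geometry: membrane forces -> delta-kernel spreading
-> implicit Stokes step with ghost-node walls -> velocity interpolation ->
forward-Euler membrane advection.  The indicator/viscosity field is
refreshed on a configurable step interval (cells move a small fraction of
a grid cell per step).  The time step is fixed for the life of the run
(the implicit operators are factorized once) and is chosen from
membrane-stiffness and bending stability bounds.

Checkpoints store membrane positions and the discrete flow state, so a
restarted run continues bit-identically.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ..grid import EulerianGrid
from ..membrane import MaterialParams, membrane_forces, area_volume
from ..units import MU_PLASMA
from .indicator import update_indicator, viscosity_field
from .stokes import StokesSolver, FluidParams

#: physiological inlet-hematocrit presets span 12% to 36%
HCT_MIN, HCT_MAX = 0.12, 0.36


def pseudo_shear_rate(mean_velocity: float, diameter: float) -> float:
    """Boundary pseudo-shear rate, U_mean / D (1/s)."""
    return mean_velocity / diameter


def footprint_timescale(distance: float, velocity: float) -> float:
    """Time for an RBC moving at ``velocity`` to traverse ``distance``;
    the timescale its moving WSS footprint imprints on the wall
    (e.g. 10 um at 0.5 mm/s -> 0.02 s)."""
    if velocity <= 0:
        raise ValueError("velocity must be positive")
    return distance / velocity


def poiseuille_body_force(pseudo_shear: float, radius: float, mu: float = MU_PLASMA):
    """Axial body-force density driving a periodic tube at the given
    pseudo-shear rate (G = 8 mu U_mean / R^2 with U_mean = pseudo_shear * 2R)."""
    u_mean = pseudo_shear * 2.0 * radius
    return 8.0 * mu * u_mean / radius**2


def stable_dt(
    h: float,
    material: MaterialParams,
    fluid: FluidParams,
    safety: float = 0.5,
) -> float:
    """Forward-Euler membrane-coupling stability bound.

    The stiff constraint is the Skalak response amplified by the area
    penalty C; bending adds a milder h^3 limit.  The constants come from
    the standard viscous-relaxation estimates for explicit immersed
    elastic interfaces.
    """
    dt_el = fluid.mu_p * h / (material.Gs * (1.0 + 0.25 * material.C))
    dt_bend = fluid.mu_p * h**3 / material.kb if material.kb > 0 else np.inf
    return safety * min(dt_el, dt_bend)


@dataclass
class SimulationConfig:
    grid: EulerianGrid
    surface: object                      # WallSurface or sdf callable
    periodic_z: bool = True
    body_force: tuple = (0.0, 0.0, 0.0)  # periodic drive (pg / um^2 s^2)
    inlet: object = None                 # (x, y) -> w profile, non-periodic
    t_end: float = 0.02
    dt: float | None = None
    dt_safety: float = 0.5
    #: drive soft-start: body force ramps linearly over this time (s)
    ramp_time: float = 0.0
    #: wall standoff distance (units of h) below which membrane vertices feel
    #: a short-range repulsion standing in for the unresolved lubrication film
    wall_standoff: float = 0.6
    #: wall repulsion stiffness (force per unit penetration); 0 disables
    wall_stiffness: float | None = None  # defaults to Gs
    #: blend factor toward the 1-ring mean when advecting membrane vertices;
    #: damps sub-grid-scale membrane modes the delta kernel cannot resolve
    #: (membrane edges are finer than the fluid grid), leaves grid-resolved
    #: motion unchanged to O(edge^2)
    advection_smoothing: float = 0.25
    #: hold the lumen mean axial velocity at this value by rescaling the
    #: body force (imposed-flow-rate drive); None = constant force
    target_mean_velocity: float | None = None
    flux_control_every: int = 50
    material: MaterialParams = field(default_factory=MaterialParams)
    fluid: FluidParams = field(default_factory=FluidParams)
    indicator_every: int = 25
    snapshot_every: float | None = None  # simulated seconds between snapshots
    seed: int = 0


@dataclass
class Snapshot:
    t: float
    flow: object
    membranes: list


class Simulation:
    """One coupled run in a fixed geometry."""

    def __init__(self, config: SimulationConfig, membranes=None):
        self.config = config
        self.membranes = list(membranes or [])
        dt = config.dt or stable_dt(
            config.grid.h, config.material, config.fluid, config.dt_safety
        )
        self.dt = dt
        self.solver = StokesSolver(
            config.grid,
            config.surface,
            dt=dt,
            params=config.fluid,
            periodic_z=config.periodic_z,
            inlet=config.inlet,
        )
        self.step_count = 0
        self.snapshots: list[Snapshot] = []
        self.diagnostics = {"t": [], "area": [], "volume": [], "max_u": []}
        self._mu_cells = None
        self._ref_area = None
        self._ref_volume = None
        self._drive_scale = 1.0
        if self.membranes:
            a = sum(area_volume(m)[0] for m in self.membranes)
            v = sum(area_volume(m)[1] for m in self.membranes)
            self._ref_area, self._ref_volume = a, v

    # -------------------------------------------------------------- helpers
    def _wrap_membranes(self):
        if not self.config.periodic_z:
            return
        lz = self.config.grid.extent[2]
        z0 = self.config.grid.origin[2]
        for m in self.membranes:
            zc = m.vertices[:, 2].mean()
            if zc >= z0 + lz:
                m.vertices[:, 2] -= lz
            elif zc < z0:
                m.vertices[:, 2] += lz

    def _refresh_viscosity(self):
        fp = self.config.fluid
        if not self.membranes or fp.mu_c == fp.mu_p:
            self._mu_cells = None
            return
        I = update_indicator(
            self.membranes, self.solver.p_lattice, periodic_z=self.config.periodic_z
        )
        self._mu_cells = viscosity_field(I, fp.mu_p, fp.mu_c)
        self.solver.set_viscosity(self._mu_cells)

    def mean_axial_velocity(self) -> float:
        """Mean axial velocity over fluid w-faces (lumen average)."""
        wv = self.solver.state["w"]
        return float(wv.mean()) if len(wv) else 0.0

    def _effective_body_force(self):
        cfg = self.config
        if not any(cfg.body_force):
            return None
        scale = self._drive_scale
        if cfg.ramp_time > 0:
            scale *= min(self.solver.t / cfg.ramp_time, 1.0)
        if (
            cfg.target_mean_velocity
            and self.step_count > 0
            and self.step_count % cfg.flux_control_every == 0
            and (cfg.ramp_time == 0 or self.solver.t > cfg.ramp_time)
        ):
            measured = self.mean_axial_velocity()
            if measured > 0:
                # gentle proportional controller; hard clips avoid drive spikes
                adj = np.clip(
                    (cfg.target_mean_velocity / measured) ** 0.25, 0.9, 1.15
                )
                self._drive_scale *= float(adj)
                scale = self._drive_scale
        return tuple(b * scale for b in cfg.body_force)

    def _ring_average(self, mesh):
        """Sparse row-stochastic 1-ring averaging operator (cached per mesh)."""
        key = id(mesh.faces)
        cache = getattr(self, "_ring_ops", None)
        if cache is None:
            cache = self._ring_ops = {}
        if key not in cache:
            import scipy.sparse as sp

            n = mesh.n_vertices
            rows, cols = [], []
            for tri in mesh.faces:
                for a, b in ((0, 1), (1, 2), (2, 0)):
                    rows.extend([tri[a], tri[b]])
                    cols.extend([tri[b], tri[a]])
            M = sp.csr_matrix(
                (np.ones(len(rows)), (rows, cols)), shape=(n, n)
            )
            M.data[:] = 1.0  # dedupe repeated edges
            M = sp.csr_matrix((np.ones_like(M.indices, dtype=float), M.indices, M.indptr), shape=(n, n))
            deg = np.asarray(M.sum(axis=1)).ravel()
            Dinv = sp.diags(1.0 / deg)
            cache[key] = Dinv @ M
        return cache[key]

    def _wall_sdf(self, pts):
        surf = self.config.surface
        fn = surf if callable(surf) else surf.sdf
        return np.asarray(fn(pts))

    def _wall_repulsion(self, pts):
        """Short-range inward force on vertices closer to the wall than the
        standoff distance (stand-in for the unresolved lubrication film)."""
        cfg = self.config
        k = cfg.wall_stiffness if cfg.wall_stiffness is not None else cfg.material.Gs
        if not k:
            return None
        delta = cfg.wall_standoff * cfg.grid.h
        s = self._wall_sdf(pts)
        pen = s + delta
        active = pen > 0
        if not np.any(active):
            return None
        out = np.zeros_like(pts)
        eps = 0.1 * cfg.grid.h
        g = np.zeros((int(active.sum()), 3))
        for a in range(3):
            dp = np.zeros(3)
            dp[a] = eps
            g[:, a] = (self._wall_sdf(pts[active] + dp) - self._wall_sdf(pts[active] - dp)) / (2 * eps)
        g /= np.linalg.norm(g, axis=1)[:, None]
        out[active] = -k * pen[active, None] * g
        return out

    def step(self):
        cfg = self.config
        forces = None
        if self.membranes:
            if self.step_count % cfg.indicator_every == 0:
                self._refresh_viscosity()
            pts = np.vstack([m.vertices for m in self.membranes])
            f = np.vstack([membrane_forces(m, cfg.material) for m in self.membranes])
            fw = self._wall_repulsion(pts)
            if fw is not None:
                f = f + fw
            forces = self.solver.spread(pts, f)
        self.solver.step(forces=forces, body_force=self._effective_body_force())
        if self.membranes:
            pts = np.vstack([m.vertices for m in self.membranes])
            vel = self.solver.interpolate_at(pts)
            if cfg.advection_smoothing > 0:
                a = cfg.advection_smoothing
                lo = 0
                for m in self.membranes:
                    n = m.n_vertices
                    vel[lo:lo + n] = (
                        (1.0 - a) * vel[lo:lo + n]
                        + a * (self._ring_average(m) @ vel[lo:lo + n])
                    )
                    lo += n
            vmax = float(np.abs(vel).max())
            if vmax * self.dt > self.config.grid.h:
                raise RuntimeError(
                    f"instability: membrane velocity {vmax:.3g} um/s exceeds the "
                    f"grid CFL at dt = {self.dt:.3g} s (step {self.step_count})"
                )
            lo = 0
            for m in self.membranes:
                n = m.n_vertices
                m.vertices = m.vertices + self.dt * vel[lo:lo + n]
                lo += n
            self._wrap_membranes()
        self.step_count += 1
        return self

    def run(self, t_end: float | None = None, progress=None):
        t_end = self.config.t_end if t_end is None else t_end
        next_snap = (
            self.solver.t + self.config.snapshot_every
            if self.config.snapshot_every
            else np.inf
        )
        self._record()
        if self.config.snapshot_every is not None:
            self._snapshot()
        while self.solver.t < t_end - 1e-15:
            self.step()
            self._record()
            if self.solver.t >= next_snap - 1e-12:
                self._snapshot()
                next_snap += self.config.snapshot_every
            if progress is not None and self.step_count % 200 == 0:
                progress(self)
        return self

    def _record(self):
        d = self.diagnostics
        d["t"].append(self.solver.t)
        if self.membranes:
            a = sum(area_volume(m)[0] for m in self.membranes)
            v = sum(area_volume(m)[1] for m in self.membranes)
            d["area"].append(a)
            d["volume"].append(v)
        vmax = max(
            (float(np.abs(self.solver.state[c]).max()) if len(self.solver.state[c]) else 0.0)
            for c in ("u", "v", "w")
        )
        d["max_u"].append(vmax)

    def _snapshot(self):
        self.snapshots.append(
            Snapshot(self.solver.t, self.solver.flow_state(), [m.copy() for m in self.membranes])
        )

    # ------------------------------------------------------------ diagnostics
    def area_drift(self) -> float:
        """Max relative surface-area change over the run so far."""
        if self._ref_area is None:
            return 0.0
        a = np.asarray(self.diagnostics["area"])
        return float(np.abs(a - self._ref_area).max() / self._ref_area)

    def volume_drift(self) -> float:
        if self._ref_volume is None:
            return 0.0
        v = np.asarray(self.diagnostics["volume"])
        return float(np.abs(v - self._ref_volume).max() / self._ref_volume)

    # ------------------------------------------------------------ checkpoints
    def save_checkpoint(self, path):
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["t"] = self.solver.t
            f.attrs["step"] = self.step_count
            for c in ("u", "v", "w"):
                f.create_dataset(f"state_{c}", data=self.solver.state[c])
            f.create_dataset("pressure", data=self.solver.pressure)
            for i, m in enumerate(self.membranes):
                f.create_dataset(f"membrane_{i}/vertices", data=m.vertices)
                f.create_dataset(f"membrane_{i}/ref", data=m.ref_vertices)
                f.create_dataset(f"membrane_{i}/faces", data=m.faces)

    def load_checkpoint(self, path):
        import h5py
        from ..membrane import MembraneMesh

        with h5py.File(path, "r") as f:
            self.solver.t = float(f.attrs["t"])
            self.step_count = int(f.attrs["step"])
            for c in ("u", "v", "w"):
                self.solver.state[c] = f[f"state_{c}"][...]
            self.solver.pressure = f["pressure"][...]
            self.membranes = []
            i = 0
            while f"membrane_{i}" in f:
                m = MembraneMesh(
                    f[f"membrane_{i}/vertices"][...], f[f"membrane_{i}/faces"][...]
                )
                m.set_reference(f[f"membrane_{i}/ref"][...])
                self.membranes.append(m)
                i += 1
        if self.membranes and self._ref_area is None:
            self._ref_area = sum(area_volume(m)[0] for m in self.membranes)
            self._ref_volume = sum(area_volume(m)[1] for m in self.membranes)
        return self


def run_simulation(config: SimulationConfig, membranes=None) -> Simulation:
    """Build and run a coupled simulation; returns the finished object."""
    sim = Simulation(config, membranes)
    sim.run()
    return sim


# ---------------------------------------------------------------- injection
class InletFeeder:
    """Library of RBC shapes used for injection at an inlet.

    In full runs the shapes come from a separate straight-tube feeder
    simulation of the same diameter; by default the rest biconcave shape
    is used.
    """

    def __init__(self, shapes=None, rbc_diameter=7.8, level=3):
        from ..membrane import make_membrane_mesh, biconcave_shape

        if shapes is None:
            t = biconcave_shape(make_membrane_mesh(level), rbc_diameter)
            t.vertices -= t.vertices.mean(axis=0)
            shapes = [t.vertices.copy()]
            self._faces = t.faces
        else:
            self._faces = shapes[0].faces
            shapes = [s.vertices - s.vertices.mean(axis=0) for s in shapes]
        self.shapes = shapes
        _, self.cell_volume = area_volume((self.shapes[0] + 0.0, self._faces))

    def make_membrane(self, index, position):
        from ..membrane import MembraneMesh

        verts = self.shapes[index % len(self.shapes)] + np.asarray(position)
        m = MembraneMesh(verts.copy(), self._faces)
        m.set_reference(verts)
        return m


def inject_rbcs(
    membranes: list,
    feeder: InletFeeder,
    target_hematocrit: float,
    *,
    inlet_z: float,
    outlet_z: float,
    tube_radius: float,
    rng,
    window: float = 20.0,
    clearance: float = 0.6,
):
    """Maintain inlet hematocrit by inserting feeder shapes; cull outflow.

    The running hematocrit is measured over a window of tube downstream of
    the inlet; a new cell is inserted (random cross-section offset, up to
    three overlap retries) whenever the windowed value falls below target.
    Cells whose centroid passes the outlet are removed.  Returns the
    updated membrane list and the windowed hematocrit.
    """
    if target_hematocrit < 0:
        raise ValueError("hematocrit must be non-negative")
    if target_hematocrit > 0 and not HCT_MIN <= target_hematocrit <= HCT_MAX:
        clamped = float(np.clip(target_hematocrit, HCT_MIN, HCT_MAX))
        warnings.warn(
            f"inlet hematocrit {target_hematocrit:.2f} outside the physiological "
            f"preset range [{HCT_MIN}, {HCT_MAX}]; clamped to {clamped:.2f}"
        )
        target_hematocrit = clamped
    membranes = [m for m in membranes if m.vertices[:, 2].mean() < outlet_z]
    if target_hematocrit == 0:
        return membranes, 0.0
    zw0, zw1 = inlet_z, min(inlet_z + window, outlet_z)
    wvol = np.pi * tube_radius**2 * (zw1 - zw0)

    def windowed_hct():
        v = sum(
            feeder.cell_volume
            for m in membranes
            if zw0 <= m.vertices[:, 2].mean() < zw1
        )
        return v / wvol

    hct = windowed_hct()
    if hct < target_hematocrit:
        inserted = False
        for attempt in range(3):
            off = rng.standard_normal(2)
            off *= rng.uniform(0, max(tube_radius - 2.0, 0.3)) / np.linalg.norm(off)
            pos = np.array([off[0], off[1], inlet_z + 2.5])
            cand = feeder.make_membrane(rng.integers(0, len(feeder.shapes)), pos)
            if all(
                np.linalg.norm(m.vertices[:, 2].mean() - pos[2]) > clearance * 4.0
                or np.abs(m.vertices[:, 2].mean() - pos[2]) > 6.0
                for m in membranes
            ):
                overlap = any(
                    np.abs(m.vertices[:, 2].mean() - pos[2]) < 5.0
                    and np.linalg.norm(m.vertices.mean(0) - pos) < 4.0
                    for m in membranes
                )
                if not overlap:
                    membranes.append(cand)
                    inserted = True
                    break
        if not inserted:
            warnings.warn("injection skipped: no overlap-free inlet position found")
    return membranes, windowed_hct()
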