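"""Vessel centerlines, network specifications, and analytic lumen distance fields.

A :class:`Centerline` is an ordered 3D polyline with a local lumen radius at
every point.  A :class:`NetworkSpec` collects centerlines, the junctions
where their ends meet, and the inlet/outlet role of every free end.  Both
carry enough information to evaluate a signed distance to the lumen wall
analytically (negative inside the lumen), which the wall machinery and the
RBC seeding use as the fast geometric oracle alongside the triangulated
surface.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Centerline:
    """Ordered centerline trajectory with a local radius profile (um)."""

    points: np.ndarray          # (N, 3)
    radii: np.ndarray           # (N,)
    label: int = 0

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        self.radii = np.broadcast_to(
            np.asarray(self.radii, dtype=float), (len(self.points),)
        ).copy()
        if len(self.points) < 2:
            raise ValueError("centerline needs at least 2 points")
        seg = np.diff(self.points, axis=0)
        if np.any(np.linalg.norm(seg, axis=1) <= 0):
            raise ValueError("consecutive centerline points must be distinct")
        if np.any(self.radii <= 0):
            raise ValueError("all radii must be positive")

    @property
    def arclength(self) -> np.ndarray:
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length(self) -> float:
        return float(self.arclength[-1])

    def tangents(self) -> np.ndarray:
        t = np.gradient(self.points, self.arclength, axis=0)
        return t / np.linalg.norm(t, axis=1)[:, None]

    def curvature(self) -> np.ndarray:
        """Discrete curvature magnitude |dT/ds| at every point."""
        t = self.tangents()
        dt = np.gradient(t, self.arclength, axis=0)
        return np.linalg.norm(dt, axis=1)

    def signed_curvature_2d(self, normal=(0.0, 1.0, 0.0)) -> np.ndarray:
        """Signed curvature for near-planar centerlines (sign from the
        binormal component along ``normal``); used to characterize
        tortuosity (alternating curvature sign)."""
        t = self.tangents()
        dt = np.gradient(t, self.arclength, axis=0)
        b = np.cross(t, dt)
        return np.einsum("ij,j->i", b, np.asarray(normal))

    def resample(self, ds: float) -> "Centerline":
        s = self.arclength
        n = max(2, int(np.ceil(s[-1] / ds)) + 1)
        si = np.linspace(0.0, s[-1], n)
        pts = np.column_stack([np.interp(si, s, self.points[:, k]) for k in range(3)])
        rad = np.interp(si, s, self.radii)
        return Centerline(pts, rad, self.label)

    def sdf(self, pts: np.ndarray, chunk: int = 20000) -> np.ndarray:
        """Signed distance to the tube wall (negative inside the lumen)."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        P0 = self.points[:-1]
        seg = np.diff(self.points, axis=0)
        seg_len2 = np.einsum("ij,ij->i", seg, seg)
        r0, r1 = self.radii[:-1], self.radii[1:]
        out = np.empty(len(pts))
        for lo in range(0, len(pts), chunk):
            q = pts[lo:lo + chunk]
            d = q[:, None, :] - P0[None, :, :]
            t = np.clip(np.einsum("pmk,mk->pm", d, seg) / seg_len2, 0.0, 1.0)
            proj = d - t[..., None] * seg[None, :, :]
            dist = np.sqrt(np.einsum("pmk,pmk->pm", proj, proj))
            rad = r0[None, :] + t * (r1 - r0)[None, :]
            out[lo:lo + chunk] = np.min(dist - rad, axis=1)
        return out


@dataclass(frozen=True)
class Junction:
    """Record of centerline ends meeting at a point.

    ``ends`` is a tuple of ``(centerline_label, which)`` pairs where
    ``which`` is "start" or "end"; interior attachment to the middle of a
    parent centerline is recorded as ("interior", index).
    """

    position: tuple
    ends: tuple


@dataclass
class NetworkSpec:
    """Collection of centerlines, junction records, and boundary roles.

    ``boundary_roles`` maps ``(centerline_label, "start"|"end")`` of every
    free end to "inlet" or "outlet".  Vessels at the domain border are
    always one or the other.
    """

    centerlines: list
    junctions: list = field(default_factory=list)
    boundary_roles: dict = field(default_factory=dict)
    obstructions: list = field(default_factory=list)  # pillar-like subtracted tubes

    def __post_init__(self):
        labels = {c.label for c in self.centerlines}
        if len(labels) != len(self.centerlines):
            raise ValueError("centerline labels must be unique")
        roles = set(self.boundary_roles.values())
        if self.boundary_roles and not {"inlet", "outlet"} <= roles | {"inlet", "outlet"}:
            raise ValueError("boundary roles must be inlet/outlet")
        if self.boundary_roles:
            if "inlet" not in roles or "outlet" not in roles:
                raise ValueError("need at least one inlet and one outlet")

    def by_label(self, label: int) -> Centerline:
        for c in self.centerlines:
            if c.label == label:
                return c
        raise KeyError(label)

    def boundary_ends(self) -> list:
        """Free-end records: (label, which, point, outward_tangent, radius, role)."""
        out = []
        for (label, which), role in sorted(self.boundary_roles.items()):
            c = self.by_label(label)
            t = c.tangents()
            if which == "start":
                pt, tangent, rad = c.points[0], -t[0], c.radii[0]
            else:
                pt, tangent, rad = c.points[-1], t[-1], c.radii[-1]
            out.append((label, which, pt, tangent, rad, role))
        return out

    def sdf(self, pts: np.ndarray) -> np.ndarray:
        """Signed distance of the lumen union (negative inside any vessel);
        pillar-type obstructions are carved out with a CSG difference."""
        pts = np.atleast_2d(pts)
        d = np.min(np.column_stack([c.sdf(pts) for c in self.centerlines]), axis=1)
        for obs in self.obstructions:
            d = np.maximum(d, -obs.sdf(pts))
        return d

    # ------------------------------------------------------------- serialization
    def to_dict(self) -> dict:
        def cl(c):
            return {
                "label": int(c.label),
                "points_um": c.points.tolist(),
                "radii_um": c.radii.tolist(),
            }

        return {
            "units": "um",
            "centerlines": [cl(c) for c in self.centerlines],
            "junctions": [
                {"position_um": list(map(float, j.position)),
                 "ends": [list(e) for e in j.ends]}
                for j in self.junctions
            ],
            "boundary_roles": [
                {"centerline": lbl, "end": which, "role": role}
                for (lbl, which), role in sorted(self.boundary_roles.items())
            ],
            "obstructions": [cl(o) for o in self.obstructions],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "NetworkSpec":
        def cl(d):
            return Centerline(
                np.asarray(d["points_um"]), np.asarray(d["radii_um"]), d["label"]
            )

        return cls(
            [cl(d) for d in data["centerlines"]],
            [
                Junction(tuple(j["position_um"]),
                         tuple(tuple(e) for e in j["ends"]))
                for j in data.get("junctions", [])
            ],
            {
                (r["centerline"], r["end"]): r["role"]
                for r in data.get("boundary_roles", [])
            },
            [cl(d) for d in data.get("obstructions", [])],
        )

    def save(self, path) -> None:
        """Serialize to a structured YAML document (lengths in um)."""
        import yaml

        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=False)

    @classmethod
    def load(cls, path) -> "NetworkSpec":
        import yaml

        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f))
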