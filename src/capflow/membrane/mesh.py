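"""Triangulated RBC membrane meshes.

The membrane is a closed genus-0 Lagrangian surface built by icosahedral
quadrisection: level ``n`` has ``20 * 4**n`` triangles and ``10 * 4**n + 2``
vertices.  Level 4 (5120 elements) is the production resolution.  The resting
shape is the classic biconcave discocyte given by the Evans-Fung quartic
profile; for the standard 7.8 um major diameter it has a surface area of
about 134.1 um^2 and a volume of about 94.1 um^3.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Evans-Fung quartic coefficients on the normalized radius rho = 2 r / D:
#   z(rho) = +/- (D / 4) * sqrt(1 - rho^2) * (c0 + c1 rho^2 + c2 rho^4)
EVANS_FUNG_C0 = 0.207161
EVANS_FUNG_C1 = 2.002558
EVANS_FUNG_C2 = -1.122762


def _icosahedron():
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    verts /= np.linalg.norm(verts[0])
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=np.int64,
    )
    return verts, faces


def _subdivide(verts, faces):
    """One quadrisection step; midpoints are deduplicated and re-projected."""
    verts = list(map(tuple, verts))
    cache = {}

    def midpoint(a, b):
        key = (a, b) if a < b else (b, a)
        if key in cache:
            return cache[key]
        p = 0.5 * (np.asarray(verts[a]) + np.asarray(verts[b]))
        p /= np.linalg.norm(p)
        verts.append(tuple(p))
        cache[key] = len(verts) - 1
        return cache[key]

    new_faces = []
    for (a, b, c) in faces:
        ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
        new_faces.extend([(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)])
    return np.asarray(verts, dtype=float), np.asarray(new_faces, dtype=np.int64)


@dataclass
class MembraneMesh:
    """Closed triangulated membrane with an optional reference configuration.

    ``vertices`` are current positions (um).  ``set_reference`` freezes the
    current shape as the stress-free state and precomputes the per-element
    reference metric and the hinge (edge) structure used by the mechanics.
    """

    vertices: np.ndarray
    faces: np.ndarray
    ref_vertices: np.ndarray | None = None
    # hinge structure: (E, 4) vertex indices [i0 i1 oppA oppB] per interior edge
    hinges: np.ndarray | None = None
    _ref_cache: dict = field(default_factory=dict, repr=False)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def copy(self) -> "MembraneMesh":
        m = MembraneMesh(self.vertices.copy(), self.faces)
        m.ref_vertices = None if self.ref_vertices is None else self.ref_vertices.copy()
        m.hinges = self.hinges
        m._ref_cache = self._ref_cache
        return m

    def build_hinges(self) -> np.ndarray:
        """Edge stencils [i0, i1, oppA, oppB]: faces (i0,i1,oppA), (i1,i0,oppB)."""
        if self.hinges is not None:
            return self.hinges
        edge_map = {}
        for f, (a, b, c) in enumerate(self.faces):
            for (u, v, w) in ((a, b, c), (b, c, a), (c, a, b)):
                key = (u, v) if u < v else (v, u)
                edge_map.setdefault(key, []).append((u, v, w))
        hinges = []
        for key, occ in sorted(edge_map.items()):
            if len(occ) != 2:
                raise ValueError("membrane mesh is not a closed 2-manifold")
            (u, v, w1), (u2, v2, w2) = occ
            # occ stores half-edges; orient so hinge = [u, v, w1(left), w2(right)]
            hinges.append((u, v, w1, w2))
        self.hinges = np.asarray(hinges, dtype=np.int64)
        return self.hinges

    def set_reference(self, vertices: np.ndarray | None = None) -> None:
        self.ref_vertices = np.array(self.vertices if vertices is None else vertices)
        self.build_hinges()
        self._ref_cache = {}


def make_membrane_mesh(level: int) -> MembraneMesh:
    """Unit-sphere membrane mesh by icosahedral quadrisection.

    Level 0 is the icosahedron (20 faces, 12 vertices); each level
    quadruples the face count, so level 4 carries 5120 triangular elements.
    """
    if not 0 <= level <= 6:
        raise ValueError("subdivision level must be in [0, 6]")
    verts, faces = _icosahedron()
    for _ in range(level):
        verts, faces = _subdivide(verts, faces)
    return MembraneMesh(verts, faces)


def biconcave_shape(mesh: MembraneMesh, major_diameter: float = 7.8) -> MembraneMesh:
    """Map a unit-sphere mesh onto the Evans-Fung biconcave discocyte.

    The equatorial (x, y) coordinates are scaled to the major radius and the
    axial coordinate is replaced by the quartic profile, keeping the sign of
    the original hemisphere.  The returned mesh has its reference
    configuration set to the rest shape.
    """
    if major_diameter <= 0:
        raise ValueError("major_diameter must be positive")
    R = 0.5 * major_diameter
    X = mesh.vertices
    rho2 = np.clip(X[:, 0] ** 2 + X[:, 1] ** 2, 0.0, 1.0)
    profile = (
        0.5 * R
        * np.sqrt(1.0 - rho2)
        * (EVANS_FUNG_C0 + EVANS_FUNG_C1 * rho2 + EVANS_FUNG_C2 * rho2**2)
    )
    out = np.empty_like(X)
    out[:, 0] = R * X[:, 0]
    out[:, 1] = R * X[:, 1]
    out[:, 2] = np.sign(X[:, 2]) * profile
    shaped = MembraneMesh(out, mesh.faces)
    shaped.set_reference()
    return shaped


def area_volume(mesh: MembraneMesh | tuple) -> tuple:
    """Surface area and enclosed volume of a closed mesh.

    Area by triangle summation; volume by the divergence theorem
    (positive for outward orientation).
    """
    if isinstance(mesh, MembraneMesh):
        verts, faces = mesh.vertices, mesh.faces
    else:
        verts, faces = mesh
    p0, p1, p2 = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    cr = np.cross(p1 - p0, p2 - p0)
    areas = 0.5 * np.linalg.norm(cr, axis=1)
    if np.any(areas <= 0):
        raise ValueError("mesh has degenerate triangles")
    area = float(areas.sum())
    volume = float(np.einsum("ij,ij->i", p0, cr).sum() / 6.0)
    return area, volume


def vertex_normals_areas(verts: np.ndarray, faces: np.ndarray):
    """Area-weighted outward vertex normals and barycentric vertex areas."""
    p0, p1, p2 = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    cr = np.cross(p1 - p0, p2 - p0)
    fa = 0.5 * np.linalg.norm(cr, axis=1)
    vn = np.zeros_like(verts)
    va = np.zeros(len(verts))
    for k in range(3):
        np.add.at(vn, faces[:, k], cr)
        np.add.at(va, faces[:, k], fa / 3.0)
    nrm = np.linalg.norm(vn, axis=1)
    vn /= np.where(nrm > 0, nrm, 1.0)[:, None]
    return vn, va


def mean_curvature(mesh: MembraneMesh) -> np.ndarray:
    """Per-vertex mean curvature kappa = (k1 + k2) / 2 (cotangent operator).

    Positive for a sphere with outward-oriented faces; converges to 1/R
    under refinement.
    """
    verts, faces = mesh.vertices, mesh.faces
    H = np.zeros_like(verts)
    va = np.zeros(len(verts))
    p = [verts[faces[:, k]] for k in range(3)]
    fa = 0.5 * np.linalg.norm(np.cross(p[1] - p[0], p[2] - p[0]), axis=1)
    for k in range(3):
        np.add.at(va, faces[:, k], fa / 3.0)
    for k in range(3):
        i, j, o = faces[:, k], faces[:, (k + 1) % 3], faces[:, (k + 2) % 3]
        # cotangent at the vertex opposite to edge (i, j)
        u = verts[i] - verts[o]
        v = verts[j] - verts[o]
        cot = np.einsum("ij,ij->i", u, v) / np.linalg.norm(np.cross(u, v), axis=1)
        w = 0.5 * cot
        d = verts[i] - verts[j]
        np.add.at(H, i, w[:, None] * d)
        np.add.at(H, j, -w[:, None] * d)
    # H = (1/(4A)) sum (cot a + cot b)(x_i - x_j), magnitude kappa = (k1+k2)/2
    H /= (2.0 * va)[:, None]
    vn, _ = vertex_normals_areas(verts, faces)
    return np.sign(np.einsum("ij,ij->i", H, vn)) * np.linalg.norm(H, axis=1)
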