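"""Triangulated lumen wall surfaces."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh


@dataclass
class WallSurface:
    """Triangulated microvascular wall with per-vertex vessel labels.

    Vertices in um.  ``vessel_label`` assigns each wall vertex to the
    nearest centerline (junction collars get label -1).  ``sdf`` is an
    optional analytic signed-distance callable for the same lumen
    (negative inside), used as the fast path for grid classification.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    vessel_label: np.ndarray | None = None
    sdf: object = None
    network: object = None
    _tm: trimesh.Trimesh | None = field(default=None, repr=False)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.triangles.max() >= len(self.vertices) or self.triangles.min() < 0:
            raise ValueError("triangle indices out of range")
        areas = self.face_areas()
        if np.any(areas <= 0):
            raise ValueError("surface has degenerate (zero-area) triangles")

    def face_areas(self) -> np.ndarray:
        p0 = self.vertices[self.triangles[:, 0]]
        p1 = self.vertices[self.triangles[:, 1]]
        p2 = self.vertices[self.triangles[:, 2]]
        return 0.5 * np.linalg.norm(np.cross(p1 - p0, p2 - p0), axis=1)

    def vertex_areas(self) -> np.ndarray:
        fa = self.face_areas()
        va = np.zeros(len(self.vertices))
        for k in range(3):
            np.add.at(va, self.triangles[:, k], fa / 3.0)
        return va

    def outward_normals(self) -> np.ndarray:
        """Per-vertex outward unit normals (area-weighted face normals)."""
        p0 = self.vertices[self.triangles[:, 0]]
        p1 = self.vertices[self.triangles[:, 1]]
        p2 = self.vertices[self.triangles[:, 2]]
        fn = np.cross(p1 - p0, p2 - p0)
        vn = np.zeros_like(self.vertices)
        for k in range(3):
            np.add.at(vn, self.triangles[:, k], fn)
        nrm = np.linalg.norm(vn, axis=1)
        return vn / np.where(nrm > 0, nrm, 1.0)[:, None]

    def as_trimesh(self) -> trimesh.Trimesh:
        if self._tm is None:
            self._tm = trimesh.Trimesh(
                vertices=self.vertices, faces=self.triangles, process=False
            )
        return self._tm

    def boundary_loops(self) -> int:
        """Number of open boundary loops (connected components of
        boundary edges); equals inlets + outlets for a lumen surface."""
        edges = {}
        for tri in self.triangles:
            for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
                key = (a, b) if a < b else (b, a)
                edges[key] = edges.get(key, 0) + 1
        boundary = [e for e, n in edges.items() if n == 1]
        if not boundary:
            return 0
        import networkx as nx  # lazy; only for loop counting

        g = nx.Graph()
        g.add_edges_from(boundary)
        return nx.number_connected_components(g)

    def euler_characteristic(self) -> int:
        edges = set()
        for tri in self.triangles:
            for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
                edges.add((a, b) if a < b else (b, a))
        used = np.unique(self.triangles)
        return int(len(used) - len(edges) + len(self.triangles))

    def export_stl(self, path, ascii_format: bool = False) -> None:
        tm = self.as_trimesh()
        if ascii_format:
            tm.export(path, file_type="stl_ascii")
        else:
            tm.export(path, file_type="stl")

    @classmethod
    def from_stl(cls, path) -> "WallSurface":
        tm = trimesh.load_mesh(path)
        return cls(np.asarray(tm.vertices), np.asarray(tm.faces))

    def mean_edge_length(self) -> float:
        e = self.vertices[self.triangles[:, [0, 1, 2]]] - self.vertices[self.triangles[:, [1, 2, 0]]]
        return float(np.linalg.norm(e, axis=2).mean())
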