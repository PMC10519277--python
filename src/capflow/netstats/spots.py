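"""TAWSS hot- and cold-spot detection on the wall mesh.

Spots are localized, concentrated regions of high or low TAWSS bounded by
steep surface gradients.  Vertices where the TAWSSG magnitude reaches the
threshold (default 10 dyne/cm^2/um) seed regions that are grown along
monotone TAWSS paths to the local extremum; seeds are classified hot or
cold by the sign of their TAWSS deviation from the vessel median, and the
resulting connected components are kept if they exceed a minimum area.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .vessels import JUNCTION_LABEL

HOT, COLD, NONE = 1, -1, 0


@dataclass
class SpotLabel:
    spot_class: np.ndarray  # per vertex: HOT / COLD / NONE
    spot_id: np.ndarray     # per vertex: component id or -1
    table: list             # per spot: dict(id, kind, area, mean_tawss, peak_vertex)


def _adjacency(surface):
    n = len(surface.vertices)
    nbr = [[] for _ in range(n)]
    for tri in surface.triangles:
        for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
            nbr[a].append(b)
            nbr[b].append(a)
    return [np.unique(x) for x in nbr]


def detect_spots(
    tawss,
    wssg,
    surface,
    threshold: float = 10.0,
    min_area: float = 1.0,
) -> SpotLabel:
    """Detect hot/cold spots from the TAWSS field and its gradients."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    field = np.asarray(getattr(tawss, "tawss", tawss))
    gmag = np.sqrt(np.asarray(wssg.axial) ** 2 + np.asarray(wssg.circ) ** 2)
    labels = surface.vessel_label
    if labels is None:
        labels = np.zeros(len(field), dtype=int)
    medians = {}
    for lab in set(labels.tolist()):
        medians[lab] = float(np.median(field[labels == lab]))
    med = np.array([medians[l] for l in labels])
    nbr = _adjacency(surface)
    seeds = np.flatnonzero(gmag >= threshold)
    marked_hot = np.zeros(len(field), dtype=bool)
    marked_cold = np.zeros(len(field), dtype=bool)
    for s in seeds:
        kind = HOT if field[s] >= med[s] else COLD
        marked = marked_hot if kind == HOT else marked_cold
        v = s
        marked[v] = True
        # greedy monotone walk to the local extremum
        for _ in range(len(field)):
            cand = nbr[v]
            if kind == HOT:
                nxt = cand[np.argmax(field[cand])]
                if field[nxt] <= field[v]:
                    break
            else:
                nxt = cand[np.argmin(field[cand])]
                if field[nxt] >= field[v]:
                    break
            v = nxt
            marked[v] = True

    spot_class = np.zeros(len(field), dtype=int)
    spot_id = np.full(len(field), -1, dtype=int)
    areas = surface.vertex_areas()
    table = []
    next_id = 0
    for kind, marked in ((HOT, marked_hot), (COLD, marked_cold)):
        # connected components within the marked set
        todo = set(np.flatnonzero(marked).tolist())
        while todo:
            start = todo.pop()
            comp = [start]
            stack = [start]
            while stack:
                v = stack.pop()
                for u in nbr[v]:
                    if u in todo:
                        todo.discard(u)
                        comp.append(u)
                        stack.append(u)
            comp = np.asarray(comp)
            area = float(areas[comp].sum())
            if area < min_area:
                continue
            spot_class[comp] = kind
            spot_id[comp] = next_id
            peak = comp[np.argmax(field[comp])] if kind == HOT else comp[np.argmin(field[comp])]
            table.append(
                {
                    "id": next_id,
                    "kind": "hot" if kind == HOT else "cold",
                    "area": area,
                    "mean_tawss": float(np.average(field[comp], weights=areas[comp])),
                    "peak_vertex": int(peak),
                }
            )
            next_id += 1
    return SpotLabel(spot_class, spot_id, table)
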