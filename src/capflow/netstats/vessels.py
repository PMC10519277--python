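"""Per-vessel aggregation of wall fields.

Wall vertices are grouped by their vessel label (nearest centerline;
junction collars carry label -1 and form a junction pseudo-vessel that is
excluded from per-vessel statistics).  All statistics are area-weighted
over the vessel's wall vertices; gradient entries aggregate absolute
values.  Vessel diameter is twice the area-weighted mean vertex-to-
centerline distance and vessel length the centerline arc length.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

JUNCTION_LABEL = -1
#: denominators below this floor (dyne/cm^2) are masked in ratio tables
RATIO_FLOOR = 1e-3


def _weighted_stats(x, w):
    wsum = w.sum()
    mean = float(np.sum(w * x) / wsum)
    var = float(np.sum(w * (x - mean) ** 2) / wsum)
    return mean, float(x.max()), float(x.min()), np.sqrt(max(var, 0.0))


def vessel_aggregate(tawss, wssg, surface, min_vertices: int = 10) -> pd.DataFrame:
    """Area-weighted per-vessel statistics of TAWSS and TAWSSG.

    Returns a table indexed by vessel label with TAWSS mean/max/min/sigma
    (dyne/cm^2), mean absolute gradient components (dyne/cm^2/um),
    geometry columns, and a low-confidence flag for sparsely resolved
    vessels.
    """
    field = np.asarray(getattr(tawss, "tawss", tawss))
    labels = surface.vessel_label
    if labels is None:
        raise ValueError("surface has no vessel labels")
    areas = surface.vertex_areas()
    rows = []
    for lab in sorted(set(labels.tolist())):
        if lab == JUNCTION_LABEL:
            continue
        m = labels == lab
        w = areas[m]
        mean, mx, mn, sd = _weighted_stats(field[m], w)
        row = {
            "vessel": lab,
            "n_vertices": int(m.sum()),
            "surface_area": float(w.sum()),
            "tawss_mean": mean,
            "tawss_max": mx,
            "tawss_min": mn,
            "tawss_sigma": sd,
            "low_confidence": bool(m.sum() < min_vertices),
        }
        if wssg is not None:
            row["tawssg_axial"] = float(np.sum(w * np.abs(wssg.axial[m])) / w.sum())
            row["tawssg_circ"] = float(np.sum(w * np.abs(wssg.circ[m])) / w.sum())
        if getattr(surface, "network", None) is not None:
            c = surface.network.by_label(lab)
            d = c.sdf(surface.vertices[m]) + _local_radius(c, surface.vertices[m])
            row["diameter"] = float(2.0 * np.sum(w * d) / w.sum())
            row["length"] = c.length
        rows.append(row)
    df = pd.DataFrame(rows).set_index("vessel")
    return df


def _local_radius(centerline, pts):
    """Radius of the centerline at the closest point to each query."""
    cl = centerline.resample(0.25)
    from scipy.spatial import cKDTree

    _, idx = cKDTree(cl.points).query(np.atleast_2d(pts))
    return cl.radii[idx]


def relative_histogram(tawss, areas, labels, bins: int = 9):
    """Per-vessel nine-bin area histograms of TAWSS, averaged over vessels.

    For each vessel the bin edges span its own [min, max] TAWSS uniformly,
    so the first and last bins correspond to that vessel's low and high
    TAWSS extremes.  Returns (average_fractions, per_vessel dict); each
    vessel's fractions sum to 1.  Degenerate vessels (max == min) are
    excluded and logged.
    """
    field = np.asarray(getattr(tawss, "tawss", tawss))
    per_vessel = {}
    for lab in sorted(set(np.asarray(labels).tolist())):
        if lab == JUNCTION_LABEL:
            continue
        m = np.asarray(labels) == lab
        f, w = field[m], np.asarray(areas)[m]
        lo, hi = f.min(), f.max()
        if hi <= lo:
            warnings.warn(f"vessel {lab} has uniform TAWSS; excluded from histogram")
            continue
        edges = np.linspace(lo, hi, bins + 1)
        idx = np.clip(np.searchsorted(edges, f, side="right") - 1, 0, bins - 1)
        frac = np.bincount(idx, weights=w, minlength=bins) / w.sum()
        per_vessel[lab] = frac
    if not per_vessel:
        raise ValueError("no vessel with a nondegenerate TAWSS range")
    avg = np.mean(np.vstack(list(per_vessel.values())), axis=0)
    return avg, per_vessel


def compare_runs(stats_a: pd.DataFrame, stats_b: pd.DataFrame, mode: str) -> pd.DataFrame:
    """Elementwise per-vessel ratios between two runs (A over B).

    mode "rbc_vs_plasma": A is the RBC-resolved run, B the plasma-only
    run; TAWSS ratios plus the gradient ratios alpha = TAWSSG_RBC /
    TAWSSG_plasma per component and their circ/axial quotient.
    mode "gamma_scaling": A is the scaled-drive run, B the baseline.
    Denominators below the floor are masked (NaN).
    """
    if mode not in ("rbc_vs_plasma", "gamma_scaling"):
        raise ValueError("mode must be rbc_vs_plasma or gamma_scaling")
    if not stats_a.index.equals(stats_b.index):
        raise ValueError("vessel label mismatch between runs")
    out = pd.DataFrame(index=stats_a.index)
    for col in ("tawss_mean", "tawss_max", "tawss_min", "tawss_sigma"):
        den = stats_b[col].where(stats_b[col].abs() > RATIO_FLOOR)
        out[f"ratio_{col.removeprefix('tawss_')}"] = stats_a[col] / den
    if "tawssg_axial" in stats_a and "tawssg_axial" in stats_b:
        for comp in ("axial", "circ"):
            den = stats_b[f"tawssg_{comp}"].where(
                stats_b[f"tawssg_{comp}"].abs() > RATIO_FLOOR
            )
            out[f"alpha_{comp}"] = stats_a[f"tawssg_{comp}"] / den
        out["alpha_circ_over_axial"] = out["alpha_circ"] / out["alpha_axial"]
    return out
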