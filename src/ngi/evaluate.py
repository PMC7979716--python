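"""Scoring the analysis pipeline against synthetic-slide ground truth."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree


def match_cells(truth: pd.DataFrame, detected: pd.DataFrame,
                max_dist_um: float = 4.0) -> pd.DataFrame:
    """Greedy mutual-nearest matching of detections to ground-truth cells.

    Returns the matched pairs with ``*_true`` columns from the truth table;
    each truth cell and each detection is used at most once.
    """
    if len(truth) == 0 or len(detected) == 0:
        return pd.DataFrame()
    t_xy = truth[["x_um", "y_um"]].to_numpy()
    d_xy = detected[["x_um", "y_um"]].to_numpy()
    tree = cKDTree(t_xy)
    dist, idx = tree.query(d_xy, distance_upper_bound=max_dist_um)
    order = np.argsort(dist)
    used_t, used_d = set(), set()
    pairs = []
    for di in order:
        ti = idx[di]
        if not np.isfinite(dist[di]) or ti >= len(truth):
            continue
        if ti in used_t or di in used_d:
            continue
        used_t.add(ti)
        used_d.add(di)
        pairs.append((di, ti, dist[di]))
    if not pairs:
        return pd.DataFrame()
    d_idx, t_idx, dists = zip(*pairs)
    out = detected.iloc[list(d_idx)].reset_index(drop=True)
    tr = truth.iloc[list(t_idx)].reset_index(drop=True)
    out = out.join(tr.add_suffix("_true"))
    out["match_dist_um"] = list(dists)
    return out


def phenotype_accuracy(matched: pd.DataFrame) -> float:
    """Fraction of matched cells whose called phenotype equals the truth."""
    if len(matched) == 0:
        return 0.0
    return float((matched["phenotype"] == matched["phenotype_true"]).mean())


def zone_agreement(matched: pd.DataFrame) -> float:
    """Fraction of matched cells whose zone label equals the truth."""
    if len(matched) == 0:
        return 0.0
    return float((matched["zone"] == matched["zone_true"]).mean())


def density_relative_errors(truth: pd.DataFrame, truth_areas,
                            metrics) -> pd.DataFrame:
    """Per-marker per-zone relative density error of measured vs truth.

    Truth densities come from the ground-truth cell table and the true zone
    areas; measured densities from :class:`~ngi.metrics.SampleMetrics`.
    """
    rows = []
    for m in ("CD3", "CD4", "CD8", "Foxp3"):
        pos = truth[truth[m]]
        for zone in ("A", "B", "C", "total"):
            if zone == "total":
                true_n = len(pos)
                area = truth_areas.roi_area_um2
            else:
                true_n = int((pos["zone"] == zone).sum())
                area = truth_areas.area_um2[zone]
            true_d = None if area <= 0 else true_n / (area / 1e6)
            meas_d = metrics.density[m][zone]
            if true_d in (None, 0) or meas_d is None:
                rel = None
            else:
                rel = (meas_d - true_d) / true_d
            rows.append({"marker": m, "zone": zone, "true_density": true_d,
                         "measured_density": meas_d, "rel_error": rel})
    return pd.DataFrame(rows)


def ki67_fraction_errors(truth: pd.DataFrame, metrics) -> pd.DataFrame:
    """Per-marker per-zone Ki67+ percentage error (points) vs ground truth."""
    rows = []
    for m in ("CD3", "CD4", "CD8", "Foxp3"):
        pos = truth[truth[m]]
        for zone in ("A", "B", "C", "total"):
            sub = pos if zone == "total" else pos[pos["zone"] == zone]
            true_pct = None if len(sub) == 0 else 100.0 * sub["Ki67"].mean()
            meas_pct = metrics.pct_ki67[m][zone]
            err = (None if true_pct is None or meas_pct is None
                   else meas_pct - true_pct)
            rows.append({"marker": m, "zone": zone, "true_pct": true_pct,
                         "measured_pct": meas_pct, "error_points": err})
    return pd.DataFrame(rows)
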