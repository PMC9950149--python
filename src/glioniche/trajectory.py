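"""Spatial invasion trajectories: spot capture along a drawn polyline,
binned expression trends, and peak-template classification.

Spots within half the corridor width of a user-drawn polyline are ordered by
their projected arc length. Gene expression is averaged in equal arc-length
bins, min-max normalized, and classified against unit-peak templates
(Gaussian bumps centered early / mid / late along the path) by maximal
Pearson correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point

logger = logging.getLogger(__name__)

TEMPLATE_CENTERS = {"early_peak": 0.15, "one_peak": 0.5, "late_peak": 0.85}
TEMPLATE_SIGMA = 0.15


@dataclass
class Trajectory:
    barcodes: list[str]  # ordered by arc-length position
    positions: pd.Series  # spot -> arc length along the polyline
    width: float
    length: float


@dataclass
class TrendCurves:
    curves: pd.DataFrame  # genes x bins, min-max normalized to [0, 1]
    centers: np.ndarray  # normalized bin centers in [0, 1]
    constant: pd.Series  # genes flagged constant (excluded from classification)


def build_trajectory(coords: pd.DataFrame, polyline, width: float = 90.0) -> Trajectory:
    """Capture spots within ``width/2`` of the polyline, ordered by projected
    arc length (ties broken by perpendicular distance)."""
    polyline = [tuple(p) for p in polyline]
    if len(polyline) < 2:
        raise ValueError("polyline needs at least two points")
    line = LineString(polyline)
    rows = []
    for barcode, (x, y) in coords[["x", "y"]].iterrows():
        p = Point(x, y)
        d = line.distance(p)
        if d <= width / 2.0:
            rows.append((barcode, line.project(p), d))
    if not rows:
        raise ValueError("no spot within the trajectory corridor")
    rows.sort(key=lambda t: (t[1], t[2]))
    positions = pd.Series({b: pos for b, pos, _ in rows}, name="position")
    positions = positions.loc[[b for b, _, _ in rows]]
    return Trajectory(
        barcodes=[b for b, _, _ in rows],
        positions=positions,
        width=width,
        length=float(line.length),
    )


def fit_trends(expr: pd.DataFrame, trajectory: Trajectory, n_bins: int = 20) -> TrendCurves:
    """Per-gene mean expression in equal arc-length bins, min-max normalized.

    Empty bins are merged into their populated neighbors (logged); constant
    genes are flagged and left out of classification.
    """
    if len(trajectory.barcodes) < n_bins:
        raise ValueError("trajectory has fewer spots than bins")
    pos = trajectory.positions.to_numpy()
    span = pos.max() - pos.min()
    if span <= 0:
        raise ValueError("degenerate trajectory: all spots project to one point")
    rel = (pos - pos.min()) / span
    bins = np.minimum((rel * n_bins).astype(int), n_bins - 1)
    occupied = np.unique(bins)
    if len(occupied) < n_bins:
        logger.info("%d empty bins merged with neighbors", n_bins - len(occupied))
    X = np.asarray(expr.loc[:, trajectory.barcodes], dtype=float)
    means = np.column_stack([X[:, bins == b].mean(axis=1) for b in occupied])
    centers = np.array([rel[bins == b].mean() for b in occupied])
    lo = means.min(axis=1, keepdims=True)
    hi = means.max(axis=1, keepdims=True)
    rng_ = hi - lo
    constant = rng_[:, 0] < 1e-12
    curves = np.where(constant[:, None], 0.0, (means - lo) / np.where(rng_ == 0, 1.0, rng_))
    return TrendCurves(
        curves=pd.DataFrame(curves, index=expr.index, columns=[f"bin{int(b)}" for b in occupied]),
        centers=centers,
        constant=pd.Series(constant, index=expr.index, name="constant"),
    )


def peak_templates(centers: np.ndarray, sigma: float = TEMPLATE_SIGMA) -> pd.DataFrame:
    """Unit-maximum Gaussian peak templates evaluated at normalized bin centers."""
    return pd.DataFrame(
        {name: np.exp(-0.5 * ((centers - mu) / sigma) ** 2) for name, mu in TEMPLATE_CENTERS.items()}
    )


def classify_trends(
    trends: TrendCurves,
    templates: pd.DataFrame | None = None,
    r_min: float = 0.5,
) -> pd.DataFrame:
    """Label each non-constant gene with the best-correlated peak template
    (if its Pearson r reaches ``r_min``), else ``none``."""
    if templates is None:
        templates = peak_templates(trends.centers)
    C = trends.curves.to_numpy()
    T = templates.to_numpy()
    Cc = C - C.mean(axis=1, keepdims=True)
    Tc = T - T.mean(axis=0, keepdims=True)
    denom = np.sqrt((Cc**2).sum(axis=1))[:, None] * np.sqrt((Tc**2).sum(axis=0))[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        R = (Cc @ Tc) / denom
    R = np.nan_to_num(R, nan=-np.inf)
    best = np.argmax(R, axis=1)
    best_r = R[np.arange(len(R)), best]
    labels = np.where(
        trends.constant.to_numpy() | (best_r < r_min),
        "none",
        templates.columns.to_numpy()[best],
    )
    peak_bin = np.argmax(C, axis=1)
    return pd.DataFrame(
        {"label": labels, "r": np.where(np.isfinite(best_r), best_r, np.nan), "peak_bin": peak_bin},
        index=trends.curves.index,
    )


def intersect_signature(one_peak_genes, signature) -> list[str]:
    """Sorted exact intersection of two gene sets."""
    return sorted(set(one_peak_genes) & set(signature))
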