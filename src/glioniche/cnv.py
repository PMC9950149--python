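"""Moving-average copy-number scoring and CNV-based tumor-content estimation.

The score for each spot and gene window is the chromosome-wise moving average
(window of 100 analyzed genes by default) of log expression relative to a
normal reference, median-centered per spot and rescaled into [0.7, 1.3]
(scores < 1 mark chromosomal loss, > 1 gain). Contiguous regions whose mean
score in candidate tumor spots exceeds 1.2 (gain) or falls below 0.8 (loss)
are designated tumor signature CNV events; the per-spot mean score over an
event region, A_CNV, yields the tumor content

    C_i = (A_CNVi - 1) / (max(A_CNV) - 1)        for a gain,
    C_i = (1 - A_CNVi) / (1 - min(A_CNV))        for a loss,

clipped to [0, 1]; a spot is called malignant when C > 0.2. A consensus over
at least three events (per-spot median) guards against single-event noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

MALIGNANT_CUTOFF = 0.2
GAIN_THRESHOLD = 1.2
LOSS_THRESHOLD = 0.8


@dataclass
class CNVProfile:
    """Spot-by-gene-window matrix of rescaled CNV scores in [0.7, 1.3]."""

    scores: pd.DataFrame  # spots x gene windows (genes ordered by chrom, start)
    gene_order: pd.DataFrame  # chrom, start per window, in column order
    reference_spots: list[str]
    window: int

    def chromosome_slice(self, chrom: str) -> np.ndarray:
        return np.flatnonzero((self.gene_order["chrom"] == chrom).to_numpy())


@dataclass(frozen=True)
class SignatureEvent:
    """A contiguous gene-window span called as a tumor signature CNV event."""

    chrom: str
    start_index: int  # inclusive, positional in profile column order
    end_index: int  # exclusive
    direction: str  # "gain" | "loss"
    candidate_mean: float

    @property
    def n_windows(self) -> int:
        return self.end_index - self.start_index


@dataclass
class TumorContent:
    """Per-spot event-region score A_CNV, tumor content C, malignant flag."""

    a_cnv: pd.Series
    content: pd.Series
    malignant: pd.Series
    event: SignatureEvent


def moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average truncated at the array boundaries.

    ``out[i]`` is the mean of ``values[max(0, i-h) : i+h']`` covering at most
    ``window`` elements centered on ``i`` (h = window // 2). Operates on the
    last axis.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    values = np.asarray(values, dtype=float)
    n = values.shape[-1]
    window = min(window, n)
    h_left = window // 2
    h_right = window - 1 - h_left
    csum = np.cumsum(values, axis=-1)
    csum = np.concatenate([np.zeros(values.shape[:-1] + (1,)), csum], axis=-1)
    i = np.arange(n)
    lo = np.maximum(i - h_left, 0)
    hi = np.minimum(i + h_right + 1, n)
    return (csum[..., hi] - csum[..., lo]) / (hi - lo)


def infer_cnv(
    expr: pd.DataFrame,
    annotation: pd.DataFrame,
    reference_spots,
    window: int = 100,
    saturation: float = 0.3,
) -> CNVProfile:
    """Estimate per-spot CNV scores from log-normalized expression.

    Per spot: log expression minus the reference mean, smoothed by a
    centered moving average of ``window`` genes within each chromosome,
    median-centered per spot, and mapped into [0.7, 1.3] by a two-sided
    linear rescale that saturates at +/- ``saturation`` on the smoothed
    log scale (1.0 is anchored at the reference mean).
    """
    reference_spots = [s for s in reference_spots]
    if len(reference_spots) == 0:
        raise ValueError("reference spot set must not be empty")
    missing = set(reference_spots) - set(expr.columns)
    if missing:
        raise ValueError(f"reference spots absent from expression matrix: {sorted(missing)[:5]}")
    ann = annotation.reindex(expr.index)
    if ann[["chrom", "start"]].isna().any().any():
        raise ValueError("annotation must cover all genes (chrom, start)")

    chrom_key = ann["chrom"].astype(str)
    # natural chromosome order: numeric part when present, else lexicographic
    def _chrom_rank(c: str):
        digits = "".join(ch for ch in c if ch.isdigit())
        return (0, int(digits)) if digits else (1, c)

    chrom_order = sorted(chrom_key.unique(), key=_chrom_rank)
    order = np.lexsort((ann["start"].to_numpy(), chrom_key.map({c: i for i, c in enumerate(chrom_order)}).to_numpy()))
    genes_sorted = expr.index[order]
    ann_sorted = ann.iloc[order]

    mat = np.asarray(expr, dtype=float)[order]  # genes x spots
    ref_mean = mat[:, expr.columns.isin(reference_spots)].mean(axis=1)
    rel = (mat - ref_mean[:, None]).T  # spots x genes

    smooth = np.empty_like(rel)
    for chrom in chrom_order:
        cols = np.flatnonzero((ann_sorted["chrom"] == chrom).to_numpy())
        w = window
        if len(cols) < window:
            warnings.warn(
                f"{chrom} has {len(cols)} genes < window {window}; window shrunk to chromosome length"
            )
            w = len(cols)
        smooth[:, cols] = moving_average(rel[:, cols], w)
    smooth -= np.median(smooth, axis=1, keepdims=True)
    scores = 1.0 + 0.3 * np.clip(smooth / saturation, -1.0, 1.0)

    return CNVProfile(
        scores=pd.DataFrame(scores, index=expr.columns, columns=genes_sorted),
        gene_order=ann_sorted,
        reference_spots=reference_spots,
        window=window,
    )


def default_candidate_spots(profile: CNVProfile, fraction: float = 0.1) -> list[str]:
    """Automatic surrogate for histology-guided tumor candidates: the top
    ``fraction`` of spots by total absolute CNV deviation."""
    dev = np.abs(np.asarray(profile.scores) - 1.0).sum(axis=1)
    k = max(1, int(np.ceil(fraction * len(dev))))
    idx = np.argsort(dev)[::-1][:k]
    return list(profile.scores.index[idx])


def designate_signature_events(
    profile: CNVProfile,
    candidate_spots=None,
    min_region_windows: int = 10,
) -> list[SignatureEvent]:
    """Maximal contiguous regions whose candidate-spot mean score crosses the
    gain (>1.2) or loss (<0.8) threshold, per chromosome."""
    if candidate_spots is None:
        candidate_spots = default_candidate_spots(profile)
    candidate_spots = [s for s in candidate_spots]
    unknown = set(candidate_spots) - set(profile.scores.index)
    if unknown:
        raise ValueError(f"candidate spots not in profile: {sorted(unknown)[:5]}")
    mean = profile.scores.loc[candidate_spots].mean(axis=0).to_numpy()
    chroms = profile.gene_order["chrom"].to_numpy()
    events: list[SignatureEvent] = []
    for chrom in dict.fromkeys(chroms):
        cols = np.flatnonzero(chroms == chrom)
        for direction, mask in (
            ("gain", mean[cols] > GAIN_THRESHOLD),
            ("loss", mean[cols] < LOSS_THRESHOLD),
        ):
            edges = np.diff(np.concatenate([[0], mask.view(np.int8), [0]]))
            for s, e in zip(np.flatnonzero(edges == 1), np.flatnonzero(edges == -1)):
                if e - s >= min_region_windows:
                    lo, hi = cols[s], cols[e - 1] + 1
                    events.append(
                        SignatureEvent(
                            chrom=chrom,
                            start_index=int(lo),
                            end_index=int(hi),
                            direction=direction,
                            candidate_mean=float(mean[lo:hi].mean()),
                        )
                    )
    return events


def tumor_content(profile: CNVProfile, event: SignatureEvent) -> TumorContent:
    """Direction-specific tumor content from the event-region mean score."""
    if not 0 <= event.start_index < event.end_index <= profile.scores.shape[1]:
        raise ValueError("event region outside profile")
    a = profile.scores.iloc[:, event.start_index : event.end_index].mean(axis=1)
    if event.direction == "gain":
        denom = a.max() - 1.0
        if denom <= 1e-12:
            raise ValueError("no signal in event region: max(A_CNV) = 1 for a gain event")
        c = (a - 1.0) / denom
    elif event.direction == "loss":
        denom = 1.0 - a.min()
        if denom <= 1e-12:
            raise ValueError("no signal in event region: min(A_CNV) = 1 for a loss event")
        c = (1.0 - a) / denom
    else:
        raise ValueError(f"unknown event direction {event.direction!r}")
    c = c.clip(0.0, 1.0)
    return TumorContent(a_cnv=a, content=c, malignant=c > MALIGNANT_CUTOFF, event=event)


def robust_content(profile: CNVProfile, events: list[SignatureEvent]) -> tuple[pd.Series, pd.DataFrame]:
    """Consensus per-spot tumor content: median of per-event C values.

    Returns the consensus series and the per-event Spearman concordance
    matrix. Fewer than three events triggers a warning (the estimate is then
    less robust) but the available events are still used.
    """
    if len(events) == 0:
        raise ValueError("need at least one signature event")
    if len(events) < 3:
        warnings.warn(f"only {len(events)} signature events; consensus is less robust")
    per_event = pd.DataFrame(
        {f"{e.chrom}:{e.direction}:{i}": tumor_content(profile, e).content for i, e in enumerate(events)}
    )
    consensus = per_event.median(axis=1)
    consensus.name = "tumor_content"
    if per_event.shape[1] == 2:
        r = stats.spearmanr(per_event.iloc[:, 0], per_event.iloc[:, 1]).statistic
        rho = np.array([[1.0, r], [r, 1.0]])
    elif per_event.shape[1] > 2:
        rho = stats.spearmanr(per_event.to_numpy()).statistic
    else:
        rho = np.ones((1, 1))
    concordance = pd.DataFrame(rho, index=per_event.columns, columns=per_event.columns)
    return consensus, concordance


def mutation_colocalization(
    variant_counts: pd.DataFrame, malignant_mask: pd.Series
) -> tuple[float, pd.DataFrame]:
    """Colocalization of variant-positive spots (mutant reads >= 1) with
    CNV-called malignant spots: 2x2 table and the fraction of variant-positive
    spots that are malignant (NaN when no spot is variant-positive)."""
    mask = malignant_mask.reindex(variant_counts.index).fillna(False).astype(bool)
    positive = variant_counts["mutant"] >= 1
    table = pd.crosstab(
        positive.map({True: "variant+", False: "variant-"}),
        mask.map({True: "malignant", False: "non-malignant"}),
    ).reindex(index=["variant+", "variant-"], columns=["malignant", "non-malignant"], fill_value=0)
    n_pos = int(positive.sum())
    fraction = float((positive & mask).sum() / n_pos) if n_pos else float("nan")
    return fraction, table
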