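"""Meta-module discovery: signature scoring, three integration strategies,
partition comparison, and niche assignment.

Cluster signatures from all samples are scored per spot with a control-bin
gene-set score (mean expression of the set minus the mean of expression-
matched control genes). Signatures are then integrated into meta-modules by
hierarchical clustering (average linkage, distance 1 - Pearson r) of a
signature-by-signature correlation matrix computed three ways: over spots,
over cluster pseudobulks, or as a spatially (Gaussian-kernel) weighted local
correlation averaged over spots and samples. Each spot's niche is the
meta-module with the highest z-normalized score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

Partition = dict[str, int]


@dataclass
class ModuleAssignment:
    """Partition of signatures into meta-modules plus per-spot niche calls."""

    partition: Partition  # signature name -> module id (1..k)
    module_scores: pd.DataFrame  # spots x modules (z-normalized)
    niche_labels: pd.Series  # spot -> module id


def module_score(
    expr: pd.DataFrame,
    gene_set,
    n_bins: int = 24,
    n_control: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Control-bin gene-set score per spot.

    Genes are binned by their average expression; for every gene of the set,
    ``n_control`` control genes are drawn from its bin, and the score is the
    mean expression of the set minus the mean expression of the pooled
    controls. Deterministic given ``seed``.
    """
    gene_set = list(dict.fromkeys(gene_set))
    present = [g for g in gene_set if g in expr.index]
    if not present:
        raise ValueError(f"gene set entirely absent from matrix: {gene_set[:5]} ...")
    rng = np.random.default_rng(seed)
    mat = np.asarray(expr, dtype=float)
    avg = mat.mean(axis=1)
    order = np.argsort(avg, kind="mergesort")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(len(avg))
    bins = np.minimum((ranks * n_bins) // len(avg), n_bins - 1)

    gene_pos = {g: i for i, g in enumerate(expr.index)}
    set_idx = np.array([gene_pos[g] for g in present])
    control_idx = []
    for gi in set_idx:
        pool = np.flatnonzero(bins == bins[gi])
        control_idx.append(rng.choice(pool, size=n_control, replace=len(pool) < n_control))
    control_idx = np.concatenate(control_idx)
    score = mat[set_idx].mean(axis=0) - mat[control_idx].mean(axis=0)
    return pd.Series(score, index=expr.columns, name="score")


def score_signatures(
    expr: pd.DataFrame, signatures, n_bins: int = 24, n_control: int = 100, seed: int = 0
) -> pd.DataFrame:
    """Spot-by-signature matrix of control-bin scores."""
    return pd.DataFrame(
        {sig.name: module_score(expr, sig.genes, n_bins, n_control, seed) for sig in signatures}
    )


def _cut_correlation(corr: pd.DataFrame, k: int) -> Partition:
    """Average-linkage hierarchical clustering of 1 - r, cut at k modules."""
    if corr.isna().any().any():
        bad = corr.columns[corr.isna().any()].tolist()
        raise ValueError(f"undefined correlation (constant score column?) for {bad[:5]}")
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    labels = hierarchy.fcluster(link, t=k, criterion="maxclust")
    return {name: int(lab) for name, lab in zip(corr.columns, labels)}


def integrate_spotlevel(scores: pd.DataFrame, k: int = 4) -> Partition:
    """Method 1: Pearson correlation of signature scores over spots."""
    if scores.shape[1] < k:
        raise ValueError(f"need at least {k} signatures, got {scores.shape[1]}")
    stds = scores.std(axis=0)
    if (stds == 0).any():
        raise ValueError(f"constant score column(s): {list(scores.columns[stds == 0])}")
    return _cut_correlation(scores.corr(method="pearson"), k)


def integrate_pseudobulk(
    exprs: dict[str, pd.DataFrame],
    labels: dict[str, pd.Series],
    signatures,
    k: int = 4,
    seed: int = 0,
) -> Partition:
    """Method 2: signatures scored on per-cluster pseudobulk mean expression."""
    bulks = {}
    for sample_id, expr in exprs.items():
        lab = labels[sample_id].reindex(expr.columns)
        for c in sorted(lab.dropna().unique()):
            bulks[f"{sample_id}:c{int(c)}"] = np.asarray(expr.loc[:, (lab == c).to_numpy()]).mean(axis=1)
    any_expr = next(iter(exprs.values()))
    bulk_mat = pd.DataFrame(bulks, index=any_expr.index)
    scores = score_signatures(bulk_mat, signatures, seed=seed)
    return integrate_spotlevel(scores, k=k)


def gwr_correlation(
    scores: pd.DataFrame,
    coords: pd.DataFrame,
    bandwidth_k: float = 0.1,
    bandwidth: float | None = None,
) -> pd.DataFrame:
    """Spatially weighted signature-signature correlation for one sample.

    At each spot, a local Pearson correlation matrix is computed with
    Gaussian kernel weights whose adaptive bandwidth is the distance to the
    ``ceil(bandwidth_k * n)``-th nearest neighbor (or the fixed ``bandwidth``
    distance when given); local matrices are averaged over spots. As the
    bandwidth grows the result converges to the global Pearson correlation.
    """
    S = np.asarray(scores, dtype=float)
    n, p = S.shape
    xy = coords[["x", "y"]].to_numpy()
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
    if bandwidth is not None:
        bw = np.full(n, float(bandwidth))
    else:
        m = min(max(int(np.ceil(bandwidth_k * n)), 1), n - 1)
        bw = np.sort(d, axis=1)[:, m]
    bw = np.maximum(bw, 1e-12)
    acc = np.zeros((p, p))
    for i in range(n):
        w = np.exp(-0.5 * (d[i] / bw[i]) ** 2)
        w = w / w.sum()
        mu = w @ S
        Xc = (S - mu) * np.sqrt(w)[:, None]
        cov = Xc.T @ Xc
        sd = np.sqrt(np.diag(cov))
        acc += cov / np.outer(sd, sd)
    return pd.DataFrame(acc / n, index=scores.columns, columns=scores.columns)


def integrate_gwr(
    scores_per_sample: dict[str, pd.DataFrame],
    coords_per_sample: dict[str, pd.DataFrame],
    bandwidth_k: float = 0.1,
    k: int = 4,
    min_spots: int = 10,
) -> Partition:
    """Method 3: per-sample spatially weighted correlations, averaged across
    samples, then clustered."""
    mats = []
    for sample_id, scores in scores_per_sample.items():
        if scores.shape[0] < min_spots:
            logger.warning("sample %s has < %d spots; excluded from GWR", sample_id, min_spots)
            continue
        mats.append(gwr_correlation(scores, coords_per_sample[sample_id], bandwidth_k))
    if not mats:
        raise ValueError("no sample large enough for spatially weighted correlation")
    mean_corr = sum(m.to_numpy() for m in mats) / len(mats)
    corr = pd.DataFrame(mean_corr, index=mats[0].index, columns=mats[0].columns)
    return _cut_correlation(corr, k)


def jaccard_partitions(p1: Partition, p2: Partition) -> float:
    """Pair-counting Jaccard index between two partitions of the same universe."""
    if set(p1) != set(p2):
        raise ValueError("partitions must cover the same elements")
    items = sorted(p1)
    both = either = 0
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            a = p1[items[i]] == p1[items[j]]
            b = p2[items[i]] == p2[items[j]]
            both += a and b
            either += a or b
    if either == 0:
        return 1.0  # two all-singleton partitions are identical
    return both / either


def module_gene_sets(partition: Partition, signatures) -> dict[int, list[str]]:
    """Union of member-signature genes per meta-module."""
    by_name = {sig.name: sig for sig in signatures}
    out: dict[int, list[str]] = {}
    for name, mod in sorted(partition.items()):
        out.setdefault(mod, [])
        out[mod].extend(g for g in by_name[name].genes if g not in out[mod])
    return dict(sorted(out.items()))


def assign_niches(
    expr: pd.DataFrame,
    gene_sets: dict[int, list[str]],
    n_bins: int = 24,
    n_control: int = 100,
    seed: int = 0,
) -> ModuleAssignment:
    """Score each module's gene set per spot, z-normalize across spots, and
    label each spot with its highest-scoring module (ties go to the first
    module in canonical order and are logged)."""
    if len(gene_sets) < 2:
        raise ValueError("need at least two modules to assign niches")
    for mod, genes in gene_sets.items():
        if not genes:
            raise ValueError(f"module {mod} has an empty gene set")
    raw = pd.DataFrame(
        {mod: module_score(expr, genes, n_bins, n_control, seed) for mod, genes in sorted(gene_sets.items())}
    )
    z = (raw - raw.mean(axis=0)) / raw.std(axis=0).replace(0.0, np.nan)
    if z.isna().any().any():
        raise ValueError("constant module score; cannot z-normalize")
    arr = z.to_numpy()
    best = np.argmax(arr, axis=1)
    ties = (arr == arr[np.arange(len(arr)), best][:, None]).sum(axis=1) > 1
    if ties.any():
        logger.info("%d spots had tied module scores; first module in order kept", int(ties.sum()))
    labels = pd.Series([z.columns[b] for b in best], index=expr.columns, name="niche")
    return ModuleAssignment(partition={}, module_scores=z, niche_labels=labels)
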