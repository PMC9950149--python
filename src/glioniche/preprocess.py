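"""Spot QC, normalization, spatially informed clustering, and marker signatures.

Clustering follows the neighborhood-augmentation idea used for spatial
transcriptomics: each spot is represented by its own expression principal
components concatenated with the principal components of its spatial
neighbors' mean expression, weighted ``sqrt(1-lambda)`` / ``sqrt(lambda)``,
and the augmented features are clustered with Leiden on a kNN graph. With
``lambda_mix = 0`` this reduces to purely transcriptional clustering.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)

_LOG2FC_EPS = 1e-9


@dataclass
class QCMask:
    """Per-spot QC metrics; ``passed`` iff detected genes >= min_genes and
    mitochondrial fraction <= max_mito."""

    metrics: pd.DataFrame  # n_genes, mito_fraction, passed
    min_genes: int
    max_mito: float

    @property
    def passed(self) -> pd.Series:
        return self.metrics["passed"]


@dataclass
class ClusterSignature:
    """Top marker genes of one spatially informed cluster (<= 50 genes,
    sorted by descending log2 fold change)."""

    sample_id: str
    cluster_id: int
    markers: pd.DataFrame  # index gene; log2fc, p_adj
    n_significant: int

    @property
    def genes(self) -> list[str]:
        return list(self.markers.index)

    @property
    def name(self) -> str:
        return f"{self.sample_id}:c{self.cluster_id}"


def qc_filter(
    sample,
    mito_gene_prefix: str = "MT-",
    min_genes: int = 200,
    max_mito: float = 0.25,
) -> QCMask:
    """Flag low-quality spots: detected genes < min_genes OR mito fraction > max_mito.

    Both rules are strict in the failing direction: a spot with exactly
    ``min_genes`` detected genes and exactly ``max_mito`` mitochondrial
    fraction passes.
    """
    mat = np.asarray(sample.counts)
    n_genes = (mat > 0).sum(axis=0)
    mito_rows = sample.counts.index.str.startswith(mito_gene_prefix)
    totals = mat.sum(axis=0)
    if not mito_rows.any():
        logger.warning("no genes with prefix %r; mito fraction set to 0", mito_gene_prefix)
        mito_frac = np.zeros(mat.shape[1])
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_frac = np.where(totals > 0, mat[mito_rows].sum(axis=0) / np.maximum(totals, 1), 0.0)
    passed = (n_genes >= min_genes) & (mito_frac <= max_mito)
    metrics = pd.DataFrame(
        {"n_genes": n_genes, "mito_fraction": mito_frac, "passed": passed},
        index=sample.counts.columns,
    )
    return QCMask(metrics=metrics, min_genes=min_genes, max_mito=max_mito)


def lognormalize(counts: pd.DataFrame, scale: float = 1e4) -> pd.DataFrame:
    """Per-spot depth normalization: log(1 + scale * count / spot_total)."""
    totals = np.asarray(counts.sum(axis=0), dtype=float)
    if (totals == 0).any():
        bad = counts.columns[totals == 0]
        raise ValueError(f"zero-total spots must be filtered before normalization: {list(bad)[:5]}")
    return pd.DataFrame(
        np.log1p(scale * np.asarray(counts, dtype=float) / totals),
        index=counts.index,
        columns=counts.columns,
    )


def spatial_cluster(
    expr: pd.DataFrame,
    coords: pd.DataFrame,
    lambda_mix: float = 0.2,
    k_neighbors: int = 6,
    n_pcs: int = 20,
    resolution: float = 0.3,
    seed: int = 0,
) -> pd.Series:
    """Leiden clustering of neighborhood-augmented expression features.

    Parameters follow the hex-lattice geometry: ``k_neighbors=6`` averages
    each spot's first hexagonal ring.
    """
    if not 0 <= lambda_mix <= 1:
        raise ValueError("lambda_mix must be in [0, 1]")
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    n_spots = expr.shape[1]
    if n_spots < k_neighbors + 1:
        raise ValueError("fewer spots than k_neighbors + 1")
    X = np.asarray(expr, dtype=float).T  # spots x genes
    xy = coords[["x", "y"]].to_numpy()
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(xy)
    _, idx = nn.kneighbors(xy)
    neigh_mean = X[idx[:, 1:]].mean(axis=1)

    k_pcs = min(n_pcs, n_spots - 1, X.shape[1])
    own = PCA(n_components=k_pcs, random_state=0).fit_transform(X)
    nbr = PCA(n_components=k_pcs, random_state=0).fit_transform(neigh_mean)
    feats = np.hstack([np.sqrt(1.0 - lambda_mix) * own, np.sqrt(lambda_mix) * nbr])

    import igraph as ig
    import leidenalg

    k_graph = min(15, n_spots - 1)
    adj = NearestNeighbors(n_neighbors=k_graph).fit(feats).kneighbors_graph(feats)
    sources, targets = adj.nonzero()
    edges = {(min(a, b), max(a, b)) for a, b in zip(sources.tolist(), targets.tolist()) if a != b}
    graph = ig.Graph(n=n_spots, edges=sorted(edges))
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    labels = np.asarray(part.membership)
    return pd.Series(labels, index=expr.columns, name="cluster")


def _log2fc(expr_in: np.ndarray, expr_out: np.ndarray) -> np.ndarray:
    """Seurat-convention fold change on log-normalized data."""
    mean_in = np.expm1(expr_in).mean(axis=1)
    mean_out = np.expm1(expr_out).mean(axis=1)
    return np.log2((mean_in + _LOG2FC_EPS) / (mean_out + _LOG2FC_EPS))


def find_markers(
    expr: pd.DataFrame,
    labels: pd.Series,
    sample_id: str = "sample",
    min_significant: int = 50,
    top_n: int = 50,
    min_log2fc: float = 0.25,
    max_p_adj: float = 0.05,
) -> list[ClusterSignature]:
    """One-vs-rest Wilcoxon marker detection per cluster, Seurat-style.

    Per cluster: rank-sum test for every gene, Benjamini-Hochberg adjustment,
    positive markers only; a gene is significant if log2FC > ``min_log2fc``
    and adjusted p < ``max_p_adj``. Clusters with fewer than
    ``min_significant`` significant genes are dropped; genes significant in
    more than one retained cluster are excluded from all of them; each
    signature keeps the top ``top_n`` genes by log2FC (ties broken by smaller
    adjusted p, then gene id).
    """
    labels = labels.reindex(expr.columns)
    uniq = [c for c in sorted(labels.dropna().unique())]
    if len(uniq) < 2:
        raise ValueError("need at least two clusters for marker detection")
    mat = np.asarray(expr, dtype=float)
    per_cluster: dict[int, pd.DataFrame] = {}
    for c in uniq:
        in_mask = (labels == c).to_numpy()
        if in_mask.sum() < 2:
            warnings.warn(f"cluster {c} has a single spot; excluded from marker detection")
            continue
        x_in, x_out = mat[:, in_mask], mat[:, ~in_mask]
        with np.errstate(all="ignore"):
            res = stats.mannwhitneyu(x_in, x_out, axis=1, alternative="two-sided")
        pvals = np.nan_to_num(res.pvalue, nan=1.0)
        p_adj = stats.false_discovery_control(pvals)
        lfc = _log2fc(x_in, x_out)
        sig = (lfc > min_log2fc) & (p_adj < max_p_adj)
        df = pd.DataFrame({"log2fc": lfc, "p_adj": p_adj, "significant": sig}, index=expr.index)
        per_cluster[c] = df

    retained = {c: df for c, df in per_cluster.items() if int(df["significant"].sum()) >= min_significant}
    # exclusion of markers shared by different clusters
    sig_sets = {c: set(df.index[df["significant"]]) for c, df in retained.items()}
    shared: set[str] = set()
    seen: set[str] = set()
    for genes in sig_sets.values():
        shared |= genes & seen
        seen |= genes
    signatures = []
    for c, df in retained.items():
        own = df[df["significant"] & ~df.index.isin(shared)].copy()
        own = own.sort_values(
            by=["log2fc", "p_adj"], ascending=[False, True], kind="mergesort"
        )
        own["_gene"] = own.index
        own = own.sort_values(
            by=["log2fc", "p_adj", "_gene"], ascending=[False, True, True], kind="mergesort"
        ).drop(columns=["_gene", "significant"])
        signatures.append(
            ClusterSignature(
                sample_id=sample_id,
                cluster_id=int(c),
                markers=own.head(top_n),
                n_significant=int(df["significant"].sum()),
            )
        )
    return signatures
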