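"""Isoform-level analysis: QC filters, percent spliced in (PSI), niche-wise
differential isoform enrichment, cross-sample conservation and switch genes,
and splicing-factor association.

PSI for an ordered isoform pair (IR, ER) of one host gene is IR/(IR + ER),
defined only in spots with at least 5 reads for the pair (raw counts).
Differentially expressed isoforms (DEIs) come from pairwise niche Wilcoxon
tests on normalized isoform expression with the thresholds p < 0.01,
|log2FC| > 0.1 and expressing-spot fraction > 0.1. A DEI is conserved when
the same (isoform, enriched niche) recurs in at least two samples, and a host
gene is an isoform-switch gene when at least two of its isoforms are
conserved DEIs with different niches.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import _log2fc
from .simulate import IsoformTable

logger = logging.getLogger(__name__)

DEI_MAX_P = 0.01
DEI_MIN_ABS_LOG2FC = 0.1
DEI_MIN_PCT = 0.1


@dataclass
class PSIMap:
    """Per-spot PSI for one ordered isoform pair; NaN where reads < threshold."""

    gene: str
    ir_isoform: str
    er_isoform: str
    psi: pd.Series
    min_reads: int


def filter_isoforms(
    table: IsoformTable, min_spots: int = 50, min_features: int = 100
) -> IsoformTable:
    """Remove isoforms detected in fewer than ``min_spots`` spots, then spots
    expressing fewer than ``min_features`` isoforms (strict < rules)."""
    mat = np.asarray(table.counts)
    keep_iso = (mat > 0).sum(axis=1) >= min_spots
    logger.info("isoform filter: %d/%d isoforms kept", int(keep_iso.sum()), len(keep_iso))
    mat = mat[keep_iso]
    keep_spot = (mat > 0).sum(axis=0) >= min_features
    logger.info("spot filter: %d/%d spots kept", int(keep_spot.sum()), len(keep_spot))
    counts = table.counts.loc[keep_iso, keep_spot]
    if counts.size == 0:
        raise ValueError(
            "no isoforms/spots survive filtering; relax min_spots/min_features"
        )
    return IsoformTable(counts=counts, gene_of=table.gene_of.loc[counts.index])


def compute_psi(
    table: IsoformTable,
    gene: str,
    iso_pair: tuple[str, str],
    min_reads: int = 5,
) -> PSIMap:
    """Exact PSI = IR/(IR+ER) per spot, NaN below the read threshold."""
    ir, er = iso_pair
    for iso in (ir, er):
        if iso not in table.counts.index:
            raise ValueError(f"isoform {iso!r} not in table")
        if table.gene_of.loc[iso] != gene:
            raise ValueError(f"isoform {iso!r} does not belong to gene {gene!r}")
    ir_counts = table.counts.loc[ir].astype(float)
    er_counts = table.counts.loc[er].astype(float)
    total = ir_counts + er_counts
    psi = (ir_counts / total).where(total >= min_reads)
    psi.name = "psi"
    return PSIMap(gene=gene, ir_isoform=ir, er_isoform=er, psi=psi, min_reads=min_reads)


def differential_isoforms(
    expr: pd.DataFrame,
    niche_labels: pd.Series,
    sample_id: str = "sample",
    max_p: float = DEI_MAX_P,
    min_abs_log2fc: float = DEI_MIN_ABS_LOG2FC,
    min_pct: float = DEI_MIN_PCT,
    min_spots_per_niche: int = 3,
) -> pd.DataFrame:
    """Pairwise niche Wilcoxon tests per isoform on normalized expression.

    Returns one record per (isoform, niche pair) passing all thresholds, with
    the enriched niche being the higher-mean side.
    """
    labels = niche_labels.reindex(expr.columns)
    niches = sorted(labels.dropna().unique(), key=str)
    usable = []
    for n in niches:
        if (labels == n).sum() < min_spots_per_niche:
            warnings.warn(f"niche {n} has < {min_spots_per_niche} spots; skipped")
        else:
            usable.append(n)
    if len(usable) < 2:
        raise ValueError("need at least two niches with enough spots")
    mat = np.asarray(expr, dtype=float)
    records = []
    for i in range(len(usable)):
        for j in range(i + 1, len(usable)):
            a, b = usable[i], usable[j]
            xa = mat[:, (labels == a).to_numpy()]
            xb = mat[:, (labels == b).to_numpy()]
            with np.errstate(all="ignore"):
                res = stats.mannwhitneyu(xa, xb, axis=1, alternative="two-sided")
            pvals = np.nan_to_num(res.pvalue, nan=1.0)
            lfc = _log2fc(xa, xb)
            enriched_a = lfc > 0
            pct = np.where(enriched_a, (xa > 0).mean(axis=1), (xb > 0).mean(axis=1))
            keep = (pvals < max_p) & (np.abs(lfc) > min_abs_log2fc) & (pct > min_pct)
            for idx in np.flatnonzero(keep):
                records.append(
                    {
                        "isoform": expr.index[idx],
                        "enriched_niche": a if enriched_a[idx] else b,
                        "contrast_niche": b if enriched_a[idx] else a,
                        "log2fc": abs(float(lfc[idx])),
                        "p": float(pvals[idx]),
                        "pct": float(pct[idx]),
                        "sample_id": sample_id,
                    }
                )
    return pd.DataFrame(
        records,
        columns=["isoform", "enriched_niche", "contrast_niche", "log2fc", "p", "pct", "sample_id"],
    )


def conserved_switches(
    records_per_sample: list[pd.DataFrame],
    gene_of: pd.Series,
    min_samples: int = 2,
) -> tuple[pd.DataFrame, list[str]]:
    """Cross-sample conservation of DEIs and isoform-switch genes.

    A (isoform, enriched niche) pair is conserved when it appears in at least
    ``min_samples`` samples; a host gene is a switch gene when at least two of
    its isoforms are conserved DEIs with different enriched niches.
    """
    if len(records_per_sample) < 2:
        raise ValueError("need DEI records from at least two samples")
    pooled = pd.concat(records_per_sample, ignore_index=True)
    if pooled.empty:
        return pooled.assign(n_samples=pd.Series(dtype=int)), []
    support = (
        pooled.groupby(["isoform", "enriched_niche"])["sample_id"]
        .nunique()
        .rename("n_samples")
        .reset_index()
    )
    conserved = support[support["n_samples"] >= min_samples].copy()
    conserved["gene"] = gene_of.reindex(conserved["isoform"]).to_numpy()
    switch_genes = []
    for gene, grp in conserved.groupby("gene"):
        iso_sets = [set(s) for s in grp.groupby("isoform")["enriched_niche"].agg(set)]
        if len(iso_sets) < 2:
            continue
        # two isoforms qualify if some pair of their enriched niches differ
        if any(len(a | b) >= 2 for i, a in enumerate(iso_sets) for b in iso_sets[i + 1 :]):
            switch_genes.append(str(gene))
    return conserved, sorted(switch_genes)


def associate_splicing_factors(
    sf_expr: pd.DataFrame,
    psi_maps: list[PSIMap],
    niche_labels: pd.Series,
    niche_pairs: dict[str, tuple[str, str]] | None = None,
    min_abs_rho: float = 0.3,
    min_defined_spots: int = 20,
    max_p: float = DEI_MAX_P,
    min_abs_log2fc: float = DEI_MIN_ABS_LOG2FC,
    min_pct: float = DEI_MIN_PCT,
) -> pd.DataFrame:
    """Candidate splicing factors for each switch gene.

    A factor qualifies when it is itself differential across the gene's niche
    pair (same Wilcoxon thresholds as DEIs) and its expression correlates with
    the gene's PSI (Spearman |rho| >= ``min_abs_rho``) across spots with
    defined PSI; ``consistent`` records whether the factor tracks the IR
    isoform (rho > 0). Genes with fewer than ``min_defined_spots`` defined
    spots are skipped.
    """
    labels = niche_labels.reindex(sf_expr.columns)
    sf_dei = differential_isoforms(
        sf_expr, labels, sample_id="sf", max_p=max_p,
        min_abs_log2fc=min_abs_log2fc, min_pct=min_pct,
    )
    rows = []
    for pmap in psi_maps:
        psi = pmap.psi.reindex(sf_expr.columns)
        defined = psi.notna()
        if defined.sum() < min_defined_spots:
            logger.warning("gene %s: only %d spots with defined PSI; skipped", pmap.gene, int(defined.sum()))
            continue
        pair = niche_pairs.get(pmap.gene) if niche_pairs else None
        for sf in sf_expr.index:
            hits = sf_dei[sf_dei["isoform"] == sf]
            if pair is not None:
                hits = hits[
                    (hits["enriched_niche"].isin(pair)) & (hits["contrast_niche"].isin(pair))
                ]
            if hits.empty:
                continue
            rho = stats.spearmanr(
                sf_expr.loc[sf, defined.to_numpy()], psi[defined]
            ).statistic
            if np.isnan(rho):
                continue
            rows.append(
                {
                    "sf": sf,
                    "gene": pmap.gene,
                    "rho": float(rho),
                    "candidate": bool(abs(rho) >= min_abs_rho),
                    "consistent": bool(rho > 0),
                }
            )
    return pd.DataFrame(rows, columns=["sf", "gene", "rho", "candidate", "consistent"])
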