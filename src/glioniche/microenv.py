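"""Spot deconvolution, niche-wise cell-type composition, and module-restricted
ligand-receptor pairing.

Deconvolution fits each spot's linear-scale expression as a non-negative
combination of cell-type reference profiles (NNLS) and normalizes the
coefficients to fractions. This is a deliberately simple mixture model; the
downstream niche aggregation (mean cell-type abundance per niche) is the
analysis product of interest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

logger = logging.getLogger(__name__)


@dataclass
class DeconvolutionResult:
    fractions: pd.DataFrame  # spots x cell types, rows sum to 1
    reference: pd.DataFrame  # cell types x genes actually used


@dataclass(frozen=True)
class LigandReceptorHit:
    module: int
    ligand: str
    receptor: str


def build_reference(
    profiles: pd.DataFrame | None = None,
    cells: pd.DataFrame | None = None,
    cell_types: pd.Series | None = None,
    n_cells_per_type: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Cell-type mean-expression reference (types x genes).

    Either pass precomputed ``profiles`` (returned normalized per type), or a
    single-cell matrix ``cells`` (genes x cells) with per-cell ``cell_types``
    labels, in which case up to ``n_cells_per_type`` cells are sampled per
    type (deterministic given ``seed``) and averaged.
    """
    if profiles is None:
        if cells is None or cell_types is None:
            raise ValueError("pass either profiles or (cells, cell_types)")
        rng = np.random.default_rng(seed)
        labels = cell_types.reindex(cells.columns)
        rows = {}
        for t in sorted(labels.dropna().unique()):
            members = np.flatnonzero((labels == t).to_numpy())
            if len(members) == 0:
                logger.warning("cell type %s has no cells; excluded", t)
                continue
            if len(members) > n_cells_per_type:
                members = rng.choice(members, size=n_cells_per_type, replace=False)
            rows[t] = np.asarray(cells, dtype=float)[:, members].mean(axis=1)
        profiles = pd.DataFrame(rows, index=cells.index).T
    if profiles.shape[0] < 2:
        raise ValueError("need at least two cell types")
    sums = profiles.sum(axis=1)
    return profiles.div(sums.replace(0.0, np.nan), axis=0).fillna(0.0)


def deconvolve(expr: pd.DataFrame, reference: pd.DataFrame) -> DeconvolutionResult:
    """Non-negative least-squares mixture fractions per spot.

    ``expr`` is linear-scale (depth-normalized, not log) genes x spots;
    ``reference`` is types x genes. Fractions are normalized to sum to 1.
    """
    shared = expr.index.intersection(reference.columns)
    if len(shared) == 0:
        raise ValueError("no shared genes between expression and reference")
    ref = reference[shared]
    if ref.shape[0] < 2:
        raise ValueError("need at least two reference cell types")
    # duplicate profiles make the fit ill-posed; report the colliding types
    R = ref.to_numpy()
    norms = np.linalg.norm(R, axis=1, keepdims=True)
    unit = R / np.maximum(norms, 1e-300)
    gram = unit @ unit.T
    dup = np.argwhere(np.triu(gram > 1.0 - 1e-10, k=1))
    if len(dup):
        a, b = dup[0]
        raise ValueError(
            f"reference is rank deficient: profiles {ref.index[a]!r} and {ref.index[b]!r} collide"
        )
    A = R.T  # genes x types
    X = np.asarray(expr.loc[shared], dtype=float)
    out = np.zeros((expr.shape[1], ref.shape[0]))
    for j in range(X.shape[1]):
        coef, _ = nnls(A, X[:, j])
        total = coef.sum()
        out[j] = coef / total if total > 0 else 1.0 / len(coef)
    fractions = pd.DataFrame(out, index=expr.columns, columns=ref.index)
    return DeconvolutionResult(fractions=fractions, reference=ref)


def merge_homonym_types(fractions: pd.DataFrame, suffix: str = "-like") -> pd.DataFrame:
    """Sum fractions of tumor/normal homonym cell types (e.g. 'AC-like' + 'AC')."""
    base = [c[: -len(suffix)] if c.endswith(suffix) else c for c in fractions.columns]
    return fractions.T.groupby(pd.Index(base, name="cell_type")).sum().T


def niche_composition(result: DeconvolutionResult, niche_labels: pd.Series) -> pd.DataFrame:
    """Mean cell-type fraction per niche (rows sum to 1)."""
    labels = niche_labels.reindex(result.fractions.index)
    covered = labels.notna()
    if not covered.all():
        logger.warning("%d spots without niche label excluded", int((~covered).sum()))
    comp = result.fractions[covered.to_numpy()].groupby(labels[covered].to_numpy()).mean()
    comp.index.name = "niche"
    return comp


def ligand_receptor_pairs(
    gene_sets: dict[int, list[str]], pair_pool: pd.DataFrame
) -> list[LigandReceptorHit]:
    """Directional (ligand, receptor) pool pairs whose both partners are in the
    same module's gene set; deduplicated."""
    if pair_pool.empty:
        raise ValueError("ligand-receptor pool is empty")
    hits: list[LigandReceptorHit] = []
    seen = set()
    for mod, genes in sorted(gene_sets.items()):
        members = set(genes)
        for lig, rec in pair_pool[["ligand", "receptor"]].itertuples(index=False):
            if lig in members and rec in members and (mod, lig, rec) not in seen:
                seen.add((mod, lig, rec))
                hits.append(LigandReceptorHit(module=mod, ligand=lig, receptor=rec))
    return hits
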