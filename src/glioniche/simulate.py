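"""Synthetic multi-sample Visium-like glioma datasets with planted ground truth.

The generator emulates the data layout assumed by the rest of the pipeline:
a hexagonal spot lattice per sample, spot-level cell-type mixtures whose
malignant fraction varies over space, subclonal whole-chromosome copy-number
events, four spatially organized niche expression programs (tumor core,
vascular, invasive, hypoxic) on top of a normal rim, transcript bleed between
nearby spots ("spot swapping"), isoform switch genes whose two isoforms mix
with niche-specific proportions, and rare reads covering a point-mutation
locus. Every planted quantity is returned as :class:`GroundTruth` so that
recovery can be scored exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

MALIGNANT_NICHES = ("core", "vascular", "invasive", "hypoxic")
NICHES = MALIGNANT_NICHES + ("normal",)

CELL_TYPES = (
    "malignant",
    "astrocyte",
    "oligodendrocyte",
    "OPC",
    "neuron",
    "endothelial",
    "immune",
)

# microenvironment (non-malignant) composition per niche; rows sum to 1
_NICHE_MICROENV = {
    "core":     dict(astrocyte=0.30, oligodendrocyte=0.20, OPC=0.30, neuron=0.05, endothelial=0.05, immune=0.10),
    "hypoxic":  dict(astrocyte=0.30, oligodendrocyte=0.05, OPC=0.03, neuron=0.02, endothelial=0.20, immune=0.40),
    "vascular": dict(astrocyte=0.20, oligodendrocyte=0.02, OPC=0.05, neuron=0.03, endothelial=0.50, immune=0.20),
    "invasive": dict(astrocyte=0.20, oligodendrocyte=0.15, OPC=0.04, neuron=0.55, endothelial=0.03, immune=0.03),
    "normal":   dict(astrocyte=0.25, oligodendrocyte=0.25, OPC=0.05, neuron=0.40, endothelial=0.03, immune=0.02),
}

_NICHE_TUMOR_FRACTION = {
    "core": 0.85,
    "hypoxic": 0.90,
    "vascular": 0.50,
    "invasive": 0.45,
    "normal": 0.0,
}


@dataclass(frozen=True)
class CNVEvent:
    """A whole-chromosome copy-number event carried by a subclone."""

    chrom: str
    direction: str  # "gain" | "loss"
    multiplier: float

    def __post_init__(self) -> None:
        if self.direction not in ("gain", "loss"):
            raise ValueError(f"direction must be gain|loss, got {self.direction!r}")
        if self.direction == "gain" and not self.multiplier > 1:
            raise ValueError("gain multiplier must be > 1")
        if self.direction == "loss" and not 0 < self.multiplier < 1:
            raise ValueError("loss multiplier must be in (0, 1)")


@dataclass(frozen=True)
class SubcloneSpec:
    """A subclone, its CNV events, and where it lives on the array.

    ``region`` is one of ``"everywhere"`` (default clone for all tumor spots),
    ``"sector:A-B"`` (tumor spots whose polar angle from the lattice center is
    within [A, B) degrees), or ``"niche:<name>"`` (tumor spots of that niche).
    Later subclones in the config override earlier ones inside their region.
    """

    name: str
    events: tuple[CNVEvent, ...]
    region: str = "everywhere"

    def __post_init__(self) -> None:
        if len(self.events) < 1:
            raise ValueError(f"subclone {self.name!r} must carry at least one CNV event")
        chroms = [e.chrom for e in self.events]
        if len(set(chroms)) != len(chroms):
            raise ValueError(
                f"subclone {self.name!r} has overlapping event regions on {chroms}"
            )


def default_subclones() -> tuple[SubcloneSpec, ...]:
    truncal = (
        CNVEvent("chr1", "gain", 1.5),
        CNVEvent("chr7", "gain", 1.5),
        CNVEvent("chr10", "loss", 0.5),
    )
    return (
        SubcloneSpec("clone_a", truncal, region="everywhere"),
        SubcloneSpec("clone_b", truncal + (CNVEvent("chr5", "loss", 0.5),), region="sector:0-120"),
    )


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated multi-sample Visium experiment."""

    n_samples: int = 3
    grid_shape: tuple[int, int] = (32, 32)
    n_genes: int = 2000
    n_isoform_genes: int = 40
    niche_layout: str = "concentric"  # "concentric" | "blocks"
    module_genes_per_niche: int = 60
    module_fold: float = 2.0
    subclones: tuple[SubcloneSpec, ...] = field(default_factory=default_subclones)
    tumor_fraction_field: str = "concentric"  # "concentric" | "plateau" | "zero"
    bleed_rate: float = 0.25
    bleed_kernel_sd: float = 1.5
    nb_dispersion: float = 0.5
    library_size_lognormal: tuple[float, float] = (np.log(10_000.0), 0.35)
    n_chromosomes: int = 10
    n_cell_type_markers: int = 60
    n_mito_genes: int = 10
    mito_weight: float = 0.06
    isoform_switching: bool = True
    switch_p_high: float = 0.8
    switch_p_low: float = 0.2
    variant_read_rate: float = 1e-5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.bleed_rate < 1:
            raise ValueError("bleed_rate must be in [0, 1)")
        if self.grid_shape[0] * self.grid_shape[1] < 25:
            raise ValueError("grid too small to place the requested niches")
        if self.niche_layout not in ("concentric", "blocks"):
            raise ValueError(f"unknown niche_layout {self.niche_layout!r}")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")


@dataclass
class SpatialSample:
    """One sample's gene-by-spot counts with hex-lattice coordinates."""

    sample_id: str
    counts: pd.DataFrame  # genes x spots, nonnegative integers
    coords: pd.DataFrame  # spots x (array_row, array_col, x, y), index = barcode
    genes: pd.DataFrame  # gene annotation: chrom, start; index = gene id

    def __post_init__(self) -> None:
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate barcodes")
        if not np.array_equal(self.counts.columns, self.coords.index):
            raise ValueError("coordinate rows must match barcode order")
        if (np.asarray(self.counts) < 0).any():
            raise ValueError("counts must be nonnegative")
        if not self.genes.index.equals(self.counts.index):
            raise ValueError("every gene needs a genomic annotation row")

    @property
    def barcodes(self) -> pd.Index:
        return self.counts.columns

    def to_anndata(self):
        """Spots-by-genes AnnData view (optional; requires anndata)."""
        import anndata as ad

        adata = ad.AnnData(
            X=np.asarray(self.counts, dtype=np.float32).T,
            obs=self.coords.copy(),
            var=self.genes.copy(),
        )
        adata.obsm["spatial"] = self.coords[["x", "y"]].to_numpy()
        return adata


@dataclass
class GroundTruth:
    """Everything planted into one simulated sample."""

    spots: pd.DataFrame  # niche, tumor_fraction, subclone (object; None = normal)
    cell_fractions: pd.DataFrame  # spots x cell types, rows sum to 1
    gene_modules: pd.Series  # gene -> niche name or NaN
    cell_type_markers: pd.Series  # gene -> cell type or NaN
    profiles: pd.DataFrame  # cell type x gene, rows sum to 1
    switches: pd.DataFrame  # per switch gene: iso_a, iso_b, niche_high, niche_low
    sf_drivers: pd.DataFrame  # per splicing-factor gene: niche_high, niche_low
    subclone_events: dict[str, tuple[CNVEvent, ...]]


@dataclass
class IsoformTable:
    """Isoform-by-spot counts with a many-to-one isoform -> host gene map."""

    counts: pd.DataFrame  # isoforms x spots, nonnegative integers
    gene_of: pd.Series  # isoform id -> host gene id

    def __post_init__(self) -> None:
        if (np.asarray(self.counts) < 0).any():
            raise ValueError("isoform counts must be nonnegative")
        missing = self.counts.index.difference(self.gene_of.index)
        if len(missing):
            raise ValueError(f"isoforms without a host gene: {list(missing)[:5]}")


@dataclass
class SimulatedDataset:
    config: SimConfig
    samples: list[SpatialSample]
    isoforms: list[IsoformTable]
    variants: list[pd.DataFrame]  # per spot: mutant, total
    truths: list[GroundTruth]


# ---------------------------------------------------------------------------
# lattice and spatial layout


def hex_lattice(rows: int, cols: int) -> pd.DataFrame:
    """Offset-row hexagonal lattice; pixel coords are an affine map of array coords."""
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    rr, cc = rr.ravel(), cc.ravel()
    x = cc + 0.5 * (rr % 2)
    y = rr * (np.sqrt(3.0) / 2.0)
    barcodes = [f"s{r:03d}x{c:03d}" for r, c in zip(rr, cc)]
    return pd.DataFrame(
        {"array_row": rr, "array_col": cc, "x": x, "y": y}, index=pd.Index(barcodes, name="barcode")
    )


def _radial(coords: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Normalized radius (1 = inscribed circle) and polar angle in degrees."""
    x = coords["x"].to_numpy()
    y = coords["y"].to_numpy()
    cx, cy = (x.min() + x.max()) / 2, (y.min() + y.max()) / 2
    half = min(x.max() - x.min(), y.max() - y.min()) / 2
    r = np.hypot(x - cx, y - cy) / half
    theta = np.degrees(np.arctan2(y - cy, x - cx)) % 360.0
    return r, theta


def _assign_niches(coords: pd.DataFrame, layout: str, rng: np.random.Generator) -> np.ndarray:
    n = len(coords)
    niche = np.full(n, "normal", dtype=object)
    if layout == "concentric":
        r, _ = _radial(coords)
        niche[r < 0.82] = "invasive"
        niche[r < 0.58] = "core"
        niche[r < 0.27] = "hypoxic"
        # vascular speckles: a few contiguous blobs inside the tumor area,
        # kept clear of the small hypoxic center
        xy = coords[["x", "y"]].to_numpy()
        inside = np.flatnonzero((r >= 0.34) & (r < 0.72))
        n_blobs = 4
        centers = rng.choice(inside, size=min(n_blobs, len(inside)), replace=False)
        for c in centers:
            d = np.hypot(xy[:, 0] - xy[c, 0], xy[:, 1] - xy[c, 1])
            niche[(d < 1.8) & (niche != "normal")] = "vascular"
    else:  # blocks: five vertical bands
        x = coords["x"].to_numpy()
        edges = np.quantile(x, [0.2, 0.4, 0.6, 0.8])
        bands = np.searchsorted(edges, x)
        for b, name in enumerate(["normal", "invasive", "core", "hypoxic", "vascular"]):
            niche[bands == b] = name
    return niche


def _smooth_noise(coords: pd.DataFrame, rng: np.random.Generator, scale: float = 3.0) -> np.ndarray:
    """Smooth zero-mean spatial field via Gaussian-kernel smoothing of white noise."""
    xy = coords[["x", "y"]].to_numpy()
    raw = rng.normal(size=len(xy))
    d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1)
    w = np.exp(-0.5 * d2 / scale**2)
    sm = w @ raw / w.sum(1)
    sm = (sm - sm.mean()) / (sm.std() + 1e-12)
    return sm


def _tumor_fraction(niche: np.ndarray, coords: pd.DataFrame, mode: str, rng: np.random.Generator) -> np.ndarray:
    if mode == "zero":
        return np.zeros(len(niche))
    if mode == "plateau":
        return np.where(niche != "normal", 0.95, 0.0)
    if mode != "concentric":
        raise ValueError(f"unknown tumor_fraction_field {mode!r}")
    base = np.array([_NICHE_TUMOR_FRACTION[n] for n in niche])
    jitter = 0.08 * _smooth_noise(coords, rng)
    f = np.clip(base + jitter, 0.05, 0.98)
    f[niche == "normal"] = 0.0
    return f


def _assign_subclones(
    niche: np.ndarray,
    tumor_fraction: np.ndarray,
    coords: pd.DataFrame,
    subclones: Sequence[SubcloneSpec],
) -> np.ndarray:
    sub = np.full(len(niche), None, dtype=object)
    tumor = tumor_fraction > 0
    _, theta = _radial(coords)
    for spec in subclones:
        if spec.region == "everywhere":
            mask = tumor
        elif spec.region.startswith("sector:"):
            a, b = (float(v) for v in spec.region.split(":", 1)[1].split("-"))
            mask = tumor & (theta >= a) & (theta < b)
        elif spec.region.startswith("niche:"):
            mask = tumor & (niche == spec.region.split(":", 1)[1])
        else:
            raise ValueError(f"unknown subclone region {spec.region!r}")
        sub[mask] = spec.name
    return sub


# ---------------------------------------------------------------------------
# gene annotation and cell-type profiles


def _gene_annotation(config: SimConfig) -> pd.DataFrame:
    n = config.n_genes
    per = int(np.ceil(n / config.n_chromosomes))
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes) for _ in range(per)][:n]
    starts = np.concatenate(
        [np.arange(1, 1 + (np.array(chroms) == c).sum()) * 10_000 for c in dict.fromkeys(chroms)]
    )
    names = [f"G{i:04d}" for i in range(n)]
    return pd.DataFrame({"chrom": chroms, "start": starts}, index=pd.Index(names, name="gene"))


def _plant_genes(config: SimConfig, rng: np.random.Generator, genes: pd.Index):
    """Pick disjoint mito / module / switch / SF / cell-type-marker gene sets."""
    n = len(genes)
    order = rng.permutation(n)
    cursor = 0

    def take(k: int) -> np.ndarray:
        nonlocal cursor
        sel = order[cursor : cursor + k]
        cursor += k
        return sel

    mito = take(config.n_mito_genes)
    module = {niche: take(config.module_genes_per_niche) for niche in MALIGNANT_NICHES}
    switch = take(config.n_isoform_genes)
    niche_pairs = [
        ("core", "invasive"), ("core", "hypoxic"), ("core", "vascular"),
        ("invasive", "hypoxic"), ("invasive", "vascular"), ("hypoxic", "vascular"),
    ]
    sf = take(len(niche_pairs))
    markers = {t: take(config.n_cell_type_markers) for t in CELL_TYPES}
    return mito, module, switch, niche_pairs, sf, markers


def _cell_type_profiles(
    config: SimConfig,
    rng: np.random.Generator,
    genes: pd.Index,
    mito: np.ndarray,
    switch: np.ndarray,
    markers: dict[str, np.ndarray],
) -> pd.DataFrame:
    n = len(genes)
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n)
    base[switch] = np.maximum(base[switch], 4.0)  # switch genes need PSI-level depth
    base[mito] = 0.0
    profiles = {}
    for t in CELL_TYPES:
        w = base.copy()
        w[markers[t]] *= 5.0  # cell-type marker boost
        for other, idx in markers.items():
            if other != t:
                w[idx] *= 0.25
        w = w / w.sum() * (1.0 - config.mito_weight)
        w[mito] = config.mito_weight / len(mito)
        profiles[t] = w
    out = pd.DataFrame(profiles, index=genes).T
    out.index.name = "cell_type"
    return out


# ---------------------------------------------------------------------------
# operations


def apply_spot_swapping(
    counts: pd.DataFrame,
    coords: pd.DataFrame,
    bleed_rate: float,
    kernel_sd: float = 1.5,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Multinomially reallocate a fraction of each spot's UMIs to nearby spots.

    Each UMI independently stays in its spot with probability ``1 - bleed_rate``
    or bleeds to another spot with Gaussian-distance weights. The total UMI
    count of the array is conserved exactly.
    """
    if not 0 <= bleed_rate < 1:
        raise ValueError("bleed_rate must be in [0, 1)")
    if bleed_rate == 0:
        return counts.copy()
    if counts.shape[1] < 2:
        raise ValueError("cannot bleed with a single spot: nowhere to go")
    rng = np.random.default_rng() if rng is None else rng
    mat = np.asarray(counts, dtype=np.int64)
    n_genes, n_spots = mat.shape
    xy = coords[["x", "y"]].to_numpy()
    out = np.zeros_like(mat)
    for j in range(n_spots):
        col = mat[:, j]
        kept = rng.binomial(col, 1.0 - bleed_rate)
        leaked = col - kept
        out[:, j] += kept
        total_leak = int(leaked.sum())
        if total_leak == 0:
            continue
        d2 = ((xy - xy[j]) ** 2).sum(1)
        w = np.exp(-0.5 * d2 / kernel_sd**2)
        w[j] = 0.0
        if w.sum() == 0:  # pathological geometry; bleed uniformly
            w[:] = 1.0
            w[j] = 0.0
        w = w / w.sum()
        gene_idx = np.repeat(np.arange(n_genes), leaked)
        dest = rng.choice(n_spots, size=total_leak, p=w)
        np.add.at(out, (gene_idx, dest), 1)
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


def generate_isoform_counts(
    gene_counts: pd.DataFrame,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
) -> IsoformTable:
    """Binomially split each switch gene's spot counts between its two isoforms."""
    rng = np.random.default_rng() if rng is None else rng
    sw = truth.switches
    missing = sw.index.difference(gene_counts.index)
    if len(missing):
        raise ValueError(f"switch genes absent from gene counts: {list(missing)[:5]}")
    niche = truth.spots["niche"].to_numpy()
    rows, names, gene_of = [], [], {}
    for gene, rec in sw.iterrows():
        p = np.full(len(niche), 0.5)
        p[niche == rec["niche_high"]] = rec["p_high"]
        p[niche == rec["niche_low"]] = rec["p_low"]
        if not ((p >= 0) & (p <= 1)).all():
            raise ValueError("mixing proportion outside [0, 1]")
        g = gene_counts.loc[gene].to_numpy(dtype=np.int64)
        a = rng.binomial(g, p)
        rows += [a, g - a]
        names += [rec["iso_a"], rec["iso_b"]]
        gene_of[rec["iso_a"]] = gene
        gene_of[rec["iso_b"]] = gene
    counts = pd.DataFrame(np.vstack(rows), index=pd.Index(names, name="isoform"), columns=gene_counts.columns)
    return IsoformTable(counts=counts, gene_of=pd.Series(gene_of, name="gene"))


def generate_variant_reads(
    truth: GroundTruth,
    per_read_rate: float,
    counts: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Sparse coverage of a mutant locus: Poisson totals, mutant reads only in tumor spots."""
    if not 0 < per_read_rate < 1:
        raise ValueError("per_read_rate must be in (0, 1)")
    rng = np.random.default_rng() if rng is None else rng
    umi = np.asarray(counts.sum(axis=0), dtype=float)
    total = rng.poisson(per_read_rate * umi)
    frac = truth.spots["tumor_fraction"].to_numpy()
    mutant = rng.binomial(total, frac)
    return pd.DataFrame({"mutant": mutant, "total": total}, index=counts.columns)


def generate_dataset(config: SimConfig) -> SimulatedDataset:
    """Generate the full multi-sample dataset; deterministic given ``config.seed``."""
    root = np.random.SeedSequence(config.seed)
    layout_rng = np.random.default_rng(root.spawn(1)[0])
    genes = _gene_annotation(config)
    mito, module, switch, niche_pairs, sf, markers = _plant_genes(config, layout_rng, genes.index)
    gene_names = genes.index.to_numpy().copy()
    mito_names = [f"MT-{i}" for i in range(len(mito))]
    gene_names[mito] = mito_names
    genes.index = pd.Index(gene_names, name="gene")
    profiles = _cell_type_profiles(config, layout_rng, genes.index, mito, switch, markers)

    gene_modules = pd.Series(np.nan, index=genes.index, dtype=object)
    for niche_name, idx in module.items():
        gene_modules.iloc[idx] = niche_name
    marker_of = pd.Series(np.nan, index=genes.index, dtype=object)
    for t, idx in markers.items():
        marker_of.iloc[idx] = t

    switch_genes = genes.index[switch]
    sw_rows = []
    for i, g in enumerate(switch_genes):
        hi, lo = niche_pairs[i % len(niche_pairs)]
        p_hi = config.switch_p_high if config.isoform_switching else 0.5
        p_lo = config.switch_p_low if config.isoform_switching else 0.5
        sw_rows.append((g, f"{g}-201", f"{g}-202", hi, lo, p_hi, p_lo))
    switches = pd.DataFrame(
        sw_rows, columns=["gene", "iso_a", "iso_b", "niche_high", "niche_low", "p_high", "p_low"]
    ).set_index("gene")
    sf_drivers = pd.DataFrame(
        [(genes.index[sf[i]], hi, lo) for i, (hi, lo) in enumerate(niche_pairs)],
        columns=["gene", "niche_high", "niche_low"],
    ).set_index("gene")

    samples, iso_tables, variant_tables, truths = [], [], [], []
    sample_seeds = root.spawn(config.n_samples + 1)[1:]
    rows, cols = config.grid_shape
    for s in range(config.n_samples):
        rng = np.random.default_rng(sample_seeds[s])
        sample_id = f"sample{s + 1}"
        coords = hex_lattice(rows, cols)
        coords.index = pd.Index([f"{sample_id}_{b}" for b in coords.index], name="barcode")
        niche = _assign_niches(coords, config.niche_layout, rng)
        frac = _tumor_fraction(niche, coords, config.tumor_fraction_field, rng)
        if (frac == 0).all():
            niche = np.full(len(niche), "normal", dtype=object)
        subclone = _assign_subclones(niche, frac, coords, config.subclones)
        event_map = {sc.name: sc.events for sc in config.subclones}

        # cell-type fraction per spot
        micro = np.array([[_NICHE_MICROENV[n][t] for t in CELL_TYPES[1:]] for n in niche])
        alpha = micro * 60.0 + 1e-3
        micro_jittered = rng.gamma(alpha)
        micro_jittered /= micro_jittered.sum(1, keepdims=True)
        fractions = np.column_stack([frac, (1.0 - frac)[:, None] * micro_jittered])
        cell_fractions = pd.DataFrame(fractions, index=coords.index, columns=list(CELL_TYPES))

        # expected expression: mixture of cell-type profiles x module fold x CNV
        mu = fractions @ profiles.to_numpy()  # spots x genes
        for niche_name, idx in module.items():
            in_niche = niche == niche_name
            mu[np.ix_(in_niche, idx)] *= config.module_fold
        for i, (hi, _lo) in enumerate(niche_pairs):  # splicing factors track their high niche
            mu[niche == hi, sf[i]] *= 3.0
        chrom_arr = genes["chrom"].to_numpy()
        for sc_name, events in event_map.items():
            spots_in = subclone == sc_name
            if not spots_in.any():
                continue
            for ev in events:
                on_chrom = chrom_arr == ev.chrom
                eff = 1.0 + frac[spots_in, None] * (ev.multiplier - 1.0)
                mu[np.ix_(spots_in, on_chrom)] *= eff

        lib_mu, lib_sigma = config.library_size_lognormal
        lib = rng.lognormal(lib_mu, lib_sigma, size=len(coords))
        mu = mu / mu.sum(1, keepdims=True) * lib[:, None]

        inv_disp = 1.0 / config.nb_dispersion
        p_nb = inv_disp / (inv_disp + mu)
        clean = rng.negative_binomial(inv_disp, p_nb).T.astype(np.int64)  # genes x spots
        counts = pd.DataFrame(clean, index=genes.index, columns=coords.index)
        if config.bleed_rate > 0:
            counts = apply_spot_swapping(
                counts, coords, config.bleed_rate, config.bleed_kernel_sd, rng
            )

        truth = GroundTruth(
            spots=pd.DataFrame(
                {"niche": niche, "tumor_fraction": frac, "subclone": subclone}, index=coords.index
            ),
            cell_fractions=cell_fractions,
            gene_modules=gene_modules,
            cell_type_markers=marker_of,
            profiles=profiles,
            switches=switches,
            sf_drivers=sf_drivers,
            subclone_events=event_map,
        )
        sample = SpatialSample(sample_id=sample_id, counts=counts, coords=coords, genes=genes)
        iso_tables.append(generate_isoform_counts(counts, truth, rng))
        variant_tables.append(generate_variant_reads(truth, config.variant_read_rate, counts, rng))
        samples.append(sample)
        truths.append(truth)

    return SimulatedDataset(
        config=config, samples=samples, isoforms=iso_tables, variants=variant_tables, truths=truths
    )
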