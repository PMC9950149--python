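"""Readers and writers for the 10X-style on-disk layout used across stages.

A sample directory holds ``matrix.mtx`` (genes x spots), ``features.tsv``
(gene id, chromosome, start), ``barcodes.tsv``, and ``coords.csv``
(barcode, array_row, array_col, x, y). Isoform counts use the same MTX
triplet with ``features.tsv`` carrying (isoform id, host gene id).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .simulate import GroundTruth, IsoformTable, SimulatedDataset, SpatialSample

COORD_COLUMNS = ["array_row", "array_col", "x", "y"]


def write_visium_like(sample: SpatialSample, outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mat = sparse.csc_matrix(np.asarray(sample.counts, dtype=np.int64))
    spio.mmwrite(outdir / "matrix.mtx", mat)
    feats = sample.genes.reset_index()
    feats.to_csv(outdir / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(sample.counts.columns).to_csv(outdir / "barcodes.tsv", sep="\t", header=False, index=False)
    coords = sample.coords.reset_index()
    coords.columns = ["barcode"] + COORD_COLUMNS
    coords.to_csv(outdir / "coords.csv", index=False)
    return outdir


def read_visium_like(indir, sample_id: str | None = None) -> SpatialSample:
    indir = Path(indir)
    for name in ("matrix.mtx", "features.tsv", "barcodes.tsv", "coords.csv"):
        if not (indir / name).exists():
            raise FileNotFoundError(f"missing {name} in {indir}")
    mat = spio.mmread(indir / "matrix.mtx").toarray().astype(np.int64)
    feats = pd.read_csv(indir / "features.tsv", sep="\t", header=None, names=["gene", "chrom", "start"])
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    coords = pd.read_csv(indir / "coords.csv").set_index("barcode")
    if mat.shape != (len(feats), len(barcodes)):
        raise ValueError(
            f"matrix shape {mat.shape} does not match {len(feats)} features x {len(barcodes)} barcodes"
        )
    if barcodes.duplicated().any():
        raise ValueError("duplicate barcodes")
    if (mat < 0).any():
        raise ValueError("negative counts")
    if list(coords.index) != list(barcodes):
        raise ValueError("coords.csv barcode order does not match barcodes.tsv")
    counts = pd.DataFrame(mat, index=pd.Index(feats["gene"], name="gene"), columns=pd.Index(barcodes, name="barcode"))
    genes = feats.set_index("gene")[["chrom", "start"]]
    return SpatialSample(
        sample_id=sample_id or indir.name,
        counts=counts,
        coords=coords[COORD_COLUMNS],
        genes=genes,
    )


def write_isoforms(table: IsoformTable, outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(outdir / "matrix.mtx", sparse.csc_matrix(np.asarray(table.counts, dtype=np.int64)))
    pd.DataFrame(
        {"isoform": table.counts.index, "gene": table.gene_of.reindex(table.counts.index).to_numpy()}
    ).to_csv(outdir / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(table.counts.columns).to_csv(outdir / "barcodes.tsv", sep="\t", header=False, index=False)
    return outdir


def read_isoforms(indir) -> IsoformTable:
    indir = Path(indir)
    mat = spio.mmread(indir / "matrix.mtx").toarray().astype(np.int64)
    feats = pd.read_csv(indir / "features.tsv", sep="\t", header=None, names=["isoform", "gene"])
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    counts = pd.DataFrame(mat, index=pd.Index(feats["isoform"], name="isoform"), columns=pd.Index(barcodes, name="barcode"))
    return IsoformTable(counts=counts, gene_of=feats.set_index("isoform")["gene"])


def write_truth(truth: GroundTruth, outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth.spots.to_csv(outdir / "truth_spots.tsv", sep="\t")
    truth.cell_fractions.to_csv(outdir / "truth_cell_fractions.tsv", sep="\t")
    truth.profiles.to_csv(outdir / "truth_profiles.tsv", sep="\t")
    meta = {
        "gene_modules": {g: m for g, m in truth.gene_modules.dropna().items()},
        "cell_type_markers": {g: t for g, t in truth.cell_type_markers.dropna().items()},
        "switches": truth.switches.reset_index().to_dict(orient="records"),
        "sf_drivers": truth.sf_drivers.reset_index().to_dict(orient="records"),
        "subclone_events": {
            name: [{"chrom": e.chrom, "direction": e.direction, "multiplier": e.multiplier} for e in evs]
            for name, evs in truth.subclone_events.items()
        },
    }
    (outdir / "truth.json").write_text(json.dumps(meta, indent=1))
    return outdir


def write_dataset(dataset: SimulatedDataset, outdir) -> Path:
    """Write the full simulated dataset in the on-disk layout."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    import dataclasses

    cfg = dataclasses.asdict(dataset.config)
    cfg["subclones"] = [
        {
            "name": sc.name,
            "region": sc.region,
            "events": [{"chrom": e.chrom, "direction": e.direction, "multiplier": e.multiplier} for e in sc.events],
        }
        for sc in dataset.config.subclones
    ]
    (outdir / "config.json").write_text(json.dumps(cfg, indent=1))
    for sample, iso, var, truth in zip(dataset.samples, dataset.isoforms, dataset.variants, dataset.truths):
        sdir = outdir / sample.sample_id
        write_visium_like(sample, sdir)
        write_isoforms(iso, sdir / "isoforms")
        var.to_csv(sdir / "variants.tsv", sep="\t")
        write_truth(truth, sdir / "truth")
    return outdir
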