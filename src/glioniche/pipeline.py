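"""End-to-end orchestration of the analysis stages on a simulated dataset.

Stage order: QC -> normalization -> spatially informed clustering -> marker
signatures -> CNV -> tumor content -> module integration -> niche assignment
-> subclones -> isoforms -> deconvolution. Each stage is skippable; a run
manifest records parameters, seeds, and SHA-256 hashes of every written
output so a run can be reproduced and verified file by file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cnv as cnv_mod
from . import isoforms as iso_mod
from . import microenv as micro_mod
from . import modules as mod_mod
from . import preprocess as pre_mod
from .simulate import MALIGNANT_NICHES, SimConfig, SimulatedDataset, generate_dataset

logger = logging.getLogger(__name__)

STAGES = (
    "qc",
    "cluster",
    "markers",
    "cnv",
    "tumor_content",
    "integrate",
    "niches",
    "subclones",
    "isoforms",
    "deconvolve",
)

_KNOWN_KEYS = {
    "seed",
    "out_dir",
    "skip",
    "sim",
    "cluster",
    "markers",
    "integrate",
    "cnv",
}


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str | None = None
    skip: tuple[str, ...] = ()
    sim: SimConfig | None = None
    cluster: dict = field(default_factory=dict)  # spatial_cluster keyword overrides
    markers: dict = field(default_factory=dict)
    integrate: dict = field(default_factory=dict)
    cnv: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw = dict(raw)
        if "sim" in raw and raw["sim"] is not None and not isinstance(raw["sim"], SimConfig):
            raw["sim"] = SimConfig(**raw["sim"])
        if "skip" in raw:
            bad = set(raw["skip"]) - set(STAGES)
            if bad:
                raise ValueError(f"unknown stages in skip: {sorted(bad)}")
            raw["skip"] = tuple(raw["skip"])
        return cls(**raw)


def stage_seed(seed: int, stage: str) -> int:
    """Stable per-stage child seed derived from the global seed."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class PipelineResult:
    manifest: dict
    qc: dict
    exprs: dict
    cluster_labels: dict
    signatures: list
    profiles: dict
    events: dict
    content: dict
    partition: dict
    niche_labels: dict
    subclones: dict
    dei: dict
    composition: pd.DataFrame | None


def run_pipeline(config: PipelineConfig, dataset: SimulatedDataset | None = None) -> PipelineResult:
    """Run all (non-skipped) stages; returns in-memory results plus a manifest."""
    skip = set(config.skip)
    manifest: dict = {
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in STAGES},
        "skipped": sorted(skip),
        "parameters": {
            "cluster": config.cluster,
            "markers": config.markers,
            "integrate": config.integrate,
            "cnv": config.cnv,
        },
        "outputs": {},
    }
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    if dataset is None:
        sim = config.sim or SimConfig(seed=stage_seed(config.seed, "simulate"))
        dataset = generate_dataset(sim)
    manifest["n_samples"] = len(dataset.samples)

    qc_masks, exprs, mal_masks = {}, {}, {}
    for sample, truth in zip(dataset.samples, dataset.truths):
        mask = pre_mod.qc_filter(sample)
        qc_masks[sample.sample_id] = mask
        passing = mask.passed[mask.passed].index
        exprs[sample.sample_id] = pre_mod.lognormalize(sample.counts[passing])
    if "qc" in skip:
        for sample in dataset.samples:
            exprs[sample.sample_id] = pre_mod.lognormalize(sample.counts)

    # CNV and tumor content come first: malignant spots feed the clustering
    profiles, events, contents, mal = {}, {}, {}, {}
    if "cnv" not in skip:
        for sample, truth in zip(dataset.samples, dataset.truths):
            sid = sample.sample_id
            expr = exprs[sid]
            reference = [
                b for b in truth.spots.index[truth.spots["niche"] == "normal"] if b in expr.columns
            ]
            prof = cnv_mod.infer_cnv(expr, sample.genes, reference, **config.cnv)
            evs = cnv_mod.designate_signature_events(prof)
            profiles[sid] = prof
            events[sid] = evs
            if "tumor_content" not in skip and evs:
                consensus, _ = cnv_mod.robust_content(prof, evs)
                contents[sid] = consensus
                mal[sid] = consensus > cnv_mod.MALIGNANT_CUTOFF
    for sample, truth in zip(dataset.samples, dataset.truths):
        sid = sample.sample_id
        if sid not in mal:  # fall back to planted truth when CNV stage skipped
            mal[sid] = pd.Series(
                (truth.spots["tumor_fraction"] > 0.2).reindex(exprs[sid].columns, fill_value=False)
            )

    labels, signatures = {}, []
    if "cluster" not in skip:
        for sample in dataset.samples:
            sid = sample.sample_id
            spots = exprs[sid].columns[mal[sid].reindex(exprs[sid].columns, fill_value=False)]
            labels[sid] = pre_mod.spatial_cluster(
                exprs[sid][spots],
                sample.coords.loc[spots],
                seed=stage_seed(config.seed, "cluster"),
                **config.cluster,
            )
        if "markers" not in skip:
            for sample in dataset.samples:
                sid = sample.sample_id
                signatures.extend(
                    pre_mod.find_markers(
                        exprs[sid][labels[sid].index], labels[sid], sample_id=sid, **config.markers
                    )
                )

    partition, gene_sets, niche_labels = {}, {}, {}
    if "integrate" not in skip and signatures:
        mal_exprs = {sid: exprs[sid][labels[sid].index] for sid in labels}
        score_seed = stage_seed(config.seed, "integrate")
        scores_cat = pd.concat(
            [mod_mod.score_signatures(mal_exprs[sid], signatures, seed=score_seed) for sid in mal_exprs]
        )
        partition = mod_mod.integrate_spotlevel(scores_cat, **config.integrate)
        gene_sets = mod_mod.module_gene_sets(partition, signatures)
        if "niches" not in skip:
            for sid, expr in mal_exprs.items():
                asn = mod_mod.assign_niches(expr, gene_sets, seed=score_seed)
                niche_labels[sid] = asn.niche_labels

    subclone_tables = {}
    if "subclones" not in skip and profiles and niche_labels:
        from . import subclones as sub_mod

        for sid in profiles:
            if not events[sid]:
                continue
            table = sub_mod.cluster_subclones(profiles[sid], mal[sid], events[sid])
            subclone_tables[sid] = sub_mod.niche_dominance(table, niche_labels[sid])

    dei = {}
    if "isoforms" not in skip and niche_labels:
        for sample, iso in zip(dataset.samples, dataset.isoforms):
            sid = sample.sample_id
            spots = niche_labels[sid].index
            iso_expr = pre_mod.lognormalize(
                iso.counts[spots].loc[iso.counts[spots].sum(axis=1) > 0]
            )
            dei[sid] = iso_mod.differential_isoforms(iso_expr, niche_labels[sid], sample_id=sid)

    composition = None
    if "deconvolve" not in skip and niche_labels:
        comps = []
        for sample, truth in zip(dataset.samples, dataset.truths):
            sid = sample.sample_id
            spots = niche_labels[sid].index
            linear = sample.counts[spots] / sample.counts[spots].sum(axis=0)
            reference = micro_mod.build_reference(profiles=truth.profiles)
            result = micro_mod.deconvolve(linear, reference)
            comps.append(micro_mod.niche_composition(result, niche_labels[sid]))
        composition = pd.concat(comps).groupby(level=0).mean()

    if out_dir:
        _write_outputs(
            out_dir, manifest, signatures, partition, niche_labels, subclone_tables, dei, composition
        )
    return PipelineResult(
        manifest=manifest,
        qc=qc_masks,
        exprs=exprs,
        cluster_labels=labels,
        signatures=signatures,
        profiles=profiles,
        events=events,
        content=contents,
        partition=partition,
        niche_labels=niche_labels,
        subclones=subclone_tables,
        dei=dei,
        composition=composition,
    )


def _write_outputs(out_dir, manifest, signatures, partition, niche_labels, subclone_tables, dei, composition):
    out_dir = Path(out_dir)
    if signatures:
        rows = []
        for sig in signatures:
            for rank, (gene, rec) in enumerate(sig.markers.iterrows(), start=1):
                rows.append((sig.sample_id, sig.cluster_id, gene, rec["log2fc"], rec["p_adj"], rank))
        pd.DataFrame(rows, columns=["sample", "cluster", "gene", "log2FC", "p_adj", "rank"]).to_csv(
            out_dir / "signatures.tsv", sep="\t", index=False
        )
    if partition:
        (out_dir / "modules.json").write_text(json.dumps(partition, indent=1))
    if niche_labels:
        pd.concat(
            [s.rename("niche").to_frame().assign(sample=sid) for sid, s in niche_labels.items()]
        ).to_csv(out_dir / "niches.tsv", sep="\t")
    if subclone_tables:
        longs = []
        for sid, table in subclone_tables.items():
            frac = table.niche_fractions.reset_index(names="subclone").melt(
                id_vars="subclone", var_name="niche", value_name="fraction"
            )
            frac["sample"] = sid
            longs.append(frac)
        pd.concat(longs).to_csv(out_dir / "subclone_niche_fractions.csv", index=False)
    if dei:
        pd.concat(dei.values()).to_csv(out_dir / "differential_isoforms.tsv", sep="\t", index=False)
    if composition is not None:
        composition.to_csv(out_dir / "niche_composition.tsv", sep="\t")
    for p in sorted(out_dir.iterdir()):
        if p.is_file() and p.name != "manifest.json":
            manifest["outputs"][p.name] = _sha256(p)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
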