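"""Shared fixtures: one default simulated dataset and the analysis chain on it.

Everything is generated programmatically at test time; session scope keeps the
expensive chain (clustering, markers, CNV, scoring) computed once.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from glioniche import cnv as cnv_mod
from glioniche import modules as mod_mod
from glioniche import preprocess as pre_mod
from glioniche.simulate import (
    CNVEvent,
    MALIGNANT_NICHES,
    SimConfig,
    SubcloneSpec,
    generate_dataset,
)


@pytest.fixture(scope="session")
def default_dataset():
    """The default study conditions: 3 samples, ~1,000 spots each, 2,000 genes."""
    return generate_dataset(SimConfig(seed=7))


@pytest.fixture(scope="session")
def analysis(default_dataset):
    """Full chain on the default dataset: QC, normalization, CNV, tumor content,
    clustering of malignant spots, marker signatures, signature scores."""
    ds = default_dataset
    out = {
        "dataset": ds,
        "exprs": {},
        "profiles": {},
        "events": {},
        "content": {},
        "malignant": {},
        "labels": {},
        "signatures": [],
        "coords": {},
        "truth_niche": {},
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for sample, truth in zip(ds.samples, ds.truths):
            sid = sample.sample_id
            qc = pre_mod.qc_filter(sample)
            passing = qc.passed[qc.passed].index
            expr = pre_mod.lognormalize(sample.counts[passing])
            reference = [b for b in truth.spots.index[truth.spots["niche"] == "normal"] if b in passing]
            profile = cnv_mod.infer_cnv(expr, sample.genes, reference)
            events = cnv_mod.designate_signature_events(profile)
            consensus, _ = cnv_mod.robust_content(profile, events)
            malignant = consensus > cnv_mod.MALIGNANT_CUTOFF
            spots = expr.columns[malignant.reindex(expr.columns, fill_value=False)]
            labels = pre_mod.spatial_cluster(expr[spots], sample.coords.loc[spots], seed=0)
            sigs = pre_mod.find_markers(expr[spots], labels, sample_id=sid)
            out["exprs"][sid] = expr
            out["profiles"][sid] = profile
            out["events"][sid] = events
            out["content"][sid] = consensus
            out["malignant"][sid] = malignant
            out["labels"][sid] = labels
            out["signatures"].extend(sigs)
            out["coords"][sid] = sample.coords
            out["truth_niche"][sid] = truth.spots["niche"]
    # majority planted niche per signature = the planted block it should join
    block = {}
    for sig in out["signatures"]:
        members = out["labels"][sig.sample_id]
        spots = members.index[members == sig.cluster_id]
        niches = out["truth_niche"][sig.sample_id].loc[spots]
        tumor = niches[niches.isin(MALIGNANT_NICHES)]
        block[sig.name] = (tumor if len(tumor) else niches).mode()[0]
    out["truth_blocks"] = {
        name: MALIGNANT_NICHES.index(b) for name, b in block.items()
    }
    # per-sample malignant-spot expression and signature score matrices
    out["mal_exprs"] = {
        sid: out["exprs"][sid][out["labels"][sid].index] for sid in out["labels"]
    }
    out["scores"] = {
        sid: mod_mod.score_signatures(out["mal_exprs"][sid], out["signatures"], seed=0)
        for sid in out["mal_exprs"]
    }
    return out


@pytest.fixture(scope="session")
def two_clone_dataset():
    """One sample with two planted subclones distinguished by a chr10 loss;
    events pronounced and contamination off so the partition logic is isolated."""
    cfg = SimConfig(
        seed=3,
        n_samples=1,
        tumor_fraction_field="plateau",
        bleed_rate=0.0,
        subclones=(
            SubcloneSpec("a", (CNVEvent("chr7", "gain", 2.0),)),
            SubcloneSpec(
                "b",
                (CNVEvent("chr7", "gain", 2.0), CNVEvent("chr10", "loss", 0.3)),
                region="sector:0-180",
            ),
        ),
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def dominance_dataset():
    """One sample with a dispersed truncal clone and a core-niche-restricted
    subclone carrying one private loss."""
    truncal = (
        CNVEvent("chr7", "gain", 2.0),
        CNVEvent("chr10", "loss", 0.3),
        CNVEvent("chr2", "loss", 0.3),
    )
    cfg = SimConfig(
        seed=5,
        n_samples=1,
        tumor_fraction_field="plateau",
        bleed_rate=0.0,
        subclones=(
            SubcloneSpec("a", truncal),
            SubcloneSpec("b", truncal + (CNVEvent("chr5", "loss", 0.3),), region="niche:core"),
        ),
    )
    return generate_dataset(cfg)


def cnv_chain(sample, truth, **kwargs):
    """Normal-reference CNV chain used by subclone and acceptance tests."""
    expr = pre_mod.lognormalize(sample.counts)
    reference = list(truth.spots.index[truth.spots["niche"] == "normal"])
    profile = cnv_mod.infer_cnv(expr, sample.genes, reference, **kwargs)
    events = cnv_mod.designate_signature_events(profile)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        consensus, _ = cnv_mod.robust_content(profile, events)
    return expr, profile, events, consensus
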