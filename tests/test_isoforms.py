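"""Isoform filters, PSI arithmetic, differential enrichment, conservation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from glioniche.isoforms import (
    associate_splicing_factors,
    compute_psi,
    conserved_switches,
    differential_isoforms,
    filter_isoforms,
)
from glioniche.preprocess import lognormalize
from glioniche.simulate import IsoformTable, MALIGNANT_NICHES


def _table(mat, isoforms, genes, spots=None) -> IsoformTable:
    spots = spots or [f"s{i}" for i in range(np.asarray(mat).shape[1])]
    counts = pd.DataFrame(mat, index=pd.Index(isoforms, name="isoform"), columns=spots)
    return IsoformTable(counts=counts, gene_of=pd.Series(dict(zip(isoforms, genes))))


class TestFilterIsoforms:
    def test_spot_count_boundaries(self):
        n_spots = 60
        mat = np.zeros((2, n_spots), dtype=int)
        mat[0, :49] = 1  # detected in 49 spots -> removed
        mat[1, :50] = 1  # detected in 50 spots -> kept
        table = _table(mat, ["i49", "i50"], ["g", "g"])
        out = filter_isoforms(table, min_spots=50, min_features=0)
        assert list(out.counts.index) == ["i50"]

    def test_feature_count_boundaries(self):
        mat = np.zeros((120, 3), dtype=int)
        mat[:99, 0] = 1  # 99 isoforms -> removed
        mat[:100, 1] = 1  # exactly 100 -> retained (strict < rule)
        mat[:, 2] = 1
        table = _table(mat, [f"i{k}" for k in range(120)], ["g"] * 120)
        out = filter_isoforms(table, min_spots=1, min_features=100)
        assert list(out.counts.columns) == ["s1", "s2"]

    def test_toy_matrix_matches_hand_filtering(self):
        mat = [[1, 1, 0], [1, 0, 0], [1, 1, 1]]
        table = _table(mat, ["a", "b", "c"], ["g1", "g1", "g2"])
        out = filter_isoforms(table, min_spots=2, min_features=2)
        # isoform b (1 spot) drops first; then spot s2 has 1 < 2 isoforms
        assert list(out.counts.index) == ["a", "c"]
        assert list(out.counts.columns) == ["s0", "s1"]

    def test_empty_result_rejected(self):
        table = _table([[1]], ["a"], ["g"])
        with pytest.raises(ValueError, match="relax"):
            filter_isoforms(table, min_spots=5, min_features=5)


class TestComputePSI:
    @staticmethod
    def _pair_table(ir, er):
        return _table([ir, er], ["gA-201", "gA-202"], ["gA", "gA"])

    def test_enumerated_values(self):
        table = self._pair_table([3, 2, 5, 0], [2, 2, 0, 7])
        pmap = compute_psi(table, "gA", ("gA-201", "gA-202"), min_reads=5)
        assert pmap.psi.iloc[0] == pytest.approx(0.6)  # 3/(3+2), exactly at threshold
        assert np.isnan(pmap.psi.iloc[1])  # 4 reads < 5 -> NA
        assert pmap.psi.iloc[2] == 1.0  # ER = 0
        assert pmap.psi.iloc[3] == 0.0

    def test_wrong_gene_pairing_rejected(self):
        table = _table([[1], [1]], ["gA-201", "gB-201"], ["gA", "gB"])
        with pytest.raises(ValueError, match="does not belong"):
            compute_psi(table, "gA", ("gA-201", "gB-201"))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        ir=st.lists(st.integers(0, 20), min_size=1, max_size=10),
        er_seed=st.integers(0, 100),
    )
    def test_psi_bounds_and_definedness(self, ir, er_seed):
        er = np.random.default_rng(er_seed).integers(0, 20, len(ir)).tolist()
        table = self._pair_table(ir, er)
        pmap = compute_psi(table, "gA", ("gA-201", "gA-202"), min_reads=5)
        total = np.asarray(ir) + np.asarray(er)
        defined = pmap.psi.notna().to_numpy()
        assert np.array_equal(defined, total >= 5)
        vals = pmap.psi[pmap.psi.notna()]
        assert ((vals >= 0) & (vals <= 1)).all()
        # agreement with a read-by-read tally
        for k, (a, b) in enumerate(zip(ir, er)):
            if a + b >= 5:
                assert pmap.psi.iloc[k] == pytest.approx(a / (a + b))


class TestDifferentialIsoforms:
    @staticmethod
    def _niche_expr(diff=True, seed=0, n_per=40):
        rng = np.random.default_rng(seed)
        labels = pd.Series(
            np.repeat(["core", "invasive"], n_per), index=[f"s{i}" for i in range(2 * n_per)]
        )
        mu = np.full((6, 2 * n_per), 5.0)
        if diff:
            mu[0, :n_per] *= 4  # isoform 0 up in core
        counts = rng.poisson(mu)
        expr = pd.DataFrame(
            np.log1p(counts), index=[f"iso{k}" for k in range(6)], columns=labels.index
        )
        return expr, labels

    def test_flat_isoform_yields_no_records(self):
        expr, labels = self._niche_expr(diff=False)
        out = differential_isoforms(expr, labels)
        assert out.empty

    def test_planted_difference_detected_with_enriched_side(self):
        expr, labels = self._niche_expr(diff=True)
        out = differential_isoforms(expr, labels)
        hit = out[out["isoform"] == "iso0"]
        assert len(hit) == 1
        assert hit.iloc[0]["enriched_niche"] == "core"
        assert hit.iloc[0]["contrast_niche"] == "invasive"

    def test_small_niche_skipped_with_warning(self):
        expr, labels = self._niche_expr()
        labels.iloc[:2] = "tiny"
        labels.iloc[2:40] = "core"
        with pytest.warns(UserWarning, match="tiny"):
            differential_isoforms(expr, labels)

    def test_shuffled_labels_rarely_fire(self):
        rng = np.random.default_rng(9)
        hits = 0
        for i in range(20):
            expr, labels = self._niche_expr(diff=False, seed=100 + i)
            shuffled = pd.Series(rng.permutation(labels.to_numpy()), index=labels.index)
            hits += len(differential_isoforms(expr, shuffled))
        assert hits <= 12  # ~6 tests x 20 reps at p<0.01 -> expect ~1


class TestConservedSwitches:
    @staticmethod
    def _rec(iso, niche, sample):
        return dict(
            isoform=iso, enriched_niche=niche, contrast_niche="x", log2fc=1.0, p=1e-5,
            pct=0.5, sample_id=sample,
        )

    def test_direction_mismatch_not_conserved(self):
        a = pd.DataFrame([self._rec("i1", "core", "s1")])
        b = pd.DataFrame([self._rec("i1", "hypoxic", "s2")])
        gene_of = pd.Series({"i1": "g1"})
        conserved, switches = conserved_switches([a, b], gene_of)
        assert conserved.empty and switches == []

    def test_switch_gene_requires_two_isoforms_in_different_niches(self):
        a = pd.DataFrame([self._rec("i1", "core", "s1"), self._rec("i2", "invasive", "s1")])
        b = pd.DataFrame([self._rec("i1", "core", "s2"), self._rec("i2", "invasive", "s2")])
        gene_of = pd.Series({"i1": "g1", "i2": "g1"})
        conserved, switches = conserved_switches([a, b], gene_of)
        assert set(conserved["isoform"]) == {"i1", "i2"}
        assert switches == ["g1"]

    def test_same_niche_isoforms_are_not_a_switch(self):
        a = pd.DataFrame([self._rec("i1", "core", "s1"), self._rec("i2", "core", "s1")])
        b = pd.DataFrame([self._rec("i1", "core", "s2"), self._rec("i2", "core", "s2")])
        conserved, switches = conserved_switches([a, b], pd.Series({"i1": "g1", "i2": "g1"}))
        assert switches == []

    def test_single_sample_rejected(self):
        a = pd.DataFrame([self._rec("i1", "core", "s1")])
        with pytest.raises(ValueError, match="two samples"):
            conserved_switches([a], pd.Series({"i1": "g1"}))


class TestAssociateSplicingFactors:
    def test_sf_equal_to_psi_is_a_consistent_candidate(self):
        rng = np.random.default_rng(0)
        n = 80
        labels = pd.Series(np.repeat(["core", "invasive"], n // 2), index=[f"s{i}" for i in range(n)])
        psi_vals = np.where(labels == "core", 0.8, 0.2) + rng.normal(0, 0.03, n)

        class PMap:
            gene = "gX"
            psi = pd.Series(psi_vals, index=labels.index)

        sf_expr = pd.DataFrame([psi_vals], index=["SF1"], columns=labels.index)
        out = associate_splicing_factors(sf_expr, [PMap()], labels)
        row = out[(out["sf"] == "SF1") & (out["gene"] == "gX")].iloc[0]
        assert row["rho"] > 0.95
        assert row["candidate"] and row["consistent"]

    def test_independent_sf_is_not_a_candidate(self):
        rng = np.random.default_rng(1)
        n = 200
        labels = pd.Series(np.repeat(["core", "invasive"], n // 2), index=[f"s{i}" for i in range(n)])
        psi_vals = np.where(labels == "core", 0.8, 0.2)

        class PMap:
            gene = "gX"
            psi = pd.Series(psi_vals, index=labels.index)

        # differential between the niches but uncorrelated with PSI within them:
        # permute the niche-wise values so rank association with PSI is destroyed
        sf = np.concatenate([rng.normal(0, 1, n // 2), rng.normal(0, 1, n // 2)])
        sf_expr = pd.DataFrame([sf], index=["SFnull"], columns=labels.index)
        out = associate_splicing_factors(sf_expr, [PMap()], labels)
        if len(out):  # SF may not even be differential; if it is, rho must be small
            assert not out.iloc[0]["candidate"]

    def test_too_few_defined_spots_skipped(self, caplog):
        labels = pd.Series(["core"] * 10 + ["invasive"] * 10, index=[f"s{i}" for i in range(20)])

        class PMap:
            gene = "gX"
            psi = pd.Series(np.nan, index=labels.index)

        sf_expr = pd.DataFrame(np.ones((1, 20)), index=["SF1"], columns=labels.index)
        with caplog.at_level("WARNING"):
            out = associate_splicing_factors(sf_expr, [PMap()], labels)
        assert out.empty


def test_planted_splicing_factors_recovered(default_dataset):
    """Generator-planted SF drivers correlate with the PSI of their switch genes."""
    ds = default_dataset
    sample, iso, truth = ds.samples[0], ds.isoforms[0], ds.truths[0]
    mal = truth.spots["niche"].isin(MALIGNANT_NICHES)
    spots = truth.spots.index[mal]
    expr = lognormalize(sample.counts[spots])
    labels = truth.spots.loc[spots, "niche"]
    recovered = 0
    for sf_gene, rec in truth.sf_drivers.iterrows():
        # a switch gene driven between the same niche pair
        sw = truth.switches[
            (truth.switches["niche_high"] == rec["niche_high"])
            & (truth.switches["niche_low"] == rec["niche_low"])
        ].iloc[0]
        pmap = compute_psi(iso, sw.name, (sw["iso_a"], sw["iso_b"]))
        pmap.psi = pmap.psi.reindex(spots)
        out = associate_splicing_factors(
            expr.loc[[sf_gene]], [pmap], labels,
            niche_pairs={sw.name: (rec["niche_high"], rec["niche_low"])},
        )
        if len(out) and out.iloc[0]["candidate"] and out.iloc[0]["consistent"]:
            recovered += 1
    assert recovered >= len(truth.sf_drivers) - 1
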