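"""CNV scoring oracle checks, event designation, and the tumor-content formula."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from glioniche.cnv import (
    CNVProfile,
    SignatureEvent,
    default_candidate_spots,
    designate_signature_events,
    infer_cnv,
    moving_average,
    mutation_colocalization,
    robust_content,
    tumor_content,
)


def brute_force_moving_average(x, window):
    h = window // 2
    out = np.empty(len(x), dtype=float)
    for i in range(len(x)):
        lo = max(0, i - h)
        hi = min(len(x), i + (window - 1 - h) + 1)
        out[i] = np.mean(x[lo:hi])
    return out


class TestMovingAverage:
    def test_matches_brute_force_on_toy_chromosome(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=10)
        assert np.max(np.abs(moving_average(x, 3) - brute_force_moving_average(x, 3))) < 1e-10

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        n=st.integers(2, 40),
        window=st.integers(1, 50),
        seed=st.integers(0, 1000),
    )
    def test_matches_brute_force_generally(self, n, window, seed):
        x = np.random.default_rng(seed).normal(size=n)
        w = min(window, n)
        assert np.allclose(moving_average(x, w), brute_force_moving_average(x, w), atol=1e-10)


def _annotation(chrom_sizes: dict) -> pd.DataFrame:
    rows = []
    for chrom, n in chrom_sizes.items():
        for i in range(n):
            rows.append((f"{chrom}_g{i}", chrom, (i + 1) * 100))
    return pd.DataFrame(rows, columns=["gene", "chrom", "start"]).set_index("gene")


class TestInferCNV:
    def test_null_spots_score_near_one(self):
        rng = np.random.default_rng(2)
        ann = _annotation({"chr1": 150, "chr2": 150})
        expr = pd.DataFrame(
            rng.normal(1.0, 0.05, size=(300, 90)),
            index=ann.index,
            columns=[f"s{i}" for i in range(90)],
        )
        ref = [f"s{i}" for i in range(60)]
        prof = infer_cnv(expr, ann, ref, window=100)
        assert np.abs(prof.scores.to_numpy() - 1.0).max() < 0.05
        assert abs(prof.scores.loc[ref].mean().mean() - 1.0) < 0.02

    def test_planted_gain_pushes_event_region_over_threshold(self):
        """A 1.5x chromosome gain at tumor fraction 1 crosses the 1.2 line."""
        rng = np.random.default_rng(3)
        ann = _annotation({"chr1": 100, "chr2": 100, "chr3": 100})
        base = rng.normal(1.0, 0.2, size=(300, 80))
        base[:100, 40:] += np.log(1.5)  # chr1 gain in evaluation spots
        expr = pd.DataFrame(base, index=ann.index, columns=[f"s{i}" for i in range(80)])
        prof = infer_cnv(expr, ann, [f"s{i}" for i in range(40)], window=100)
        chr1 = prof.chromosome_slice("chr1")
        tumor_scores = prof.scores.iloc[40:, chr1]
        assert tumor_scores.mean().mean() > 1.2
        assert prof.scores.to_numpy().min() >= 0.7 - 1e-12
        assert prof.scores.to_numpy().max() <= 1.3 + 1e-12

    def test_small_chromosome_shrinks_window_with_warning(self):
        rng = np.random.default_rng(4)
        ann = _annotation({"chr1": 150, "chr2": 5})
        expr = pd.DataFrame(
            rng.normal(size=(155, 20)), index=ann.index, columns=[f"s{i}" for i in range(20)]
        )
        with pytest.warns(UserWarning, match="window shrunk"):
            infer_cnv(expr, ann, ["s0", "s1"], window=100)

    def test_empty_reference_rejected(self):
        ann = _annotation({"chr1": 10})
        expr = pd.DataFrame(np.ones((10, 4)), index=ann.index, columns=list("abcd"))
        with pytest.raises(ValueError, match="reference"):
            infer_cnv(expr, ann, [])


def _profile_from_scores(scores: np.ndarray, chroms: list) -> CNVProfile:
    gene_order = pd.DataFrame(
        {"chrom": chroms, "start": np.arange(len(chroms))},
        index=[f"w{i}" for i in range(len(chroms))],
    )
    df = pd.DataFrame(scores, columns=gene_order.index, index=[f"s{i}" for i in range(len(scores))])
    return CNVProfile(scores=df, gene_order=gene_order, reference_spots=[], window=1)


class TestEventDesignation:
    def test_flat_profile_yields_no_events(self):
        prof = _profile_from_scores(np.ones((5, 40)), ["chr1"] * 40)
        assert designate_signature_events(prof, candidate_spots=["s0", "s1"], min_region_windows=5) == []

    def test_gain_and_loss_on_different_chromosomes(self):
        scores = np.ones((4, 60))
        scores[:, :30] = 1.25  # chr1 gain
        scores[:, 30:] = 0.75  # chr2 loss
        prof = _profile_from_scores(scores, ["chr1"] * 30 + ["chr2"] * 30)
        events = designate_signature_events(prof, candidate_spots=["s0", "s1"], min_region_windows=10)
        assert {(e.chrom, e.direction) for e in events} == {("chr1", "gain"), ("chr2", "loss")}

    def test_short_regions_discarded(self):
        scores = np.ones((4, 40))
        scores[:, 5:9] = 1.3  # 4 windows < min 10
        prof = _profile_from_scores(scores, ["chr1"] * 40)
        assert designate_signature_events(prof, candidate_spots=["s0"], min_region_windows=10) == []

    def test_default_candidates_are_highest_deviation(self):
        scores = np.ones((10, 20))
        scores[0] = 1.3
        prof = _profile_from_scores(scores, ["chr1"] * 20)
        assert default_candidate_spots(prof, fraction=0.1) == ["s0"]


class TestTumorContentFormula:
    @staticmethod
    def _gain_profile(a_values):
        # one-window-per-spot construction: event of width 1 whose mean is a_values
        scores = np.asarray(a_values, dtype=float)[:, None]
        prof = _profile_from_scores(scores, ["chr1"])
        event = SignatureEvent("chr1", 0, 1, "gain", float(np.mean(a_values)))
        return prof, event

    def test_gain_formula_exact(self):
        prof, event = self._gain_profile([1.3, 1.15, 1.0])
        tc = tumor_content(prof, event)
        assert tc.content.iloc[0] == pytest.approx(1.0, abs=1e-12)
        assert tc.content.iloc[1] == pytest.approx(0.5, abs=1e-12)  # (1.15-1)/(1.3-1)
        assert tc.content.iloc[2] == pytest.approx(0.0, abs=1e-12)

    def test_loss_formula_exact(self):
        scores = np.array([[0.7], [0.85], [1.0]])
        prof = _profile_from_scores(scores, ["chr1"])
        event = SignatureEvent("chr1", 0, 1, "loss", 0.85)
        tc = tumor_content(prof, event)
        assert tc.content.iloc[0] == pytest.approx(1.0, abs=1e-12)
        assert tc.content.iloc[1] == pytest.approx(0.5, abs=1e-12)  # (1-0.85)/(1-0.7)
        assert tc.content.iloc[2] == pytest.approx(0.0, abs=1e-12)

    def test_malignant_cutoff_is_strict(self):
        # (1.0625-1)/(1.3125-1) = 0.2 exactly in binary arithmetic
        prof, event = self._gain_profile([1.3125, 1.0625, 1.0625001])
        tc = tumor_content(prof, event)
        assert tc.content.iloc[1] == 0.2
        assert not tc.malignant.iloc[1]  # C == 0.2 -> not malignant
        assert tc.malignant.iloc[0] and tc.malignant.iloc[2]

    def test_degenerate_denominator_rejected(self):
        prof, event = self._gain_profile([1.0, 1.0])
        with pytest.raises(ValueError, match="no signal"):
            tumor_content(prof, event)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(1.0, 1.3), min_size=3, max_size=12, unique=True))
    def test_monotone_in_region_score(self, a_values):
        from hypothesis import assume

        assume(max(a_values) > 1.0 + 1e-6)
        prof, event = self._gain_profile(a_values)
        tc = tumor_content(prof, event)
        order = np.argsort(a_values)
        assert (np.diff(tc.content.to_numpy()[order]) >= -1e-12).all()


class TestRobustContent:
    @staticmethod
    def _three_event_profile(columns):
        scores = np.asarray(columns, dtype=float).T  # spots x 3 windows
        chroms = ["chr1", "chr2", "chr3"]
        prof = _profile_from_scores(scores, chroms)
        events = [SignatureEvent(c, i, i + 1, "gain", 1.3) for i, c in enumerate(chroms)]
        return prof, events

    def test_identical_events_give_identical_consensus(self):
        col = [1.3, 1.15, 1.0]
        prof, events = self._three_event_profile([col, col, col])
        consensus, concordance = robust_content(prof, events)
        assert np.allclose(consensus, [1.0, 0.5, 0.0])
        assert np.allclose(concordance.to_numpy(), 1.0)

    def test_consensus_is_per_spot_median(self):
        # one spot with per-event C = (0.2, 0.4, 0.9) -> 0.4
        cols = [[1.3, 1.0 + 0.3 * 0.2], [1.3, 1.0 + 0.3 * 0.4], [1.3, 1.0 + 0.3 * 0.9]]
        prof, events = self._three_event_profile(cols)
        consensus, _ = robust_content(prof, events)
        assert consensus.iloc[1] == pytest.approx(0.4, abs=1e-12)

    def test_fewer_than_three_events_warns(self):
        prof, events = self._three_event_profile([[1.3, 1.1], [1.3, 1.1], [1.3, 1.1]])
        with pytest.warns(UserWarning, match="less robust"):
            robust_content(prof, events[:2])


class TestMutationColocalization:
    def test_toy_fraction_two_thirds(self):
        var = pd.DataFrame(
            {"mutant": [2, 1, 5, 0, 0], "total": [3, 1, 6, 2, 0]},
            index=[f"s{i}" for i in range(5)],
        )
        mal = pd.Series([True, True, False, False, True], index=var.index)
        frac, table = mutation_colocalization(var, mal)
        assert frac == pytest.approx(2 / 3)
        assert table.loc["variant+", "malignant"] == 2
        assert table.loc["variant+", "non-malignant"] == 1

    def test_no_variant_positive_spots_gives_nan(self):
        var = pd.DataFrame({"mutant": [0, 0], "total": [1, 0]}, index=["a", "b"])
        frac, _ = mutation_colocalization(var, pd.Series([True, False], index=var.index))
        assert np.isnan(frac)

    def test_variant_spots_colocalize_with_malignant_calls(self, analysis):
        ds = analysis["dataset"]
        fracs = []
        for sample, var in zip(ds.samples, ds.variants):
            sid = sample.sample_id
            frac, _ = mutation_colocalization(var, analysis["malignant"][sid])
            if not np.isnan(frac):
                fracs.append(frac)
        assert fracs and np.mean(fracs) > 0.8
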