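"""Intensity filtration, fold changes, SAM d-statistics and permutation FDR."""

import numpy as np
import pandas as pd
import pytest

from mapsig import (
    CellLineSimConfig,
    ExpressionMatrix,
    ProbeAnnotation,
    SAMDifferential,
    estimate_intensity_cutoff,
    filter_low_intensity,
    fold_changes,
    sam_d_statistics,
    sam_permutation_fdr,
    select_differential_genes,
    simulate_cell_line_arrays,
)
from mapsig.diffexpr import _enumerate_relabelings


def mixture_matrix(seed=0, n_bg=400, n_sig=400):
    """Low-intensity irreproducible background vs bright reproducible signal.

    Background scatters around 100 with array noise large enough that
    replicate log2 ratios routinely exceed 1; signal sits near 1000 with
    tight replicates.
    """
    rng = np.random.default_rng(seed)
    bg = np.clip(rng.normal(100, 60, (n_bg, 4)), 5, None)
    sig = 1000 + rng.normal(0, 100, (n_sig, 4))
    data = pd.DataFrame(
        np.vstack([bg, sig]),
        index=[f"b{i}" for i in range(n_bg)] + [f"s{i}" for i in range(n_sig)],
        columns=["muc1cd_1", "muc1cd_2", "vector_1", "vector_2"],
    )
    return ExpressionMatrix(data, "raw")


PAIRS = [("muc1cd_1", "muc1cd_2"), ("vector_1", "vector_2")]
LABELS = {
    "muc1cd_1": "muc1cd", "muc1cd_2": "muc1cd",
    "vector_1": "vector", "vector_2": "vector",
}


class TestIntensityCutoff:
    def test_mixture_cutoff_separates_background(self):
        m = mixture_matrix()
        cutoff = estimate_intensity_cutoff(m, PAIRS)
        bg_mean = m.data.iloc[:400].mean(axis=1)
        sig_mean = m.data.iloc[400:].mean(axis=1)
        # lands above the background bulk and below the signal population,
        # leaving only the upper tail of the background misclassified
        assert float(bg_mean.quantile(0.75)) < cutoff < float(sig_mean.min())
        assert (bg_mean >= cutoff).mean() < 0.10
        assert (sig_mean >= cutoff).mean() > 0.95

    def test_all_reproducible_returns_minimum_candidate(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(100, 1000, 50)
        data = pd.DataFrame(
            np.tile(base[:, None], 4) * rng.uniform(0.99, 1.01, (50, 4)),
            index=[f"p{i}" for i in range(50)],
            columns=list(LABELS),
        )
        m = ExpressionMatrix(data, "raw")
        cutoff = estimate_intensity_cutoff(m, PAIRS)
        assert cutoff == pytest.approx(m.data.mean(axis=1).min())
        assert filter_low_intensity(m, cutoff - 1).shape[0] == 50

    def test_single_candidate_is_returned(self):
        m = mixture_matrix(seed=2)
        c = estimate_intensity_cutoff(m, PAIRS, n_candidates=1)
        assert c == pytest.approx(float(m.data.mean(axis=1).min()))

    def test_no_replicate_pairs_is_error(self):
        with pytest.raises(ValueError):
            estimate_intensity_cutoff(mixture_matrix(), [])


class TestFiltration:
    def test_rule_any_array_above_cutoff(self):
        data = pd.DataFrame(
            [[10.0, 10, 10, 10], [10, 500, 10, 10], [900, 900, 900, 900]],
            index=["low", "one_high", "high"],
            columns=list(LABELS),
        )
        out = filter_low_intensity(ExpressionMatrix(data, "raw"), 100)
        assert out.feature_ids == ["one_high", "high"]

    def test_signal_retention_on_mixture(self):
        m = mixture_matrix(seed=3)
        cutoff = estimate_intensity_cutoff(m, PAIRS)
        kept = set(filter_low_intensity(m, cutoff).feature_ids)
        signal = {f"s{i}" for i in range(400)}
        assert len(kept & signal) / len(signal) >= 0.95

    def test_cutoff_removing_everything_is_error(self):
        m = mixture_matrix()
        with pytest.raises(ValueError):
            filter_low_intensity(m, 1e9)


class TestFoldChange:
    @pytest.mark.parametrize(
        "cond,ctrl,expected",
        [((4.0, 4.0), (2.0, 2.0), 2.0),
         ((3.0, 3.0), (2.0, 2.0), 1.5),
         ((2.0, 8.0), (2.0, 2.0), 2.5)],
    )
    def test_linear_mean_ratio(self, cond, ctrl, expected):
        data = pd.DataFrame([list(cond) + list(ctrl)], index=["p"], columns=list(LABELS))
        fold = fold_changes(ExpressionMatrix(data, "raw"), LABELS, "muc1cd", "vector")
        assert fold.loc["p"] == pytest.approx(expected)


class TestDStatistics:
    def test_hand_computed_four_array_case(self):
        # probe log2 values: condition {3, 5}, control {1, 2}
        x = np.array([[3.0, 5.0, 1.0, 2.0], [2.0, 2.0, 2.0, 2.0]])
        d, s0, s = sam_d_statistics(x, [0, 1], [2, 3], s0_policy=0.1)
        diff = 4.0 - 1.5
        ss = ((3 - 4) ** 2 + (5 - 4) ** 2) + ((1 - 1.5) ** 2 + (2 - 1.5) ** 2)
        s_hand = np.sqrt((1 / 2 + 1 / 2) * ss / 2)
        assert d[0] == pytest.approx(diff / (s_hand + 0.1), abs=1e-12)

    def test_equal_group_means_give_zero(self):
        x = np.array([[1.0, 3.0, 2.0, 2.0]])
        d, _, _ = sam_d_statistics(x, [0, 1], [2, 3], s0_policy=0.5)
        assert d[0] == 0.0

    def test_huge_s0_shrinks_d_to_zero(self):
        rng = np.random.default_rng(0)
        x = rng.normal(10, 1, (50, 4))
        d, _, _ = sam_d_statistics(x, [0, 1], [2, 3], s0_policy=1e12)
        assert np.abs(d).max() < 1e-9

    def test_antisymmetric_under_label_swap(self):
        rng = np.random.default_rng(1)
        x = rng.normal(10, 1, (100, 4))
        d1, s0, _ = sam_d_statistics(x, [0, 1], [2, 3])
        d2, _, _ = sam_d_statistics(x, [2, 3], [0, 1], s0_policy=s0)
        np.testing.assert_allclose(d1, -d2, rtol=1e-12)

    def test_single_array_condition_is_error(self):
        with pytest.raises(ValueError):
            sam_d_statistics(np.ones((5, 3)), [0], [1, 2])


class TestPermutationFdr:
    def test_two_plus_two_enumeration_is_exhaustive(self):
        rel = _enumerate_relabelings(2, 2)
        assert len(rel) == 6  # 4!/(2!2!)
        assert ([0, 1], [2, 3]) in [(a, b) for a, b in rel]  # identity included

    def test_called_is_monotone_in_delta(self):
        rng = np.random.default_rng(2)
        x = rng.normal(10, 0.3, (500, 4))
        x[:30, :2] += 1.5
        ft, _ = sam_permutation_fdr(x, [0, 1], [2, 3])
        called = ft.table["called"].to_numpy()
        assert (np.diff(called) <= 0).all()

    def test_delta_beyond_max_has_no_calls_and_is_excluded(self):
        rng = np.random.default_rng(3)
        x = rng.normal(10, 0.3, (200, 4))
        grid = [0.1, 1e6]
        ft, sig = sam_permutation_fdr(x, [0, 1], [2, 3], delta_grid=grid)
        row = ft.table[ft.table["delta"] == 1e6].iloc[0]
        assert row["called"] == 0 and row["fdr"] == 0.0
        assert ft.chosen_delta == 0.1  # the only delta with calls

    def test_fdr_within_unit_interval(self):
        rng = np.random.default_rng(4)
        x = rng.normal(10, 0.3, (300, 4))
        ft, _ = sam_permutation_fdr(x, [0, 1], [2, 3])
        assert ((ft.table["fdr"] >= 0) & (ft.table["fdr"] <= 1)).all()

    def test_fewer_than_two_permutations_is_error(self):
        with pytest.raises(ValueError):
            sam_permutation_fdr(np.ones((5, 2)), [0, 1], [])


class TestGeneSelection:
    def test_conjunction_rule(self):
        fold = pd.Series({"p1": 3.0, "p2": 3.0, "p3": 0.4, "p4": 1.2})
        called = pd.Series({"p1": False, "p2": True, "p3": True, "p4": True})
        ann = ProbeAnnotation({p: p.upper() for p in fold.index})
        # p1: fold but no SAM call; p4: call but no fold
        assert select_differential_genes(fold, called, ann) == ["P2", "P3"]

    def test_probes_collapse_to_unique_genes(self):
        fold = pd.Series({"p1": 2.5, "p2": 2.5})
        called = pd.Series({"p1": True, "p2": True})
        ann = ProbeAnnotation({"p1": "G", "p2": "G"})
        assert select_differential_genes(fold, called, ann) == ["G"]

    def test_empty_selection_warns_and_returns_empty(self, caplog):
        fold = pd.Series({"p1": 1.0})
        called = pd.Series({"p1": False})
        with caplog.at_level("WARNING", logger="mapsig.diffexpr"):
            out = select_differential_genes(fold, called, ProbeAnnotation({"p1": "G"}))
        assert out == [] and "no gene" in caplog.text

    def test_planted_gene_recovery_at_defaults(self):
        """Planted 2.5-fold genes are recovered with high recall/precision."""
        recs, precs = [], []
        for seed in range(5):
            m, truth = simulate_cell_line_arrays(
                CellLineSimConfig(seed=seed, n_planted_down=0)
            )
            lab = {s: s.rsplit("_", 1)[0] for s in m.sample_ids}
            filtered = filter_low_intensity(m, estimate_intensity_cutoff(m, PAIRS))
            sam = SAMDifferential().fit(filtered, lab)
            genes = set(sam.select_genes(truth.annotation))
            planted = {truth.annotation.mapping[p] for p in truth.up_probes}
            tp = len(genes & planted)
            recs.append(tp / len(planted))
            precs.append(tp / max(len(genes), 1))
        assert np.mean(recs) >= 0.9
        assert np.mean(precs) >= 0.8


def test_estimator_result_invariants():
    m, truth = simulate_cell_line_arrays(CellLineSimConfig(seed=8))
    lab = {s: s.rsplit("_", 1)[0] for s in m.sample_ids}
    sam = SAMDifferential().fit(m, lab)
    r = sam.result_
    passes_fold = (r["fold_change"] >= 2.0) | (r["fold_change"] <= 0.5)
    assert (r.loc[r["significant"], "sam_called"]).all()
    assert passes_fold[r["significant"]].all()
    assert 0.0 <= sam.fdr_at_delta_ <= 1.0
    assert sam.s0_ >= 0
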