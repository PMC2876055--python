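"""Uniform-gene elimination, k-means partition, F/t selection, AUC, scoring."""

import inspect

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mapsig import (
    CohortSimConfig,
    SignatureDeriver,
    SignatureSet,
    cohort_median_normalize,
    gene_auc,
    kmeans_partition,
    maps_score,
    remove_uniform_genes,
    select_discriminant_genes,
    select_signature,
    simulate_cohort,
)
from mapsig.signature import EXPRESSOR, OTHER, PatientPartition
from tests.conftest import make_normalized


def make_partition(pos_ids, neg_ids):
    labels = pd.Series(
        [EXPRESSOR] * len(pos_ids) + [OTHER] * len(neg_ids),
        index=list(pos_ids) + list(neg_ids),
    )
    return PatientPartition(labels, 2, 0.0, 1)


def brute_force_auc(pos, neg):
    wins = ties = 0
    for a in pos:
        for b in neg:
            wins += a > b
            ties += a == b
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestUniformGenes:
    def test_constant_gene_removed_and_spread_gene_kept(self):
        rng = np.random.default_rng(0)
        m = make_normalized(
            np.vstack([np.zeros(40), np.linspace(-2, 2, 40)]),
            feature_ids=["flat", "spread"],
        )
        out = remove_uniform_genes(m, spread_threshold=0.5)
        assert out.feature_ids == ["spread"]

    def test_threshold_compares_iqr(self):
        vals = np.tile([-1.0, 1.0], 20)  # IQR 2.0
        m = make_normalized(vals[None, :], feature_ids=["g"])
        assert remove_uniform_genes(m, 0.5).feature_ids == ["g"]

    def test_planted_uniform_genes_eliminated(self):
        expr, _, truth = simulate_cohort(CohortSimConfig(seed=11))
        norm = cohort_median_normalize(expr)
        out = remove_uniform_genes(norm)
        removed = set(norm.feature_ids) - set(out.feature_ids)
        frac = len(removed & set(truth.uniform_genes)) / len(truth.uniform_genes)
        assert frac >= 0.95

    def test_all_uniform_is_error(self):
        m = make_normalized(np.zeros((3, 10)))
        with pytest.raises(ValueError):
            remove_uniform_genes(m)


class TestKMeans:
    def test_separated_clouds_recovered_exactly(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 0.1, (5, 30))
        b = rng.normal(10, 0.1, (5, 30))
        m = make_normalized(np.hstack([a, b]))
        part = kmeans_partition(m, seed=0)
        first = part.labels.iloc[:30]
        second = part.labels.iloc[30:]
        assert first.nunique() == 1 and second.nunique() == 1
        assert second.iloc[0] == EXPRESSOR  # higher-mean cloud is the expressor

    def test_two_repeated_points_give_zero_inertia(self):
        m = make_normalized(np.array([[0.0, 0, 5, 5], [0, 0, 5, 5]]))
        part = kmeans_partition(m, seed=0)
        assert part.inertia == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(2)
        m = make_normalized(rng.normal(0, 1, (10, 60)))
        p1 = kmeans_partition(m, seed=7)
        p2 = kmeans_partition(m, seed=7)
        assert p1.labels.equals(p2.labels)

    def test_k_exceeding_patients_is_error(self):
        m = make_normalized(np.zeros((2, 3)) + np.arange(3))
        with pytest.raises(ValueError):
            kmeans_partition(m, k=4)


class TestDiscriminantSelection:
    def test_large_shift_is_selected(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, (1, 400))
        x[0, :200] += 5.0
        m = make_normalized(x, feature_ids=["g"])
        part = make_partition(m.sample_ids[:200], m.sample_ids[200:])
        rec = select_discriminant_genes(m, part)
        assert rec.loc[rec["gene"] == "g", "selected"].item()

    def test_identical_values_not_selected(self):
        m = make_normalized(np.ones((1, 20)), feature_ids=["g"])
        part = make_partition(m.sample_ids[:10], m.sample_ids[10:])
        rec = select_discriminant_genes(m, part)
        assert not rec["selected"].any()

    def test_type_one_error_near_alpha(self):
        rng = np.random.default_rng(4)
        m = make_normalized(rng.normal(0, 1, (2000, 200)))
        part = make_partition(m.sample_ids[:100], m.sample_ids[100:])
        rec = select_discriminant_genes(m, part, alpha=0.05)
        rate = rec["selected"].mean()
        assert abs(rate - 0.05) < 0.02

    def test_bh_correction_is_more_conservative(self):
        rng = np.random.default_rng(5)
        m = make_normalized(rng.normal(0, 1, (500, 100)))
        part = make_partition(m.sample_ids[:50], m.sample_ids[50:])
        plain = select_discriminant_genes(m, part)["selected"].sum()
        bh = select_discriminant_genes(m, part, use_bh_correction=True)["selected"].sum()
        assert bh <= plain

    def test_tiny_cluster_is_error(self):
        m = make_normalized(np.random.default_rng(6).normal(0, 1, (3, 5)))
        part = make_partition(m.sample_ids[:1], m.sample_ids[1:])
        with pytest.raises(ValueError):
            select_discriminant_genes(m, part)


class TestGeneAuc:
    def test_perfect_separation(self):
        part = make_partition(["a", "b"], ["c", "d"])
        v = pd.Series({"a": 3.0, "b": 4.0, "c": 1.0, "d": 2.0})
        assert gene_auc(v, part) == 1.0

    def test_interleaved_values(self):
        # brute force over the 4 pairs: only (3,2) is a win -> 0.25
        part = make_partition(["a", "b"], ["c", "d"])
        v = pd.Series({"a": 1.0, "b": 3.0, "c": 2.0, "d": 4.0})
        assert gene_auc(v, part) == 0.25

    def test_tie_gets_half_credit(self):
        part = make_partition(["a"], ["b"])
        assert gene_auc(pd.Series({"a": 1.0, "b": 1.0}), part) == 0.5

    def test_empty_cluster_is_error(self):
        labels = pd.Series([EXPRESSOR, EXPRESSOR], index=["a", "b"])
        part = PatientPartition(labels, 2, 0.0, 1)
        with pytest.raises(ValueError):
            gene_auc(pd.Series({"a": 1.0, "b": 2.0}), part)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        pos=st.lists(st.integers(0, 8), min_size=1, max_size=12),
        neg=st.lists(st.integers(0, 8), min_size=1, max_size=12),
    )
    def test_equals_brute_force_pair_enumeration(self, pos, neg):
        ids_p = [f"p{i}" for i in range(len(pos))]
        ids_n = [f"n{i}" for i in range(len(neg))]
        part = make_partition(ids_p, ids_n)
        v = pd.Series(
            [float(x) for x in pos] + [float(x) for x in neg], index=ids_p + ids_n
        )
        assert gene_auc(v, part) == pytest.approx(
            brute_force_auc(pos, neg), abs=1e-12
        )

    def test_negation_complements_auc_without_ties(self):
        rng = np.random.default_rng(7)
        v = rng.permutation(20).astype(float)  # all distinct
        ids = [f"s{i}" for i in range(20)]
        part = make_partition(ids[:8], ids[8:])
        s = pd.Series(v, index=ids)
        assert gene_auc(s, part) + gene_auc(-s, part) == pytest.approx(1.0)


class TestSelectSignature:
    def records(self, aucs, direction="up"):
        return pd.DataFrame(
            {
                "gene": [f"G{i}" for i in range(len(aucs))],
                "auc": aucs,
                "direction": [direction] * len(aucs),
            }
        )

    def test_published_auc_profile_selects_seven(self):
        aucs = [0.99, 0.98, 0.98, 0.98, 0.97, 0.97, 0.97, 0.94]
        sig = select_signature(self.records(aucs), auc_cutoff=0.95)
        assert len(sig) == 7
        assert sig.auc[sig.gene_symbols[0]] == 0.99

    def test_cutoff_is_strict(self):
        sig = select_signature(self.records([0.95, 0.95]), auc_cutoff=0.95)
        assert len(sig) == 0

    def test_single_gene_signature(self):
        sig = select_signature(self.records([0.96, 0.90]))
        assert sig.gene_symbols == ["G0"]

    def test_down_oriented_gene_is_folded(self):
        rec = self.records([0.03], direction="down")  # 1 - 0.03 = 0.97
        sig = select_signature(rec)
        assert sig.gene_symbols == ["G0"]
        assert sig.direction["G0"] == "down"
        assert sig.auc["G0"] == pytest.approx(0.97)

    def test_ordering_auc_desc_then_alphabetical(self):
        rec = pd.DataFrame(
            {"gene": ["B", "A", "C"], "auc": [0.97, 0.99, 0.97],
             "direction": ["up"] * 3}
        )
        assert select_signature(rec).gene_symbols == ["A", "B", "C"]


class TestMapsScore:
    def sig(self, genes=("G1", "G2"), direction="up"):
        return SignatureSet(
            list(genes), {g: 0.99 for g in genes}, {g: direction for g in genes}
        )

    def test_zero_score_is_negative_class(self):
        m = make_normalized(np.zeros((2, 3)), feature_ids=["G1", "G2"])
        out = maps_score(m, self.sig())
        assert (out["score"] == 0).all()
        assert (out["maps_class"] == "MAPS_neg").all()

    def test_uniform_plus_one_scores_one(self):
        m = make_normalized(np.ones((2, 3)), feature_ids=["G1", "G2"])
        out = maps_score(m, self.sig())
        assert (out["score"] == 1.0).all()
        assert (out["maps_class"] == "MAPS_pos").all()

    def test_missing_gene_uses_remaining(self):
        sig = SignatureSet(
            ["G1", "G2", "PRC1"], {g: 0.99 for g in ["G1", "G2", "PRC1"]},
            {g: "up" for g in ["G1", "G2", "PRC1"]},
        )
        m = make_normalized(np.ones((2, 3)), feature_ids=["G1", "G2"])
        out = maps_score(m, sig)
        assert (out["n_genes_used"] == 2).all()

    def test_no_gene_present_is_error(self):
        m = make_normalized(np.ones((1, 3)), feature_ids=["X"])
        with pytest.raises(ValueError):
            maps_score(m, self.sig())

    def test_down_genes_sign_flipped(self):
        m = make_normalized(np.full((1, 3), -2.0), feature_ids=["G1"])
        out = maps_score(m, self.sig(genes=("G1",), direction="down"))
        assert (out["score"] == 2.0).all()

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(c=st.floats(-5, 5, allow_nan=False))
    def test_score_is_linear_in_constant_shift(self, c):
        rng = np.random.default_rng(8)
        base = rng.normal(0, 1, (3, 4))
        m1 = make_normalized(base, feature_ids=["G1", "G2", "G3"])
        m2 = make_normalized(base + c, feature_ids=["G1", "G2", "G3"])
        sig = self.sig(genes=("G1", "G2", "G3"))
        s1 = maps_score(m1, sig)["score"].to_numpy()
        s2 = maps_score(m2, sig)["score"].to_numpy()
        np.testing.assert_allclose(s2, s1 + c, atol=1e-9)


class TestDeriver:
    def test_recovers_planted_module(self):
        expr, _, truth = simulate_cohort(CohortSimConfig(seed=13))
        norm = cohort_median_normalize(expr)
        der = SignatureDeriver(random_state=13).fit(norm)
        recovered = set(der.signature_.gene_symbols) & set(truth.module_genes)
        assert len(recovered) >= 6
        chain = [
            der.counts_["input_genes"], der.counts_["post_elimination"],
            der.counts_["post_t_test"], der.counts_["signature"],
        ]
        assert all(a >= b for a, b in zip(chain, chain[1:]))

    def test_derivation_interface_is_outcome_blind(self):
        """No signature-stage operation accepts survival data."""
        from mapsig import signature as sigmod

        for fn in (remove_uniform_genes, kmeans_partition,
                   select_discriminant_genes, gene_auc, select_signature,
                   maps_score, SignatureDeriver.fit):
            params = inspect.signature(fn).parameters
            assert not any("clinical" in p or "survival" in p for p in params)

    def test_sklearn_param_interface(self):
        der = SignatureDeriver(alpha=0.01)
        assert der.get_params()["alpha"] == 0.01
        der.set_params(auc_cutoff=0.9)
        assert der.auc_cutoff == 0.9
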