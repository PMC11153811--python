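"""Differential expression, gating rules and the overlapping index."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lsopatch import diffexpr


def _de_row(**kw):
    row = {
        "gene_id": "g", "mean_log_c1": 0.0, "mean_log_c2": 0.0, "log2fc": 0.0,
        "t_stat": 0.0, "p_value": 1.0, "fdr": 1.0, "auroc": 0.5,
        "mean_tpm_c1": 0.0, "mean_tpm_c2": 0.0, "pct_c1": 0.0, "pct_c2": 0.0,
    }
    row.update(kw)
    return pd.DataFrame([row])


class TestWelch:
    def test_identical_groups_p_one(self):
        values = np.tile(np.arange(12, dtype=float), (5, 1))
        labels = np.array([1] * 6 + [2] * 6)
        values = np.hstack([values[:, :6], values[:, :6]])
        _, p, lfc = diffexpr.welch_test_all(values, labels)
        assert np.allclose(p, 1.0)
        assert np.allclose(lfc, 0.0)

    def test_label_swap_negates_lfc(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=(20, 15))
        labels = np.array([1] * 8 + [2] * 7)
        t1, p1, l1 = diffexpr.welch_test_all(values, labels)
        t2, p2, l2 = diffexpr.welch_test_all(values, 3 - labels)
        assert np.allclose(l1, -l2)
        assert np.allclose(p1, p2)
        assert np.allclose(t1, -t2)

    def test_planted_effect_detected(self):
        rng = np.random.default_rng(1)
        values = rng.normal(0, 1, size=(1, 86))
        labels = np.array([1] * 56 + [2] * 30)
        values[0, labels == 1] += 2.0
        _, p, _ = diffexpr.welch_test_all(values, labels)
        assert p[0] < 1e-4

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError):
            diffexpr.welch_test_all(np.ones((2, 4)), np.array([1, 1, 2, 2]))


class TestBH:
    def test_single_p(self):
        assert diffexpr.bh_adjust(np.array([0.05]))[0] == pytest.approx(0.05)

    def test_hand_computed_example(self):
        # step-up: 0.04*4/4=0.04; 0.03*4/3=0.04; 0.02*4/2=0.04; 0.01*4/1=0.04
        fdr = diffexpr.bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(fdr, 0.04)

    def test_all_ones(self):
        assert np.allclose(diffexpr.bh_adjust(np.ones(10)), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            diffexpr.bh_adjust(np.array([0.5, 1.5]))


def _auroc_bruteforce(x1, x2):
    wins = sum((a > b) + 0.5 * (a == b) for a in x1 for b in x2)
    return wins / (len(x1) * len(x2))


class TestAuroc:
    def test_perfect_separation(self):
        values = np.array([[5.0, 6.0, 7.0, 1.0, 2.0]])
        labels = np.array([1, 1, 1, 2, 2])
        assert diffexpr.auroc_all(values, labels)[0] == 1.0

    def test_identical_distributions_half(self):
        values = np.array([[3.0] * 10])
        labels = np.array([1] * 5 + [2] * 5)
        assert diffexpr.auroc_all(values, labels)[0] == 0.5

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        n1=st.integers(3, 25),
        n2=st.integers(3, 25),
        seed=st.integers(0, 10_000),
    )
    def test_matches_bruteforce_oracle(self, n1, n2, seed):
        rng = np.random.default_rng(seed)
        x = np.round(rng.normal(size=n1 + n2), 1)  # rounding forces ties
        labels = np.array([1] * n1 + [2] * n2)
        fast = diffexpr.auroc_all(x[None, :], labels)[0]
        assert fast == pytest.approx(_auroc_bruteforce(x[:n1], x[n1:]), abs=1e-12)


class TestDEGRules:
    def test_boundary_inclusive(self):
        df = diffexpr.call_degs(_de_row(log2fc=1.0, fdr=0.05))
        assert bool(df["is_deg"].iloc[0])

    def test_fold_change_gate(self):
        df = diffexpr.call_degs(_de_row(log2fc=0.9, fdr=1e-9))
        assert not bool(df["is_deg"].iloc[0])

    def test_ranking_by_auroc_distance(self):
        rows = pd.concat([
            _de_row(gene_id="a", log2fc=2.0, fdr=0.01, auroc=0.9),
            _de_row(gene_id="b", log2fc=2.0, fdr=0.01, auroc=0.99),
            _de_row(gene_id="c", log2fc=-2.0, fdr=0.01, auroc=0.05),
        ], ignore_index=True)
        df = diffexpr.call_degs(rows).set_index("gene_id")
        assert df.loc["b", "deg_rank"] == 1 and df.loc["a", "deg_rank"] == 2
        assert df.loc["c", "deg_rank"] == 1  # ranked within its own direction

    def test_super_deg_low_expression_excluded(self):
        """A DEG at 1.5 vs 0.0 TPM fails the >= 10 TPM gate."""
        df = _de_row(log2fc=3.0, fdr=0.01, mean_tpm_c1=1.5, mean_tpm_c2=0.0)
        df = diffexpr.call_super_degs(diffexpr.call_degs(df))
        assert bool(df["is_deg"].iloc[0])
        assert not bool(df["is_super_deg"].iloc[0])

    @pytest.mark.parametrize(
        "tpm1,tpm2,lfc,expected",
        [(40.0, 8.0, 2.3, True), (12.0, 4.0, 1.58, False)],
    )
    def test_super_deg_fold_gate(self, tpm1, tpm2, lfc, expected):
        df = _de_row(log2fc=lfc, fdr=0.01, mean_tpm_c1=tpm1, mean_tpm_c2=tpm2)
        df = diffexpr.call_super_degs(diffexpr.call_degs(df))
        assert bool(df["is_super_deg"].iloc[0]) is expected

    @pytest.mark.parametrize(
        "tpm1,tpm2,lfc,expected",
        [(20.0, 15.0, 0.4, True), (8.0, 6.0, 0.4, False), (30.0, 10.0, 1.58, False)],
    )
    def test_cluster_similarity_gates(self, tpm1, tpm2, lfc, expected):
        df = _de_row(log2fc=lfc, fdr=1.0, mean_tpm_c1=tpm1, mean_tpm_c2=tpm2)
        df = diffexpr.call_cluster_similar(diffexpr.call_degs(df))
        assert bool(df["is_cluster_similar"].iloc[0]) is expected

    def test_flag_exclusivity_on_real_table(self, bundle):
        de = bundle["de"]
        assert (de.loc[de["is_super_deg"], "is_deg"]).all()
        assert not (de["is_cluster_similar"] & de["is_deg"]).any()


class TestOverlappingIndex:
    def test_self_overlap_is_one(self):
        x = np.random.default_rng(0).normal(size=500)
        assert diffexpr.overlapping_index(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_distant_samples_vanishing_overlap(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 300)
        b = rng.normal(300, 1, 300)
        assert diffexpr.overlapping_index(a, b) <= 0.01

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 1000), shift=st.floats(-50, 50))
    def test_symmetry_bounds_and_shift_invariance(self, seed, shift):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, 80)
        b = rng.normal(1, 2, 60)
        oi = diffexpr.overlapping_index(a, b)
        assert 0.0 <= oi <= 1.0
        assert diffexpr.overlapping_index(b, a) == pytest.approx(oi, abs=1e-12)
        assert diffexpr.overlapping_index(a + shift, b + shift) == pytest.approx(
            oi, abs=1e-9)

    def test_degenerate_point_masses(self):
        assert diffexpr.overlapping_index([2.0, 2.0], [2.0, 2.0, 2.0]) == 1.0
        assert diffexpr.overlapping_index([2.0, 2.0], [3.0, 3.0]) == 0.0
        # half the mass shared
        assert diffexpr.overlapping_index([0.0, 0.0], [0.0, 1.0]) == pytest.approx(0.5)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            diffexpr.overlapping_index([], [1.0, 2.0])


class TestRankSimilarity:
    def test_toy_ranking_and_threshold(self):
        rng = np.random.default_rng(2)
        labels = np.array([1] * 20 + [2] * 20)
        shared = rng.normal(50, 5, 40)
        tpm = np.vstack([
            np.concatenate([shared[:20], shared[:20]]),  # identical distributions
            rng.normal(50, 5, 40),  # same law, high OI
            np.concatenate([np.full(20, 10.0) + rng.normal(0, 1, 20),
                            np.full(20, 90.0) + rng.normal(0, 1, 20)]),  # disjoint
        ])
        gene_ids = np.array(["same", "close", "disjoint"], dtype=object)
        df = pd.concat([
            _de_row(gene_id=g, mean_tpm_c1=50, mean_tpm_c2=50) for g in gene_ids
        ], ignore_index=True)
        df["is_deg"] = False
        df["is_cluster_similar"] = True
        ranked = diffexpr.rank_similarity(df, tpm, labels, gene_ids)
        assert ranked.iloc[0]["gene_id"] == "same"
        assert ranked.iloc[-1]["gene_id"] == "disjoint"
        assert not ranked.set_index("gene_id").loc["disjoint", "high_stringency"]

    def test_threshold_rule_on_oi_values(self):
        # OI values {0.95, 0.85, 0.6} at threshold 0.8 retain two genes
        ois = pd.Series([0.95, 0.85, 0.6])
        assert int((ois >= 0.8).sum()) == 2


class TestIntersection:
    def test_threshold_sets(self):
        out = diffexpr.expression_intersection(
            np.array([1200.0, 1200.0, 100.0]),
            np.array([1100.0, 300.0, 2000.0]),
            np.array(["a", "b", "c"], dtype=object),
        )
        assert out == {"intersection": ["a"], "exclusive_c1": ["b"],
                       "exclusive_c2": ["c"]}

    def test_threshold_above_max_empties_all(self):
        out = diffexpr.expression_intersection(
            np.array([10.0]), np.array([20.0]), np.array(["a"], dtype=object),
            threshold=1e9)
        assert all(len(v) == 0 for v in out.values())

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            diffexpr.expression_intersection(
                np.ones(1), np.ones(1), np.array(["a"]), threshold=0.0)


def test_null_fdr_control(small_config, small_counts):
    """With permuted labels, genes at fdr <= 0.05 stay near the nominal rate."""
    from lsopatch import preprocess

    cm, truth = small_counts
    cm_qc, _ = preprocess.cell_qc_filter(cm)
    cm_f = preprocess.gene_filter(cm_qc)
    nm = preprocess.normalize(cm_f, preprocess.compute_size_factors(cm_f))
    labels = truth.cells.set_index("cell_id").loc[cm_f.cell_ids, "cluster"].to_numpy()
    rng = np.random.default_rng(0)
    fracs = []
    for _ in range(20):
        perm = rng.permutation(labels)
        _, p, _ = diffexpr.welch_test_all(nm.values, perm)
        fracs.append(np.mean(diffexpr.bh_adjust(p) <= 0.05))
    n = nm.values.shape[0] * 20
    assert np.mean(fracs) <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n)
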