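"""Attribute weighting: closed-form contingency cases, brute-force oracle
equivalence for the entropy/Gini/chi-square family, an independent O(n^2)
ReliefF reference, OneR rule weights, and normalisation contracts."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import oracle_relief, oracle_weights
from crsignature.weighting import (
    CONTINGENCY_MODELS,
    ContingencyTable,
    MODELS,
    WeightingConfig,
    contingency,
    discretize_entropy,
    discretize_equal_frequency,
    normalize_weights,
    relief_weights,
    run_all_models,
    weight_from_contingency,
    weight_relief,
    weight_rule,
)


# ---------------------------------------------------------------------------
class TestDiscretizeEqualFrequency:
    def test_uniform_case_equal_bins(self):
        labels = discretize_equal_frequency(np.arange(1, 41), 4)
        assert np.bincount(labels).tolist() == [10, 10, 10, 10]

    def test_constant_vector_single_bin(self):
        assert set(discretize_equal_frequency(np.full(10, 3.3), 4)) == {0}

    def test_heavy_ties_no_empty_bins_deterministic(self):
        # half the mass sits on one value; quantile edges collapse
        v = np.r_[np.full(10, 5.0), np.arange(10, 20.0)]
        labels = discretize_equal_frequency(v, 4)
        counts = np.bincount(labels)
        assert (counts > 0).all()
        # all ties share one bin (right-closed edges)
        assert len(set(labels[:10])) == 1
        np.testing.assert_array_equal(labels, discretize_equal_frequency(v, 4))

    def test_n_bins_below_two_rejected(self):
        with pytest.raises(ValueError):
            discretize_equal_frequency(np.arange(5.0), 1)


class TestDiscretizeEntropy:
    def test_separable_feature_splits_at_boundary(self):
        v = np.r_[np.arange(10.0), np.arange(100, 110.0)]
        y = ["a"] * 10 + ["b"] * 10
        labels = discretize_entropy(v, y)
        assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
        assert set(labels) == {0, 1}

    def test_uninformative_feature_single_bin(self):
        v = np.arange(20.0)
        y = ["a", "b"] * 10  # class alternates along the feature: no MDL split
        assert set(discretize_entropy(v, y)) == {0}

    def test_constant_single_bin(self):
        assert set(discretize_entropy(np.full(12, 2.0), ["a", "b"] * 6)) == {0}


class TestContingency:
    def test_balanced_design_table(self, small_run):
        _, _, meta, _ = small_run
        ct = contingency(meta["tissue"], meta["diet"])
        assert ct.counts.shape == (4, 2)
        np.testing.assert_array_equal(ct.counts, 5.0)

    def test_perfect_separation_diagonal(self):
        f = pd.Series(["x"] * 20 + ["y"] * 20)
        y = ["a"] * 20 + ["b"] * 20
        ct = contingency(f, y)
        np.testing.assert_array_equal(ct.counts, [[20, 0], [0, 20]])

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(8)
        v = rng.normal(size=60)
        y = rng.choice(["a", "b"], size=60)
        ct = contingency(v, y, n_bins=4)
        bins = discretize_equal_frequency(v, 4)
        tally = np.zeros_like(ct.counts)
        for b, c in zip(bins, y):
            tally[b, 0 if c == "a" else 1] += 1
        np.testing.assert_array_equal(ct.counts, tally)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            contingency(np.arange(5.0), ["a"] * 4)


class TestContingencyWeights:
    def test_perfect_separation_closed_forms(self):
        ct = ContingencyTable([[20, 0], [0, 20]])
        assert weight_from_contingency(ct, "info_gain") == pytest.approx(1.0)
        assert weight_from_contingency(ct, "gini_index") == pytest.approx(0.5)
        assert weight_from_contingency(ct, "chi_squared") == pytest.approx(40.0)
        assert weight_from_contingency(ct, "uncertainty") == pytest.approx(1.0)
        assert weight_from_contingency(ct, "info_gain_ratio") == pytest.approx(1.0)

    def test_independence_gives_zero(self):
        ct = ContingencyTable([[10, 10], [10, 10]])
        for m in CONTINGENCY_MODELS:
            assert weight_from_contingency(ct, m) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_3113(self):
        """[[3,1],[1,3]]: IG = 1 - H(0.25) = 0.18872 bits; others from oracle."""
        ct = ContingencyTable([[3, 1], [1, 3]])
        expected_ig = 1.0 - (-(0.25 * math.log2(0.25) + 0.75 * math.log2(0.75)))
        assert weight_from_contingency(ct, "info_gain") == pytest.approx(expected_ig, abs=1e-12)
        ref = oracle_weights(np.array([[3, 1], [1, 3]]))
        for m in CONTINGENCY_MODELS:
            assert weight_from_contingency(ct, m) == pytest.approx(ref[m], abs=1e-12)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 6), min_size=4, max_size=4))
    def test_2x2_oracle_equivalence(self, cells):
        if sum(cells) == 0:
            return
        t = np.array(cells, dtype=float).reshape(2, 2)
        ref = oracle_weights(t)
        ct = ContingencyTable(t)
        for m in CONTINGENCY_MODELS:
            assert weight_from_contingency(ct, m) == pytest.approx(ref[m], abs=1e-12)

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(9)
        t = rng.integers(0, 8, size=(4, 2)).astype(float)
        t[0, 0] += 1  # ensure nonzero
        ct = ContingencyTable(t)
        perm_rows = ContingencyTable(t[[2, 0, 3, 1], :])
        perm_cols = ContingencyTable(t[:, [1, 0]])
        for m in CONTINGENCY_MODELS:
            w = weight_from_contingency(ct, m)
            assert weight_from_contingency(perm_rows, m) == pytest.approx(w, abs=1e-12)
            assert weight_from_contingency(perm_cols, m) == pytest.approx(w, abs=1e-12)

    def test_info_gain_bounded_by_class_entropy(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            t = rng.integers(0, 7, size=(3, 2)).astype(float)
            if t.sum() == 0:
                continue
            ct = ContingencyTable(t)
            # balanced binary class bounds: IG <= H(class) <= 1 bit
            assert weight_from_contingency(ct, "info_gain") <= 1.0 + 1e-12
            assert 0.0 <= weight_from_contingency(ct, "uncertainty") <= 1.0 + 1e-12

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable([[0, 0], [0, 0]])


class TestRelief:
    def _table(self, X, y, numeric):
        df = pd.DataFrame(X, columns=[f"f{j}" for j in range(X.shape[1])])
        for j, is_num in enumerate(numeric):
            if not is_num:
                df[f"f{j}"] = pd.Categorical(df[f"f{j}"].astype(int).astype(str))
        df["diet"] = pd.Categorical(y)
        return df

    def test_class_indicator_attains_max(self):
        rng = np.random.default_rng(11)
        y = np.array(["control"] * 10 + ["CR"] * 10)
        X = np.column_stack([
            (y == "CR").astype(float),        # perfect indicator
            rng.normal(size=20),               # noise
            rng.normal(size=20),
        ])
        w = relief_weights(self._table(X, y, [True] * 3), k_neighbors=3)
        assert w.idxmax() == "f0" and w["f0"] > 0

    def test_constant_feature_zero(self):
        rng = np.random.default_rng(12)
        y = ["control"] * 8 + ["CR"] * 8
        X = np.column_stack([np.full(16, 2.0), rng.normal(size=16)])
        w = relief_weights(self._table(X, np.array(y), [True, True]), k_neighbors=3)
        assert w["f0"] == 0.0

    @pytest.mark.parametrize("seed,n,p,k", [(13, 12, 2, 2), (14, 16, 4, 3), (15, 20, 3, 5)])
    def test_matches_brute_force_reference(self, seed, n, p, k):
        """Full-pass ReliefF equals the independent O(n^2) loop to 1e-12."""
        rng = np.random.default_rng(seed)
        y = np.array(["control", "CR"] * (n // 2))
        X = np.column_stack([rng.normal(size=n) for _ in range(p - 1)]
                            + [rng.integers(0, 3, size=n).astype(float)])
        numeric = [True] * (p - 1) + [False]
        w = relief_weights(self._table(X, y, numeric), k_neighbors=k)
        ref = oracle_relief(X, y, np.array(numeric), k)
        np.testing.assert_allclose(w.to_numpy(), ref, atol=1e-12)

    def test_relevant_beats_noise(self):
        rng = np.random.default_rng(16)
        y = np.array(["control"] * 6 + ["CR"] * 6)
        relevant = np.r_[rng.normal(0, 0.3, 6), rng.normal(3, 0.3, 6)]
        X = np.column_stack([relevant, rng.normal(size=12)])
        w = relief_weights(self._table(X, y, [True, True]), k_neighbors=2)
        assert w["f0"] > w["f1"]

    def test_deterministic_full_pass(self):
        rng = np.random.default_rng(17)
        y = np.array(["control", "CR"] * 10)
        X = rng.normal(size=(20, 5))
        t = self._table(X, y, [True] * 5)
        pd.testing.assert_series_equal(relief_weights(t, 3), relief_weights(t, 3))

    def test_small_class_rejected(self):
        y = np.array(["control"] * 3 + ["CR"] * 9)
        X = np.random.default_rng(18).normal(size=(12, 2))
        with pytest.raises(ValueError, match="relief_k"):
            relief_weights(self._table(X, y, [True, True]), k_neighbors=5)

    def test_weight_relief_single_feature_view(self):
        rng = np.random.default_rng(19)
        y = np.array(["control", "CR"] * 8)
        X = rng.normal(size=(16, 3))
        t = self._table(X, y, [True] * 3)
        assert weight_relief(t, "f1", k_neighbors=2) == relief_weights(t, 2)["f1"]


class TestRule:
    def test_perfect_separation(self):
        f = pd.Series(["x"] * 20 + ["y"] * 20)
        y = ["a"] * 20 + ["b"] * 20
        assert weight_rule(f, y) == pytest.approx(0.5)

    def test_constant_feature_zero(self):
        assert weight_rule(pd.Series(["x"] * 10), ["a", "b"] * 5) == 0.0

    def test_hand_tallied_partial_purity(self):
        """Two bins at 75% purity, balanced classes: accuracy 0.75 - 0.5."""
        f = pd.Series(["u"] * 8 + ["v"] * 8)
        y = ["a"] * 6 + ["b"] * 2 + ["b"] * 6 + ["a"] * 2
        assert weight_rule(f, y) == pytest.approx(0.25)


class TestNormalize:
    def test_affine_map(self):
        out = normalize_weights(pd.Series([2.0, 4.0, 6.0], index=list("abc")))
        np.testing.assert_allclose(out, [0.0, 0.5, 1.0])

    def test_constant_gives_zeros_with_warning(self):
        with pytest.warns(UserWarning):
            out = normalize_weights(pd.Series([3.0, 3.0], index=list("ab"), name="m"))
        assert (out == 0.0).all()

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=20, unique=True))
    def test_bounds_contract(self, raw):
        out = normalize_weights(pd.Series(raw))
        assert out.min() == pytest.approx(0.0) and out.max() == pytest.approx(1.0)


class TestRunAllModels:
    def test_shape_and_bounds(self, small_run):
        from crsignature.expression import assemble_mined_table, compute_fpkm, filter_low_expression
        _, cm, meta, _ = small_run
        kept, _ = filter_low_expression(compute_fpkm(cm), 5.0)
        table = assemble_mined_table(kept, meta)
        wm = run_all_models(table, WeightingConfig(seed=0))
        assert wm.norm.shape == (table.shape[1] - 1, 7)
        assert set(wm.norm.columns) == set(MODELS)
        assert ((wm.norm >= 0) & (wm.norm <= 1)).all().all()
        assert "tissue" in wm.norm.index

    def test_perfect_feature_gets_norm_one_everywhere(self):
        rng = np.random.default_rng(20)
        y = np.array(["control"] * 20 + ["CR"] * 20)
        df = pd.DataFrame({
            "perfect": np.r_[rng.normal(0, 0.2, 20), rng.normal(5, 0.2, 20)],
            "noise1": rng.normal(size=40),
            "noise2": rng.normal(size=40),
            "tissue": pd.Categorical(["h", "a"] * 20),
        })
        df["diet"] = pd.Categorical(y)
        wm = run_all_models(df, WeightingConfig(relief_k=5, seed=0))
        for m in MODELS:
            assert wm.norm.loc["perfect", m] == pytest.approx(1.0), m

    def test_permutation_null_below_planted(self, small_run):
        """Sum-of-weights under permuted class labels falls below the planted
        signature genes' sums from the unpermuted run (95th percentile)."""
        from crsignature.expression import assemble_mined_table, compute_fpkm, filter_low_expression
        from crsignature.signature import sum_weights
        _, cm, meta, truth = small_run
        kept, _ = filter_low_expression(compute_fpkm(cm), 5.0)
        table = assemble_mined_table(kept, meta)
        wm = run_all_models(table, WeightingConfig(seed=0))
        sums = sum_weights(wm)
        planted = [g for g in truth.genes_of_class("signature") if g in sums.index]

        rng = np.random.default_rng(42)
        permuted = table.copy()
        permuted["diet"] = table["diet"].to_numpy()[rng.permutation(len(table))]
        null_sums = sum_weights(run_all_models(permuted, WeightingConfig(seed=0)))
        assert np.quantile(null_sums, 0.95) < sums.loc[planted].median()

    def test_rejects_single_class(self):
        df = pd.DataFrame({"f": [1.0, 2.0], "g": [3.0, 4.0],
                           "diet": pd.Categorical(["CR", "CR"], categories=["control", "CR"])})
        with pytest.raises(ValueError, match="class"):
            run_all_models(df, WeightingConfig())
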