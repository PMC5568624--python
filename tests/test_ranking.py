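import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psgrank import ranking as rk
from psgrank.synthetic_data import generate_feature_table
from psgrank.types import FeatureTable

from oracles import cmim_oracle, mrmr_oracle


def _table(values, labels, names=None):
    values = np.asarray(values, dtype=float)
    names = names or [f"F{i + 1}" for i in range(values.shape[1])]
    return FeatureTable(values, names, np.asarray(labels, dtype=object),
                        np.array(["s"] * values.shape[0], dtype=object))


class TestDiscretize:
    def test_hand_example(self):
        assert rk.discretize(np.array([0.0, 0.5, 1.0]), 2).tolist() == [0, 1, 1]

    def test_constant_column(self):
        assert rk.discretize(np.full(5, 3.0), 4).tolist() == [0] * 5

    def test_affine_invariance(self, rng):
        x = rng.standard_normal(200)
        a = rk.discretize(x, 10)
        b = rk.discretize(3.5 * x - 2.0, 10)
        assert np.array_equal(a, b)

    @given(st.integers(min_value=2, max_value=20))
    @settings(deadline=None, max_examples=20)
    def test_labels_in_range(self, n_bins):
        x = np.random.default_rng(n_bins).standard_normal(100)
        lab = rk.discretize(x, n_bins)
        assert lab.min() >= 0 and lab.max() <= n_bins - 1


class TestMutualInformation:
    def test_identical_balanced_binary(self):
        a = np.array([0, 1] * 50)
        assert rk.mutual_information(a, a) == pytest.approx(np.log(2))

    def test_independent_product_table(self):
        a = np.repeat([0, 0, 1, 1], 25)
        b = np.tile([0, 1], 50)
        assert rk.mutual_information(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_plugin_hand_value(self):
        # joint counts [[2,1],[1,2]]
        a = np.array([0, 0, 0, 1, 1, 1])
        b = np.array([0, 0, 1, 0, 1, 1])
        p = np.array([[2, 1], [1, 2]]) / 6
        expected = sum(
            p[i, j] * np.log(p[i, j] / (p[i].sum() * p[:, j].sum()))
            for i in range(2) for j in range(2)
        )
        assert rk.mutual_information(a, b) == pytest.approx(expected)

    def test_cmi_chain_rule_consistency(self, rng):
        a = rng.integers(0, 3, 300)
        b = rng.integers(0, 3, 300)
        c = rng.integers(0, 2, 300)
        cmi = rk.conditional_mutual_information(a, b, c)
        assert cmi >= -1e-12


class TestFisher:
    def test_perfectly_separating_feature_on_top(self):
        y = ["A"] * 10 + ["B"] * 10
        sep = np.array([1.0] * 10 + [-1.0] * 10)
        noise = np.random.default_rng(0).standard_normal(20)
        t = _table(np.column_stack([noise, sep]), y)
        lst = rk.fisher_rank(t)
        assert lst.order[0] == 1
        assert lst.scores[1] > 1e6  # bounded only by epsilon

    def test_noise_ranked_below_informative(self, toy_table):
        table, roles = toy_table
        lst = rk.fisher_rank(table)
        worst_inf = max(lst.position(i) for i in roles["informative"])
        best_noise = min(lst.position(i) for i in roles["noise"])
        assert worst_inf < best_noise

    def test_duplicate_column_tie_broken_by_index(self, rng):
        x = rng.standard_normal(40)
        y = ["A"] * 20 + ["B"] * 20
        t = _table(np.column_stack([x, x]), y)
        lst = rk.fisher_rank(t)
        assert lst.scores[0] == lst.scores[1]
        assert lst.order.tolist() == [0, 1]

    def test_single_class_rejected(self, rng):
        t = _table(rng.standard_normal((10, 3)), ["A"] * 10)
        with pytest.raises(ValueError):
            rk.fisher_rank(t)


class TestChi2:
    def test_perfect_association_value(self):
        """Bins reproducing the class labels give chi2 = n (K-1)."""
        y = np.repeat(["A", "B", "C"], 30)
        feat = np.repeat([0.0, 1.0, 2.0], 30)
        t = _table(feat[:, None], y)
        lst = rk.chi2_rank(t, n_bins=3)
        n, k = 90, 3
        assert lst.scores[0] == pytest.approx(n * (k - 1))

    def test_independent_feature_mean_matches_dof(self):
        """E[chi2] equals the contingency degrees of freedom under the null."""
        rng = np.random.default_rng(1)
        n, n_bins = 400, 4
        vals = []
        y = np.repeat([0, 1], n // 2).astype(object)
        for _ in range(200):
            t = _table(rng.standard_normal((n, 1)), y)
            vals.append(rk.chi2_rank(t, n_bins=n_bins).scores[0])
        dof = (n_bins - 1) * (2 - 1)
        assert np.mean(vals) == pytest.approx(dof, rel=0.2)

    def test_joint_permutation_invariance(self, rng):
        t, _ = generate_feature_table(100, 3, 0, 3, seed=2)
        perm = rng.permutation(100)
        t2 = t.subset_rows(perm)
        assert np.allclose(rk.chi2_rank(t).scores, rk.chi2_rank(t2).scores)


class TestInfoGain:
    def test_perfect_predictor_scores_class_entropy(self):
        y = np.repeat(["A", "B", "C"], 20)
        feat = np.repeat([0.0, 1.0, 2.0], 20)
        t = _table(feat[:, None], y)
        lst = rk.infogain_rank(t, n_bins=3)
        h_y = np.log(3)
        assert lst.scores[0] == pytest.approx(h_y)

    def test_nonnegative_and_matches_mi(self, rng):
        t, _ = generate_feature_table(200, 2, 0, 4, seed=5)
        lst = rk.infogain_rank(t)
        assert np.all(lst.scores >= 0)
        _, y = np.unique(t.labels, return_inverse=True)
        for j in range(t.n_features):
            mi = rk.mutual_information(rk.discretize(t.values[:, j], 10), y)
            assert lst.scores[j] == pytest.approx(mi)


class TestReliefF:
    def test_class_flipping_feature_wins(self):
        rng = np.random.default_rng(3)
        n = 60
        y = np.array(["A"] * 30 + ["B"] * 30, dtype=object)
        flip = np.where(y == "A", 1.0, -1.0) + 0.05 * rng.standard_normal(n)
        noise = rng.standard_normal((n, 3))
        t = _table(np.column_stack([noise[:, 0], flip, noise[:, 1:]]), y)
        lst = rk.relieff_rank(t, k=5)
        assert lst.order[0] == 1

    def test_noise_feature_weight_near_zero(self):
        t, roles = generate_feature_table(500, 2, 0, 3, effect=2.0, seed=11)
        lst = rk.relieff_rank(t, k=10)
        for j in roles["noise"]:
            assert abs(lst.scores[j]) <= 0.05

    def test_small_class_raises(self):
        y = ["A"] * 20 + ["B"] * 3
        t = _table(np.random.default_rng(0).standard_normal((23, 2)), y)
        with pytest.raises(ValueError, match="smaller k"):
            rk.relieff_rank(t, k=5)


class TestCMIMAndMRMR:
    def test_duplicate_demoted(self):
        """An exact copy of the first pick falls behind all informative."""
        t, roles = generate_feature_table(400, 4, 0, 4, effect=2.0, seed=13)
        vals = t.values.copy()
        first = rk.cmim_rank(t).order[0]
        dup = np.column_stack([vals, vals[:, first]])
        t2 = _table(dup, t.labels, [f"F{i}" for i in range(dup.shape[1])])
        dup_idx = dup.shape[1] - 1
        for ranker in (rk.cmim_rank,
                       lambda x: rk.mrmr_rank(x, "MID"),
                       lambda x: rk.mrmr_rank(x, "MIQ")):
            lst = ranker(t2)
            dup_pos = lst.position(dup_idx)
            for j in roles["informative"]:
                if j != first:
                    assert lst.position(j) < dup_pos

    @pytest.mark.parametrize("seed", range(5))
    def test_cmim_matches_bruteforce(self, seed):
        t, _ = generate_feature_table(200, 3, 2, 3, effect=1.5, seed=seed)
        _, y = np.unique(t.labels, return_inverse=True)
        cols = [rk.discretize(t.values[:, j], 10) for j in range(t.n_features)]
        assert rk.cmim_rank(t).order.tolist() == cmim_oracle(cols, y)

    @pytest.mark.parametrize("variant", ["MID", "MIQ"])
    @pytest.mark.parametrize("seed", range(3))
    def test_mrmr_matches_bruteforce(self, variant, seed):
        t, _ = generate_feature_table(200, 3, 2, 3, effect=1.5, seed=seed + 50)
        _, y = np.unique(t.labels, return_inverse=True)
        cols = [rk.discretize(t.values[:, j], 10) for j in range(t.n_features)]
        assert (rk.mrmr_rank(t, variant).order.tolist()
                == mrmr_oracle(cols, y, variant))

    def test_mid_miq_agree_on_first_pick(self, toy_table):
        table, _ = toy_table
        assert (rk.mrmr_rank(table, "MID").order[0]
                == rk.mrmr_rank(table, "MIQ").order[0])


class TestRankerContracts:
    def test_deterministic(self, toy_table):
        table, _ = toy_table
        for name, r in rk.default_rankers().items():
            a, b = r(table), r(table)
            assert np.array_equal(a.order, b.order), name

    def test_scale_invariance_after_standardization(self, rng):
        from psgrank.features import standardize
        t, _ = generate_feature_table(300, 3, 0, 5, effect=2.0, seed=21)
        scaled = t.values.copy()
        scaled[:, 2] *= 37.0
        t2 = FeatureTable(scaled, t.feature_names, t.labels, t.subject_ids)
        for name, r in rk.default_rankers(relieff_k=5).items():
            a = r(standardize(t))
            b = r(standardize(t2))
            assert np.array_equal(a.order, b.order), name

    def test_row_shuffle_leaves_rankings_unchanged(self, rng):
        """Joint permutation of epochs and labels is a no-op for rankers."""
        t, _ = generate_feature_table(300, 3, 0, 5, effect=2.0, seed=22)
        perm = rng.permutation(t.n_epochs)
        t2 = t.subset_rows(perm)
        for name, r in rk.default_rankers(relieff_k=5).items():
            assert np.array_equal(r(t).order, r(t2).order), name
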