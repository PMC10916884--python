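import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from foveaspec.agreement import (
    bland_altman,
    distribution_tests,
    linear_weights,
    weighted_kappa,
    weighted_kappa_from_confusion,
)


def brute_force_weighted_kappa(confusion):
    """Direct summation over all cells of the kappa definition."""
    m = np.asarray(confusion, float)
    k = m.shape[0]
    n = m.sum()
    po = pe = 0.0
    for i in range(k):
        for j in range(k):
            w = 1.0 - abs(i - j) / (k - 1)
            po += w * m[i, j] / n
            pe += w * (m[i].sum() / n) * (m[:, j].sum() / n)
    return (po - pe) / (1.0 - pe)


class TestWeightedKappa:
    def test_identical_raters_give_kappa_one(self):
        labels = [1, 2, 3, 4, 5, 3, 2, 1]
        result = weighted_kappa(labels, labels, 5)
        assert result.kappa == pytest.approx(1.0)
        assert result.observed_agreement == pytest.approx(1.0)

    def test_two_categories_equal_unweighted_kappa(self):
        rng = np.random.default_rng(1)
        a = rng.integers(1, 3, 60)
        b = rng.integers(1, 3, 60)
        ours = weighted_kappa(a, b, 2).kappa
        sklearn = pytest.importorskip("sklearn.metrics")
        assert ours == pytest.approx(
            sklearn.cohen_kappa_score(a, b), abs=1e-12)

    @settings(max_examples=40, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_brute_force_oracle_on_random_confusions(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.integers(0, 20, (5, 5)).astype(float)
        if m.sum() == 0:
            m[0, 0] = 1
        result = weighted_kappa_from_confusion(m)
        if not result.flags:
            assert result.kappa == pytest.approx(brute_force_weighted_kappa(m),
                                                 abs=1e-12)

    def test_matches_sklearn_linear_weights(self):
        rng = np.random.default_rng(7)
        a = rng.integers(1, 6, 200)
        b = np.clip(a + rng.integers(-1, 2, 200), 1, 5)
        sklearn = pytest.importorskip("sklearn.metrics")
        ours = weighted_kappa(a, b, 5).kappa
        ref = sklearn.cohen_kappa_score(a, b, weights="linear",
                                        labels=[1, 2, 3, 4, 5])
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_degenerate_marginals_flagged(self):
        result = weighted_kappa([1, 1, 1], [1, 1, 1], 5)
        assert "kappa_undefined_degenerate_marginals" in result.flags
        assert np.isnan(result.kappa)

    def test_random_permutation_gives_zero_expectation(self):
        rng = np.random.default_rng(0)
        a = np.tile(np.arange(1, 6), 20)
        kappas = []
        for _ in range(300):
            b = rng.permutation(a)
            kappas.append(weighted_kappa(a, b, 5).kappa)
        assert abs(np.mean(kappas)) < 0.02

    def test_weight_matrix_structure(self):
        w = linear_weights(5)
        assert np.allclose(np.diag(w), 1.0)
        assert np.allclose(w, w.T)
        assert w[0, 4] == pytest.approx(0.0)


class TestBlandAltman:
    def test_perfect_agreement(self):
        obs = np.linspace(0.1, 1.0, 10)
        result = bland_altman(obs, obs)
        assert result.bias == pytest.approx(0.0)
        assert result.loa_upper - result.loa_lower == pytest.approx(0.0)

    def test_constant_offset(self):
        obs = np.linspace(0.1, 1.0, 10)
        result = bland_altman(obs + 0.1, obs)
        assert result.bias == pytest.approx(0.1)
        assert result.sd == pytest.approx(0.0, abs=1e-12)
        assert result.trend.slope == pytest.approx(0.0, abs=1e-9)

    def test_bias_equals_difference_of_means(self):
        rng = np.random.default_rng(3)
        pred = rng.normal(0.5, 0.2, 40)
        obs = rng.normal(0.5, 0.2, 40)
        result = bland_altman(pred, obs)
        assert result.bias == pytest.approx(pred.mean() - obs.mean(), abs=1e-14)

    def test_builtin_trend_recovered(self):
        # construct pairs with difference = −0.5·mean + noise
        rng = np.random.default_rng(4)
        n = 74
        mean = rng.uniform(0.2, 1.0, n)
        diff = -0.5 * mean + rng.normal(0, 0.02, n)
        pred = mean + diff / 2.0
        obs = mean - diff / 2.0
        result = bland_altman(pred, obs)
        assert result.trend.slope == pytest.approx(-0.5, abs=0.05)
        assert result.trend.dfn == 1
        assert result.trend.dfd == n - 2
        # cross-check F against scipy's regression t statistic
        from scipy import stats

        lr = stats.linregress(mean, diff)
        t2 = (lr.slope / lr.stderr) ** 2
        assert result.trend.f_statistic == pytest.approx(t2, rel=1e-6)

    def test_loa_bracket_bias(self):
        rng = np.random.default_rng(5)
        result = bland_altman(rng.normal(size=30), rng.normal(size=30))
        assert result.loa_lower <= result.bias <= result.loa_upper

    def test_zero_variance_means_flagged(self):
        result = bland_altman(np.full(5, 1.0), np.full(5, 1.0))
        assert "trend_undefined_zero_variance" in result.flags
        assert result.trend is None

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0, 2.0], [1.0, 2.0])


class TestDistributionTests:
    def test_separated_groups_significant(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0, 1, 40)
        b = rng.normal(5, 1, 40)
        report = distribution_tests(np.r_[a, b], ["a"] * 40 + ["b"] * 40)
        assert report["omnibus"]["p"] < 1e-6

    def test_identical_groups_type_i_rate(self):
        # identical distributions: omnibus significant in ≈ alpha of seeds
        rejections = 0
        n_runs = 120
        for seed in range(n_runs):
            rng = np.random.default_rng(seed)
            values = rng.normal(0, 1, 60)
            groups = np.repeat(["a", "b", "c"], 20)
            report = distribution_tests(values, groups)
            rejections += report["omnibus"]["p"] < 0.05
        assert rejections / n_runs <= 0.12

    def test_constant_group_flagged_and_nonnormal_path(self):
        values = np.r_[np.full(10, 1.0), np.arange(10.0)]
        groups = ["a"] * 10 + ["b"] * 10
        report = distribution_tests(values, groups)
        assert any("constant" in f for f in report["flags"])
        assert report["omnibus"]["test"] == "kruskal"

    def test_posthoc_identifies_outlier_group(self):
        rng = np.random.default_rng(8)
        values = np.r_[rng.normal(0, 1, 30), rng.normal(0, 1, 30),
                       rng.normal(4, 1, 30)]
        groups = np.repeat(["a", "b", "c"], 30)
        report = distribution_tests(values, groups)
        sig = {tuple(sorted(p["groups"])): p["p_adjusted"] < 0.01
               for p in report["posthoc"]}
        assert sig[("a", "c")] and sig[("b", "c")]
        assert not sig[("a", "b")]

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            distribution_tests([1.0, 2.0], ["a", "a"])
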