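"""Unit tests for the basic-attribute extractors."""

import numpy as np
import pytest
from scipy import stats as sps
from scipy import optimize

import statsmodels.api as sm

from discut import (
    ExpressionDataset,
    build_attribute_matrix,
    compute_moderated_t,
    compute_nb_wald,
    compute_sam_ranksum,
    compute_sam_t,
    compute_voom_t,
    size_factors,
)
from discut.attributes import estimate_variance_prior, log_cpm

from conftest import make_dataset


class TestSamT:
    def test_identical_groups_give_zero(self):
        y = np.tile(np.arange(1.0, 7.0), (5, 1))  # group2 identical to group1
        y = np.hstack([y[:, :3], y[:, :3]])
        ds = make_dataset(y)
        np.testing.assert_array_equal(compute_sam_t(ds, s0_mode=("fixed", 1.0)), 0.0)

    def test_s0_zero_reduces_to_pooled_t(self, rng):
        y = rng.normal(size=(30, 8))
        ds = make_dataset(y)
        got = compute_sam_t(ds, s0_mode=("fixed", 0.0))
        expected = sps.ttest_ind(y[:, 4:], y[:, :4], axis=1, equal_var=True).statistic
        np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_matches_per_feature_oracle(self, rng):
        y = rng.normal(5.0, 2.0, size=(50, 6))
        ds = make_dataset(y)
        got = compute_sam_t(ds, s0_mode="median")
        # one-feature-at-a-time reference computation
        ses = []
        for row in y:
            x1, x2 = row[:3], row[3:]
            sp2 = ((2) * x1.var(ddof=1) + (2) * x2.var(ddof=1)) / 4
            ses.append(np.sqrt(sp2 * (1 / 3 + 1 / 3)))
        s0 = np.median(ses)
        expected = [
            (row[3:].mean() - row[:3].mean()) / (se + s0) for row, se in zip(y, ses)
        ]
        np.testing.assert_allclose(got, expected, atol=1e-10)


class TestSamRanksum:
    def test_simple_separation(self):
        ds = make_dataset([[1, 2, 3, 4, 5, 6]])
        # W = 4+5+6 = 15, E0 = 3*7/2 = 10.5
        np.testing.assert_allclose(compute_sam_ranksum(ds), [4.5])

    def test_exhaustive_null_expectation(self):
        # mean of W over all C(6,3) assignments equals n2 (N+1)/2
        from itertools import combinations

        vals = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0])
        ranks = sps.rankdata(vals)
        ws = [sum(ranks[list(c)]) for c in combinations(range(6), 3)]
        assert np.mean(ws) == pytest.approx(3 * 7 / 2)

    def test_all_equal_gives_zero(self):
        ds = make_dataset([[7.0] * 8])
        np.testing.assert_array_equal(compute_sam_ranksum(ds), 0.0)


class TestModeratedT:
    def test_no_moderation_equals_ordinary_t(self, rng):
        y = rng.normal(size=(40, 10))
        ds = make_dataset(y)
        got = compute_moderated_t(ds, d0=0.0, s0_sq=1.0)
        expected = sps.ttest_ind(y[:, 5:], y[:, :5], axis=1, equal_var=True).statistic
        np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_infinite_d0_uses_common_variance(self, rng):
        y = rng.normal(size=(40, 10))
        ds = make_dataset(y)
        common = 1.7
        got = compute_moderated_t(ds, d0=1e12, s0_sq=common)
        diff = y[:, 5:].mean(axis=1) - y[:, :5].mean(axis=1)
        expected = diff / np.sqrt(common * (1 / 5 + 1 / 5))
        np.testing.assert_allclose(got, expected, rtol=1e-4)

    def test_hyperparameter_recovery(self, rng):
        # variances from a scaled inverse-chi-square with known (d0, s0^2)
        d0_true, s0_true, dg, m = 8.0, 0.9, 10, 2000
        sigma2 = s0_true * d0_true / rng.chisquare(d0_true, size=m)
        s2 = sigma2 * rng.chisquare(dg, size=m) / dg
        d0_hat, s0_hat = estimate_variance_prior(s2, dg)
        assert d0_hat == pytest.approx(d0_true, rel=0.15)
        assert s0_hat == pytest.approx(s0_true, rel=0.15)

    def test_too_few_positive_variances(self):
        with pytest.raises(ValueError, match="at least 3"):
            estimate_variance_prior(np.array([0.0, 0.0, 1.0]), 4)


class TestVoomT:
    def test_log_cpm_arithmetic(self):
        counts = np.zeros((1, 4))
        counts[0] = [0, 0, 0, 0]
        lib = np.full(4, 1e6)
        # a zero count in a 10^6 library: log2(0.5e6 / (1e6 + 1))
        got = np.log2((counts[0, 0] + 0.5) / (lib[0] + 1) * 1e6)
        assert got == pytest.approx(np.log2(0.5 * 1e6 / (1e6 + 1)))
        assert got == pytest.approx(-1.0, abs=1e-5)

    def test_unit_weight_fallback_equals_moderated_t_on_logcpm(self, rng):
        # fewer than 50 features: unit weights, exact equality
        y = rng.poisson(50.0, size=(30, 8)).astype(float)
        ds = make_dataset(y)
        with pytest.warns(UserWarning, match="unit weights"):
            got = compute_voom_t(ds)
        lds = make_dataset(log_cpm(y))
        np.testing.assert_array_equal(got, compute_moderated_t(lds))

    def test_rejects_non_integer_input(self, rng):
        ds = make_dataset(rng.uniform(0, 1, size=(60, 8)))
        with pytest.raises(ValueError, match="integer"):
            compute_voom_t(ds)

    def test_weights_follow_mean_variance_trend(self, rng):
        # strong NB mean-variance dependence: low-count genes get lower
        # precision weights for log-cpm than high-count genes
        from discut.attributes import voom_weights

        means = np.concatenate([np.full(100, 20.0), np.full(100, 2000.0)])
        y = rng.negative_binomial(10, 10 / (10 + means[:, None]), size=(200, 12)).astype(float)
        ds = make_dataset(y)
        _, w = voom_weights(y, ds.group_mask)
        assert w is not None
        assert w[:100].mean() < w[100:].mean()


class TestNbWald:
    def test_identical_groups_give_zero(self):
        y = np.tile([[3, 8, 15, 3, 8, 15]], (10, 1)).astype(float)
        ds = make_dataset(y)
        np.testing.assert_allclose(compute_nb_wald(ds, factors=np.ones(6)), 0.0, atol=1e-8)

    def test_all_zero_feature_flagged_zero(self, rng):
        y = rng.poisson(30, size=(20, 8)).astype(float)
        y[5] = 0
        ds = make_dataset(y)
        stat = compute_nb_wald(ds, factors=np.ones(8), dispersion=0.1)
        assert stat[5] == 0.0
        assert np.all(stat[np.arange(20) != 5] != 0)

    def test_zero_dispersion_matches_poisson_glm(self, rng):
        y = rng.poisson(40, size=(20, 10)).astype(float)
        sf = np.exp(rng.normal(0, 0.1, size=10))
        sf /= np.exp(np.mean(np.log(sf)))
        ds = make_dataset(y)
        got = compute_nb_wald(ds, factors=sf, dispersion=0.0)
        x = sm.add_constant((np.arange(10) >= 5).astype(float))
        expected = []
        for row in y:
            fit = sm.GLM(row, x, family=sm.families.Poisson(), offset=np.log(sf)).fit(
                tol=1e-12
            )
            expected.append(fit.params[1] / fit.bse[1])
        np.testing.assert_allclose(got, expected, atol=1e-6)

    def test_single_gene_matches_numeric_likelihood_oracle(self, rng):
        alpha = 0.1
        mu = np.array([100.0] * 6 + [200.0] * 6)
        r = 1 / alpha
        y = rng.negative_binomial(r, r / (r + mu)).astype(float)[None, :]
        ds = make_dataset(y)
        got = compute_nb_wald(ds, factors=np.ones(12), dispersion=alpha)[0]

        from scipy.special import gammaln

        def nll(params):
            b0, b1 = params
            m = np.exp(b0 + b1 * (np.arange(12) >= 6))
            return -np.sum(
                gammaln(y[0] + r) - gammaln(r) - gammaln(y[0] + 1)
                + r * np.log(r / (r + m)) + y[0] * np.log(m / (r + m))
            )

        res = optimize.minimize(nll, [4.0, 0.5], method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12})
        b1 = res.x[1]
        # observed-information SE via numeric Hessian of the profile
        eps = 1e-5
        h = np.zeros((2, 2))
        for i in range(2):
            for j in range(2):
                p = res.x.copy()
                pp, pm, mp, mm = (p.copy() for _ in range(4))
                pp[i] += eps; pp[j] += eps
                pm[i] += eps; pm[j] -= eps
                mp[i] -= eps; mp[j] += eps
                mm[i] -= eps; mm[j] -= eps
                h[i, j] = (nll(pp) - nll(pm) - nll(mp) + nll(mm)) / (4 * eps**2)
        se = np.sqrt(np.linalg.inv(h)[1, 1])
        assert got == pytest.approx(b1 / se, abs=1e-4)


class TestSizeFactors:
    def test_identical_samples(self):
        y = np.tile([[10.0], [20.0], [5.0]], (1, 6))
        np.testing.assert_allclose(size_factors(y), 1.0)

    def test_scale_equivariance(self, rng):
        y = rng.poisson(50, size=(100, 6)).astype(float) + 1
        y2 = y.copy()
        y2[:, 0] *= 2
        f = size_factors(y2)
        assert f[0] / f[1] == pytest.approx(2 * size_factors(y)[0] / size_factors(y)[1])

    def test_matches_direct_implementation(self, rng):
        y = rng.poisson(30, size=(100, 6)).astype(float)
        got = size_factors(y)
        pos = np.all(y > 0, axis=1)
        geo = np.exp(np.log(y[pos]).mean(axis=1))
        f = np.median(y[pos] / geo[:, None], axis=0)
        f /= np.exp(np.mean(np.log(f)))
        np.testing.assert_array_equal(got, f)

    def test_fallback_to_library_size(self):
        y = np.array([[0, 5, 5, 5], [5, 0, 5, 5]], dtype=float)
        with pytest.warns(UserWarning, match="library-size"):
            f = size_factors(y)
        assert np.all(f > 0)


class TestBuildAttributeMatrix:
    def test_single_feature_ranksum(self):
        ds = make_dataset([[1, 2, 3, 4, 5, 6]])
        am = build_attribute_matrix(ds, ["sam_ranksum"])
        np.testing.assert_allclose(am.stats, [[4.5]])
        assert am.attribute_names == ["sam_ranksum"]

    def test_duplicate_names_warn_and_repeat(self, gaussian_dataset):
        with pytest.warns(UserWarning, match="duplicate"):
            am = build_attribute_matrix(gaussian_dataset, ["sam_t", "sam_t"])
        np.testing.assert_array_equal(am.stats[:, 0], am.stats[:, 1])

    def test_empty_spec_rejected(self, gaussian_dataset):
        with pytest.raises(ValueError, match="non-empty"):
            build_attribute_matrix(gaussian_dataset, [])

    def test_unknown_name_lists_supported(self, gaussian_dataset):
        with pytest.raises(ValueError, match="sam_ranksum"):
            build_attribute_matrix(gaussian_dataset, ["bogus"])


@pytest.mark.parametrize("attr", ["sam_t", "sam_ranksum", "moderated_t", "voom_t", "nb_wald"])
def test_antisymmetry_under_group_exchange(attr, rng):
    """With equal group sizes, swapping the condition labels negates every
    extractor's statistic (the orientation convention)."""
    y = rng.negative_binomial(5, 0.05, size=(80, 10)).astype(float)
    labels = np.array(["a"] * 5 + ["b"] * 5)
    ds = ExpressionDataset(values=y, labels=labels)
    swapped = ExpressionDataset(values=y, labels=np.where(labels == "a", "b", "a"))
    func = {
        "sam_t": compute_sam_t,
        "sam_ranksum": compute_sam_ranksum,
        "moderated_t": compute_moderated_t,
        "voom_t": compute_voom_t,
        "nb_wald": lambda d: compute_nb_wald(d, dispersion=0.1),
    }[attr]
    np.testing.assert_allclose(func(ds), -func(swapped), atol=1e-8)


def test_extractors_deterministic(count_dataset):
    a = build_attribute_matrix(count_dataset, ["voom_t", "sam_ranksum", "nb_wald"])
    b = build_attribute_matrix(count_dataset, ["voom_t", "sam_ranksum", "nb_wald"])
    np.testing.assert_array_equal(a.stats, b.stats)
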