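import numpy as np
import pytest

from nlcc.choice_stats import (
    behavioral_dprime_fine,
    cc_closed_form,
    choice_correlation_fine,
    dprime_from_D,
    dprime_from_total_correlation,
    equivalent_ratios,
    fisher_information,
    make_cc_result,
    naccc,
    predict_optimal_cc,
)
from nlcc.features import FeatureSet, signal_noise_summary
from nlcc.trials import TrialTable

from conftest import make_gaussian_feature_world
from test_decoders import summary_from


class TestFineChoiceCorrelation:
    def test_self_correlation_is_one(self, rng):
        n = 2000
        vals = rng.normal(size=(n, 2))
        f = FeatureSet(terms=[(0,), (1,)], values=vals)
        t = TrialTable(s=np.zeros(n), r=np.zeros((n, 1)))
        cc = choice_correlation_fine(f, vals[:, 0], t)
        assert cc[0] == pytest.approx(1.0)

    def test_independent_feature_uncorrelated(self, rng):
        n = 50_000
        vals = rng.normal(size=(n, 2))
        f = FeatureSet(terms=[(0,), (1,)], values=vals)
        t = TrialTable(s=np.zeros(n), r=np.zeros((n, 1)))
        cc = choice_correlation_fine(f, vals[:, 0], t)
        assert abs(cc[1]) < 4.0 / np.sqrt(n)

    def test_identity_gamma_closed_form(self, rng):
        """Gamma = I, w along (3,4): C = (0.6, 0.8)."""
        np.testing.assert_allclose(
            cc_closed_form(np.eye(2), np.array([3.0, 4.0])), [0.6, 0.8]
        )
        n = 200_000
        vals = rng.normal(size=(n, 2))
        shat = vals @ np.array([3.0, 4.0])
        f = FeatureSet(terms=[(0,), (1,)], values=vals)
        t = TrialTable(s=np.zeros(n), r=np.zeros((n, 1)))
        cc = choice_correlation_fine(f, shat, t)
        np.testing.assert_allclose(cc, [0.6, 0.8], atol=0.01)

    def test_closed_form_matches_empirical_random_instances(self, rng):
        """Property: Eq.-15-style closed form equals the within-condition
        correlation for Gaussian features and arbitrary fixed weights."""
        for _ in range(10):
            dim = int(rng.integers(2, 7))
            A = rng.standard_normal((dim, dim))
            gamma = A @ A.T + 0.2 * np.eye(dim)
            w = rng.standard_normal(dim)
            n = 40_000
            vals = rng.multivariate_normal(np.zeros(dim), gamma, size=n)
            f = FeatureSet(terms=[(i,) for i in range(dim)], values=vals)
            t = TrialTable(s=np.zeros(n), r=np.zeros((n, 1)))
            emp = choice_correlation_fine(f, vals @ w, t)
            np.testing.assert_allclose(
                emp, cc_closed_form(gamma, w), atol=5.0 / np.sqrt(n)
            )

    def test_zero_variance_choice_raises(self):
        f = FeatureSet(terms=[(0,)], values=np.random.default_rng(0).normal(size=(10, 1)))
        t = TrialTable(s=np.zeros(10), r=np.zeros((10, 1)))
        with pytest.raises(ValueError):
            choice_correlation_fine(f, np.ones(10), t)


class TestNACCC:
    def test_equals_fine_cc_for_identical_conditions(self, rng):
        """When the conditional distributions do not depend on the
        category, the NACCC reduces to the fine choice correlation."""
        n = 100_000
        vals = rng.multivariate_normal([0, 0], [[1.0, 0.5], [0.5, 1.0]], size=n)
        s = rng.choice([0.0, 1.0], size=n)
        f = FeatureSet(terms=[(0,), (1,)], values=vals)
        t = TrialTable(s=s, r=np.zeros((n, 1)))
        shat = vals @ np.array([1.0, 2.0])
        b = naccc(f, shat, t)
        c = choice_correlation_fine(f, shat, t)
        np.testing.assert_allclose(b, c, atol=0.01)

    def test_self_is_one_and_bounded(self, rng):
        n = 10_000
        s = rng.choice([0.0, 1.0], size=n)
        vals = rng.normal(size=(n, 3)) + s[:, None]
        f = FeatureSet(terms=[(0,), (1,), (2,)], values=vals)
        t = TrialTable(s=s, r=np.zeros((n, 1)))
        b = naccc(f, vals[:, 0], t)
        assert b[0] == pytest.approx(1.0)
        assert np.all(np.abs(b) <= 1.0 + 1e-12)

    def test_independent_choice_near_zero(self, rng):
        n = 50_000
        s = rng.choice([0.0, 1.0], size=n)
        vals = rng.normal(size=(n, 2))
        f = FeatureSet(terms=[(0,), (1,)], values=vals)
        t = TrialTable(s=s, r=np.zeros((n, 1)))
        b = naccc(f, rng.normal(size=n), t)
        assert np.abs(b).max() < 4.0 / np.sqrt(n / 2)

    def test_category_with_one_trial_raises(self):
        f = FeatureSet(terms=[(0,)], values=np.arange(5.0)[:, None])
        t = TrialTable(s=np.array([0, 0, 0, 0, 1.0]), r=np.zeros((5, 1)))
        with pytest.raises(ValueError):
            naccc(f, np.arange(5.0), t)

    def test_redundant_duplicate_leaves_cc_unchanged(self, rng):
        """Adding an exact copy of a statistic changes neither its measured
        nor its predicted choice correlation."""
        n = 50_000
        s = rng.choice([0.0, 1.0], size=n)
        base = rng.normal(size=(n, 2)) + 0.3 * s[:, None]
        shat = base @ np.array([1.0, 0.5]) + 0.1 * rng.normal(size=n)
        f2 = FeatureSet(terms=[(0,), (1,)], values=base)
        f3 = FeatureSet(terms=[(0,), (1,), (2,)],
                        values=np.column_stack([base, base[:, 0]]))
        t = TrialTable(s=s, r=np.zeros((n, 1)))
        b2 = naccc(f2, shat, t)
        b3 = naccc(f3, shat, t)
        np.testing.assert_allclose(b3[:2], b2, rtol=1e-9)
        np.testing.assert_allclose(b3[2], b2[0], rtol=1e-9)
        s2 = signal_noise_summary(f2, t, mode="coarse")
        s3 = signal_noise_summary(f3, t, mode="coarse")
        np.testing.assert_allclose(s3.d_prime_terms[:2], s2.d_prime_terms)


class TestDPrime:
    def test_exact_value(self):
        assert dprime_from_D(1.0 / np.sqrt(5.0)) == pytest.approx(1.0)
        assert dprime_from_D(0.0) == 0.0

    def test_small_d_limit(self):
        for d in (1e-3, 1e-5):
            assert dprime_from_D(d) / (2 * d) == pytest.approx(1.0, abs=1e-5)

    def test_total_correlation_gaussian_two_class(self, rng):
        """Cross-check against a simulation where the true d' is 1."""
        n = 400_000
        s = rng.choice([0.0, 1.0], size=n)
        x = s + rng.normal(size=n)  # separation 1, unit variance
        assert dprime_from_total_correlation(x, s) == pytest.approx(1.0, abs=0.01)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            dprime_from_D(1.0)
        with pytest.raises(ValueError):
            dprime_from_total_correlation(np.ones(4), np.array([0, 0, 1, 1.0]))


class TestPredictions:
    def test_perfect_statistic_prediction_one(self):
        summ = summary_from(np.eye(1), [2.0])
        pred = predict_optimal_cc(summ, behavioral_dprime=2.0)
        assert pred[0] == pytest.approx(1.0)

    def test_identity_case_matches_measured(self, rng):
        """Gamma = I, F' = (3,4), optimal decoding: predictions (0.6, 0.8)
        coincide with the measured choice correlations."""
        gamma0, gamma, fp, table, feats = make_gaussian_feature_world(
            rng, dim=2, n=150_000
        )
        fp[:] = [3.0, 4.0]
        n = table.n_trials
        vals = np.outer(table.s, fp) + rng.normal(size=(n, 2))
        feats = FeatureSet(terms=[(0,), (1,)], values=vals)
        w = fp / 25.0
        shat = vals @ w
        meas = choice_correlation_fine(feats, shat, table)
        summ = summary_from(np.eye(2), fp, ds=1.0)
        d_b = behavioral_dprime_fine(shat, table.s, ds=1.0)
        pred = predict_optimal_cc(summ, d_b)
        np.testing.assert_allclose(pred, [0.6, 0.8], atol=0.01)
        np.testing.assert_allclose(meas, pred, atol=0.02)

    def test_uninformative_term_prediction_zero(self):
        summ = summary_from(np.eye(2), [2.0, 0.0])
        pred = predict_optimal_cc(summ, behavioral_dprime=2.0)
        assert pred[1] == 0.0

    def test_nonpositive_dprime_raises(self):
        summ = summary_from(np.eye(1), [1.0])
        with pytest.raises(ValueError):
            predict_optimal_cc(summ, behavioral_dprime=0.0)

    def test_over_one_flagged_not_clipped(self):
        summ = summary_from(np.eye(1), [2.0])
        with pytest.warns(UserWarning):
            pred = predict_optimal_cc(summ, behavioral_dprime=2.0, delta=1.2)
        assert pred[0] == pytest.approx(1.2)

    def test_oriented_result_nonnegative_predictions(self, rng):
        """After orienting statistics by their tuning sign, every optimal
        prediction is nonnegative."""
        summ = summary_from(np.diag([1.0, 2.0, 0.5]), [1.0, -2.0, 0.3])
        measured = np.array([0.3, -0.5, 0.1])
        res = make_cc_result(summ, measured, behavioral_dprime=3.0)
        assert np.all(res.predicted >= 0)
        assert np.all(res.d_prime_terms >= 0)
        # orientation is a joint sign flip: products are invariant
        np.testing.assert_allclose(
            res.measured * res.predicted,
            measured * predict_optimal_cc(summ, 3.0),
        )


class TestEquivalentRatios:
    def test_all_four_forms_agree(self):
        assert equivalent_ratios(fisher_pair=(1.0, 4.0)) == pytest.approx(0.5)
        assert equivalent_ratios(variance_pair=(0.01, 0.04)) == pytest.approx(0.5)
        assert equivalent_ratios(threshold_pair=(1.0, 2.0)) == pytest.approx(0.5)
        assert equivalent_ratios(dprime_pair=(1.0, 2.0)) == pytest.approx(0.5)

    def test_exactly_one_pair(self):
        with pytest.raises(ValueError):
            equivalent_ratios()
        with pytest.raises(ValueError):
            equivalent_ratios(dprime_pair=(1, 2), fisher_pair=(1, 4))


class TestFisherInformation:
    def test_identity_gamma(self):
        assert fisher_information(summary_from(np.eye(2), [3.0, 4.0])) == 25.0

    def test_info_limit_saturation(self):
        """Gamma0 = I, eps = 0.01, F' = (3,4): J0 = 25, Jinf = 100, J = 20;
        cross-checked by the matrix-inversion lemma."""
        fp = np.array([3.0, 4.0])
        eps = 0.01
        gamma = np.eye(2) + eps * np.outer(fp, fp)
        j = fisher_information(summary_from(gamma, fp))
        assert j == pytest.approx(20.0)
        j0 = 25.0
        assert j == pytest.approx(1.0 / (1.0 / j0 + eps))
        # matrix-inversion-lemma oracle
        inv = np.linalg.inv(np.eye(2)) - (
            eps * np.outer(fp, fp) / (1.0 + eps * float(fp @ fp))
        )
        assert j == pytest.approx(float(fp @ inv @ fp))

    def test_large_eps_kills_information(self):
        fp = np.array([3.0, 4.0])
        gamma = np.eye(2) + 1e6 * np.outer(fp, fp)
        assert fisher_information(summary_from(gamma, fp)) < 1e-4


try:
    from hypothesis import given, settings, strategies as st

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        dim=st.integers(2, 6),
        seed=st.integers(0, 10_000),
    )
    def test_closed_form_cc_always_bounded(dim, seed):
        """|C_k| <= 1 for every PD covariance and any readout weights."""
        rng = np.random.default_rng(seed)
        A = rng.standard_normal((dim, dim))
        gamma = A @ A.T + 1e-3 * np.eye(dim)
        w = rng.standard_normal(dim)
        cc = cc_closed_form(gamma, w)
        assert np.all(np.abs(cc) <= 1.0 + 1e-9)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(d=st.floats(1e-6, 50.0))
    def test_dprime_total_correlation_inverts(d):
        """d'(D) and D(d') = d'/sqrt(4 + d'^2) are mutual inverses."""
        D = d / np.sqrt(4.0 + d * d)
        assert dprime_from_D(D) == pytest.approx(d, rel=1e-9)
except ImportError:  # hypothesis is an optional test dependency
    pass
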