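import numpy as np
import pytest

from nlcc.decoders import (
    Decoder,
    binary_threshold_choice,
    decode,
    estimator_information,
    fit_coarse_decoder_shrunk,
    fit_network_decoder,
    fit_optimal_decoder,
    information_fraction,
    make_suboptimal_decoder,
)
from nlcc.encoding import simulate_xor
from nlcc.features import FeatureSet, SignalNoiseSummary, polynomial_features
from nlcc.trials import TrialTable


def summary_from(gamma, fp, mode="fine", ds=1.0):
    gamma = np.atleast_2d(np.asarray(gamma, dtype=float))
    fp = np.asarray(fp, dtype=float)
    dscale = ds if mode == "fine" else 1.0
    return SignalNoiseSummary(
        terms=[(i,) for i in range(fp.size)],
        F_prime=fp,
        Gamma=gamma,
        d_prime_terms=fp * dscale / np.sqrt(np.diagonal(gamma)),
        mode=mode,
        ds=ds,
        degenerate=np.zeros(fp.size, dtype=bool),
        F_ref=np.zeros(fp.size),
        s_ref=0.0,
    )


class TestOptimalDecoder:
    def test_identity_gamma_closed_form(self):
        """Gamma = I, F' = (3,4): w along F', estimator variance 1/25."""
        dec = fit_optimal_decoder(summary_from(np.eye(2), [3.0, 4.0]), ridge=0.0)
        np.testing.assert_allclose(dec.weights, np.array([3.0, 4.0]) / 25.0)
        np.testing.assert_allclose(dec.sigma2_opt, 1.0 / 25.0)
        # Monte-Carlo: decode Gaussian samples, check variance and unbiasedness
        rng = np.random.default_rng(0)
        n = 100_000
        s = rng.choice([-0.1, 0.1], size=n)
        R = np.outer(s, [3.0, 4.0]) + rng.normal(size=(n, 2))
        shat = R @ dec.weights + dec.offset
        assert abs(np.var(shat[s == 0.1]) - 1.0 / 25.0) < 0.002
        assert abs(shat[s == 0.1].mean() - 0.1) < 0.005

    def test_diagonal_gamma_weights(self):
        gamma = np.diag([1.0, 4.0, 0.25])
        fp = np.array([1.0, 2.0, -1.0])
        dec = fit_optimal_decoder(summary_from(gamma, fp), ridge=0.0)
        expected = fp / np.diagonal(gamma)
        np.testing.assert_allclose(
            dec.weights / dec.weights[0], expected / expected[0]
        )

    def test_pure_noise_feature_gets_zero_weight(self):
        gamma = np.eye(3)
        fp = np.array([3.0, 4.0, 0.0])
        dec = fit_optimal_decoder(summary_from(gamma, fp), ridge=0.0)
        assert abs(dec.weights[2]) < 1e-12
        np.testing.assert_allclose(dec.sigma2_opt, 1.0 / 25.0)

    def test_no_linear_decoder_beats_it(self, rng):
        dim = 4
        A = rng.standard_normal((dim, dim))
        gamma = A @ A.T + 0.5 * np.eye(dim)
        fp = rng.standard_normal(dim)
        j_opt = float(fp @ np.linalg.solve(gamma, fp))
        dec = fit_optimal_decoder(summary_from(gamma, fp), ridge=0.0)
        np.testing.assert_allclose(dec.sigma2_opt, 1.0 / j_opt)
        for _ in range(100):
            w = dec.weights + 0.1 * rng.standard_normal(dim)
            gain = float(w @ fp)
            if gain == 0:
                continue
            var = float(w @ gamma @ w) / gain**2  # unbiased-scale variance
            assert var >= dec.sigma2_opt - 1e-12

    def test_singular_needs_ridge(self):
        gamma = np.ones((2, 2))  # rank 1
        with pytest.raises(ValueError):
            fit_optimal_decoder(summary_from(gamma, [1.0, -1.0]), ridge=0.0)


class TestSuboptimalDecoders:
    def test_zero_flips_equals_signal_aligned(self, rng):
        summ = summary_from(np.diag([1.0, 2.0]), [1.0, 3.0])
        a = make_suboptimal_decoder(summ, "signal-aligned")
        b = make_suboptimal_decoder(summ, "sign-flipped", flip_fraction=0.0)
        np.testing.assert_allclose(a.weights, b.weights)

    def test_flip_fraction_counts(self):
        fp = np.ones(10)
        summ = summary_from(np.eye(10), fp)
        dec = make_suboptimal_decoder(summ, "sign-flipped", flip_fraction=0.4, seed=1)
        base = make_suboptimal_decoder(summ, "signal-aligned")
        flipped = np.sign(dec.weights) != np.sign(base.weights)
        assert flipped.sum() == 4  # 40% of 10 weights negated

    def test_identity_gamma_signal_aligned_is_optimal(self):
        summ = summary_from(np.eye(3), [1.0, -2.0, 0.5])
        opt = fit_optimal_decoder(summ, ridge=0.0)
        sub = make_suboptimal_decoder(summ, "signal-aligned")
        np.testing.assert_allclose(opt.weights, sub.weights, rtol=1e-9)

    def test_variance_ordering(self, rng):
        """sign-flipped >= signal-aligned >= optimal estimator variance."""
        dim = 8
        A = rng.standard_normal((dim, dim))
        gamma = A @ A.T + 0.3 * np.eye(dim)
        fp = rng.standard_normal(dim)
        summ = summary_from(gamma, fp)
        opt = fit_optimal_decoder(summ, ridge=0.0)
        ali = make_suboptimal_decoder(summ, "signal-aligned")
        fli = make_suboptimal_decoder(summ, "sign-flipped", flip_fraction=0.4, seed=2)

        def unbiased_var(w):
            gain = float(w @ fp)
            return float(w @ gamma @ w) / gain**2

        assert unbiased_var(opt.weights) <= unbiased_var(ali.weights) + 1e-12
        assert unbiased_var(ali.weights) <= unbiased_var(fli.weights) + 1e-12

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            make_suboptimal_decoder(summary_from(np.eye(2), [1, 1]), "bogus")


class TestDecode:
    def test_unit_weight_projects(self):
        f = FeatureSet(terms=[(0,), (1,)], values=np.arange(10.0).reshape(5, 2))
        dec = Decoder(weights=np.array([0.0, 1.0]), offset=0.0, terms=f.terms)
        np.testing.assert_allclose(decode(dec, f), f.values[:, 1])

    def test_zero_weights_constant(self):
        f = FeatureSet(terms=[(0,)], values=np.ones((4, 1)))
        dec = Decoder(weights=np.zeros(1), offset=2.5, terms=f.terms)
        np.testing.assert_allclose(decode(dec, f), 2.5)

    def test_term_mismatch_raises(self):
        f = FeatureSet(terms=[(0,), (1,)], values=np.ones((4, 2)))
        dec = Decoder(weights=np.zeros(2), terms=[(0,), (2,)])
        with pytest.raises(ValueError):
            decode(dec, f)

    def test_xor_quadratic_readout_is_perfect(self):
        t = simulate_xor(2000, flip_prob=0.0, seed=3)
        f = polynomial_features(t, max_degree=2)
        k = f.terms.index((0, 1))
        w = np.zeros(f.n_terms)
        w[k] = -1.0
        dec = Decoder(weights=w, offset=0.0, terms=f.terms)
        np.testing.assert_array_equal(decode(dec, f), t.s)


class TestBinaryThreshold:
    def test_squared_rule_and_tie_break(self):
        est = np.array([-3.0, -1.0, 0.0, 1.0, 3.0])
        out = binary_threshold_choice(est, threshold=2.0)
        np.testing.assert_array_equal(out, [1.0, -1.0, -1.0, -1.0, 1.0])
        # exact tie goes to the narrow category
        assert binary_threshold_choice(np.array([2.0]), 2.0)[0] == -1.0

    def test_zero_threshold_all_wide(self):
        est = np.array([-0.5, 0.1, 2.0])
        np.testing.assert_array_equal(binary_threshold_choice(est, 0.0), 1.0)

    def test_nonfinite_threshold(self):
        with pytest.raises(ValueError):
            binary_threshold_choice(np.ones(3), np.inf)


class TestNetworkDecoder:
    def test_matches_optimal_on_linear_code(self):
        """On a linear Gaussian code the net should reach the closed-form
        optimal variance within a few percent."""
        rng = np.random.default_rng(4)
        dim, n = 3, 12_000
        fp = np.array([1.0, -1.5, 0.5])
        s = rng.uniform(-0.5, 0.5, size=n)
        r = np.outer(s, fp) + rng.normal(size=(n, dim))
        table = TrialTable(s=s, r=r)
        dec = fit_network_decoder(table, n_train=10_000, seed=5, max_iter=250)
        j_opt = float(fp @ fp)  # Gamma = I
        s_h = rng.uniform(-0.5, 0.5, size=8000)
        r_h = np.outer(s_h, fp) + rng.normal(size=(8000, dim))
        held = TrialTable(s=s_h, r=r_h)
        frac = information_fraction(dec, held, sigma2_opt=1.0 / j_opt)
        assert 0.9 < frac < 1.1

    def test_n_train_bounds(self):
        t = TrialTable(s=np.zeros(10), r=np.zeros((10, 2)))
        with pytest.raises(ValueError):
            fit_network_decoder(t, n_train=11)
        with pytest.raises(ValueError):
            fit_network_decoder(t, hidden_layers=(0,))


class TestEstimatorInformation:
    def test_affine_invariance(self, rng):
        s = rng.choice([-0.1, 0.1], size=5000)
        est = 2.0 * s + rng.normal(scale=0.5, size=5000)
        j0 = estimator_information(est, s)
        j1 = estimator_information(-5.0 * est + 3.0, s)
        np.testing.assert_allclose(j0, j1, rtol=1e-9)

    def test_equals_inverse_variance_for_calibrated(self, rng):
        s = rng.choice([-0.5, 0.5], size=200_000)
        est = s + rng.normal(scale=0.2, size=s.size)
        assert abs(estimator_information(est, s) - 1.0 / 0.04) < 0.5


class TestSerialization:
    def test_json_roundtrip(self, tmp_path):
        dec = Decoder(
            weights=np.array([1.0, -2.0]),
            offset=0.3,
            kind="optimal",
            terms=[(0,), (1,)],
            threshold=5.0,
            sigma2_opt=0.1,
            meta={"mode": "coarse"},
        )
        path = tmp_path / "dec.json"
        dec.save(path)
        back = Decoder.load(path)
        np.testing.assert_allclose(back.weights, dec.weights)
        assert back.terms == dec.terms
        assert back.threshold == dec.threshold
        f = FeatureSet(terms=dec.terms, values=np.ones((3, 2)))
        np.testing.assert_allclose(decode(back, f), decode(dec, f))


def test_shrunk_coarse_decoder_calibration(rng):
    """Category means of the shrunk coarse readout sit at the labels."""
    n = 20_000
    s = rng.choice([9.0, 225.0], size=n)
    fp = np.array([0.02, -0.01, 0.015])
    r = np.outer(s, fp) + rng.normal(size=(n, 3))
    table = TrialTable(s=s, r=r)
    feats = polynomial_features(table, max_degree=1)
    dec = fit_coarse_decoder_shrunk(feats, table)
    shat = decode(dec, feats)
    assert abs(shat[s == 225.0].mean() - 225.0) < 2.0
    assert abs(shat[s == 9.0].mean() - 9.0) < 2.0
    assert dec.threshold == pytest.approx(117.0)
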