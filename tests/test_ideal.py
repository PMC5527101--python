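"""Ideal observers: closed forms vs. brute-force grid/quadrature oracles.

The closed forms are exact in the dense-tiling regime (population-summed
tuning flat over the stimulus range), so the oracle comparisons run with a
wide preferred-stimulus tiling; the oracles themselves evaluate the raw
Poisson likelihood on fine grids with no shared code path beyond the
tuning curves.
"""

import numpy as np
import pytest
from scipy.special import logsumexp

from genppc import ideal, tasks as T


def _log_evidence_oracle(r, spec, gains, grid):
    """Raw Poisson log-likelihood on a grid, marginalized over gains."""
    f = T.mean_rates(spec, grid, 1.0)
    logf = np.log(np.clip(f, 1e-300, None))
    F = f.sum(1)
    r = np.atleast_2d(r)
    parts = [r @ logf.T + np.log(g) * r.sum(1)[:, None] - g * F[None, :]
             for g in np.atleast_1d(gains)]
    return logsumexp(np.stack(parts), axis=0) - np.log(len(np.atleast_1d(gains)))


class TestCueCombination:
    def test_single_spike_center_of_mass(self, cc_spec):
        r1 = np.zeros(50)
        j = int(np.argmin(np.abs(cc_spec.preferred - 2.0)))
        r1[j] = 1
        est, ok = ideal.cc_linear_estimate(r1, np.zeros(50), cc_spec.preferred)
        assert ok[0]
        assert est[0] == pytest.approx(cc_spec.preferred[j])

    def test_symmetric_counts_give_zero(self, cc_spec):
        r = np.ones(50)
        est, _ = ideal.cc_linear_estimate(r, r, cc_spec.preferred)
        assert est[0] == pytest.approx(0.0, abs=1e-12)

    def test_zero_total_count_flagged(self, cc_spec):
        _, ok = ideal.cc_linear_estimate(np.zeros(50), np.zeros(50),
                                         cc_spec.preferred)
        assert not ok[0]

    def test_closed_form_matches_grid_posterior_high_gain(self, wide_spec):
        """Spike-weighted mean vs. numeric posterior mean, within 0.05 on
        >= 99% of 1000 high-gain trials."""
        rng = np.random.default_rng(8)
        s = rng.uniform(-10, 10, 1000)
        r1 = rng.poisson(T.mean_rates(wide_spec, s, 25.0))
        r2 = rng.poisson(T.mean_rates(wide_spec, s, 25.0))
        est, ok = ideal.cc_linear_estimate(r1, r2, wide_spec.preferred)
        grid = ideal.GridSpec(-10.5, 10.5, 601)
        ps = ideal.grid_posterior_mean([r1, r2], "cc", [wide_spec] * 2,
                                       [np.array(T.CC_HIGH_GAINS)] * 2, grid)
        assert np.mean(np.abs(est[ok] - ps.mean[ok]) < 0.05) >= 0.99


class TestGridPosterior:
    def test_flat_likelihood_returns_prior_mean(self, cc_spec, wide_spec):
        r = np.zeros((1, 50))
        ps = ideal.grid_posterior_mean([r, r], "cc", [cc_spec] * 2,
                                       [[0.5, 1.0]] * 2)
        assert ps.mean[0] == pytest.approx(0.0, abs=1e-9)
        # with a flat population rate the posterior is the uniform prior
        rw = np.zeros((1, wide_spec.n))
        psw = ideal.grid_posterior_mean([rw, rw], "cc", [wide_spec] * 2,
                                        [[0.5, 1.0]] * 2)
        assert psw.sd[0] == pytest.approx(20 / np.sqrt(12), rel=0.01)

    def test_ct_sum_posterior_matches_hand_enumeration(self):
        """With one spike per population, the posterior over each variable
        is proportional to its tuning curve; the sum's mean is the sum of
        the component means.  Hand-computed on a 3-neuron toy."""
        spec = T.TuningSpec("gaussian", np.array([-2.0, 0.0, 2.0]), width=2.0)
        r1 = np.array([[1, 0, 0]])
        r2 = np.array([[0, 0, 1]])
        grid = ideal.GridSpec(-8, 8, 321)
        ps = ideal.grid_posterior_mean([r1, r2], "ct", [spec] * 2,
                                       [[1.0], [1.0]], grid)
        g = grid.points
        def hand_mean(pref):
            w = np.exp(-0.5 * ((g - pref) / 2) ** 2
                       - T.mean_rates(spec, g, 1.0).sum(1))
            return (w * g).sum() / w.sum()
        assert ps.mean[0] == pytest.approx(hand_mean(-2) + hand_mean(2),
                                           abs=1e-9)

    def test_posterior_sd_decreases_with_gain(self, cc_spec):
        """Monte-Carlo monotonicity: average posterior SD shrinks as the
        (known) gain grows."""
        rng = np.random.default_rng(5)
        sds = []
        for g in (0.25, 0.75, 1.25):
            s = rng.uniform(-10, 10, 1000)
            r1 = rng.poisson(T.mean_rates(cc_spec, s, g))
            r2 = rng.poisson(T.mean_rates(cc_spec, s, g))
            ps = ideal.grid_posterior_mean([r1, r2], "cc", [cc_spec] * 2,
                                           [[g], [g]])
            sds.append(ps.mean.std() and ps.sd.mean())
        assert sds[0] > sds[1] > sds[2]

    def test_resolution_guard(self, cc_spec):
        with pytest.raises(ValueError):
            ideal.grid_posterior_mean([np.zeros((1, 50))], "cc", [cc_spec],
                                      [[1.0]], ideal.GridSpec(-10, 10, 20))


class TestKalman:
    def test_zero_counts_pure_prediction(self, cc_spec):
        mu, var = ideal.kalman_step(2.0, 1.5, np.zeros(50),
                                    cc_spec.preferred, cc_spec.width)
        assert mu[0] == pytest.approx(0.9 * 2.0)
        assert var[0] == pytest.approx(0.9 ** 2 * 1.5 + 1.0)

    def test_static_repeated_observations_shrink_variance(self, cc_spec):
        rng = np.random.default_rng(0)
        r = rng.poisson(T.mean_rates(cc_spec, np.zeros(5), 1.0))
        r[r.sum(1) == 0, 25] = 1  # ensure informative steps
        mu, var = np.zeros(5), np.full(5, 10.0)
        prev = var.copy()
        for t in range(5):
            mu, var = ideal.kalman_step(mu, var, r, cc_spec.preferred,
                                        cc_spec.width, gamma=0.0,
                                        sigma_eta2=0.0)
            assert np.all(var < prev)
            prev = var.copy()

    def test_recursion_matches_grid_filter(self):
        """25-step recursion vs. a discretized Bayes filter with the raw
        Poisson likelihood and AR(1) transition kernel."""
        spec = T.make_tuning("kf", {"preferred": np.linspace(-30, 30, 121)})
        b = T.generate_trials("kf", "all_g", 10, seed=5,
                              tuning_overrides={"preferred":
                                                np.linspace(-30, 30, 121)})
        mus, _ = ideal.kalman_filter(b.inputs, spec)
        grid = np.linspace(-25, 25, 1001)
        dx = grid[1] - grid[0]
        K = np.exp(-0.5 * (grid[:, None] - 0.9 * grid[None, :]) ** 2)
        f = T.mean_rates(spec, grid, 1.0)
        logf = np.log(np.clip(f, 1e-300, None))
        F = f.sum(1)
        for i in range(b.n):
            lp = -0.5 * grid ** 2 / (T.STIM_RANGE ** 2 / 3)
            for t in range(b.inputs.shape[1]):
                p = np.exp(lp - lp.max())
                p = K @ (p / p.sum())
                ll = (b.inputs[i, t] @ logf.T
                      + np.log(b.gains[i, t]) * b.inputs[i, t].sum()
                      - b.gains[i, t] * F)
                lp = np.log(np.clip(p / p.sum(), 1e-300, None)) + ll
                post = np.exp(lp - lp.max())
                post /= post.sum()
                assert abs(post @ grid - mus[i, t]) < dx

    def test_nonpositive_variance_rejected(self, cc_spec):
        with pytest.raises(ValueError):
            ideal.kalman_step(0.0, 0.0, np.zeros(50), cc_spec.preferred, 2.0)


class TestBinaryCategorization:
    def test_equal_class_sds_give_zero_llr(self, cc_spec):
        r = np.random.default_rng(0).poisson(1.0, (20, 50))
        d = ideal.bc_llr(r, cc_spec.preferred, cc_spec.width, 3.0, 3.0)
        assert np.allclose(d, 0.0)

    def test_zero_counts_give_zero_llr(self, cc_spec):
        d = ideal.bc_llr(np.zeros((1, 50)), cc_spec.preferred, cc_spec.width)
        assert d[0] == pytest.approx(0.0)

    def test_closed_form_matches_quadrature(self):
        """Eq-level LLR vs. 1-D quadrature of the raw class-conditional
        Poisson likelihood, |diff| < 1e-3 over 1000 random trials."""
        ov = {"preferred": np.linspace(-60, 60, 121), "width": T.SIGMA_F}
        spec = T.make_tuning("bc", ov)
        b = T.generate_trials("bc", "all_g", 1000, seed=3,
                              tuning_overrides=ov)
        d_cf = ideal.bc_llr(b.inputs, spec.preferred, spec.width)
        grid = np.linspace(-55, 55, 2201)
        L = _log_evidence_oracle(b.inputs, spec, [b.gains[0]], grid)
        # per-trial known gain
        parts = {}
        for sig in (T.BC_SIGMA1, T.BC_SIGMA2):
            lp = -0.5 * (grid / sig) ** 2 - np.log(sig)
            vals = np.empty(b.n)
            for g in np.unique(b.gains):
                m = b.gains == g
                Lg = _log_evidence_oracle(b.inputs[m], spec, [g], grid)
                vals[m] = logsumexp(Lg + lp[None, :], axis=1)
            parts[sig] = vals
        d_or = parts[T.BC_SIGMA1] - parts[T.BC_SIGMA2]
        assert np.max(np.abs(d_cf - d_or)) < 1e-3


class TestCausalInference:
    def test_zero_counts_give_even_odds(self, cc_spec):
        d = ideal.ci_llr(np.zeros((1, 50)), np.zeros((1, 50)),
                         cc_spec.preferred, cc_spec.width, 0.01)
        assert d[0] == pytest.approx(0.0)
        assert ideal.llr_to_prob(d)[0] == pytest.approx(0.5)

    def test_identical_strong_responses_favor_common_cause(self, wide_spec):
        rng = np.random.default_rng(1)
        r = rng.poisson(T.mean_rates(wide_spec, np.zeros(20), 2.5))
        d = ideal.ci_llr(r, r, wide_spec.preferred, wide_spec.width, 0.01)
        assert np.all(d > 0)

    def test_closed_form_matches_quadrature(self):
        """LLR vs. 1-D quadrature marginalization of the raw Poisson
        likelihoods under the Gaussian stimulus prior, |diff| < 1e-2."""
        ov = {"preferred": np.linspace(-60, 60, 121)}
        spec = T.make_tuning("ci", ov)
        b = T.generate_trials("ci", "all_g", 1000, seed=4,
                              tuning_overrides=ov)
        r1, r2 = b.split()
        Js = 1 / T.CI_SIGMA_S ** 2
        d_cf = ideal.ci_llr(r1, r2, spec.preferred, spec.width, Js)
        grid = np.linspace(-55, 55, 2201)
        lp = -0.5 * (grid / T.CI_SIGMA_S) ** 2
        lp -= logsumexp(lp)
        L1 = np.empty((b.n, len(grid)))
        L2 = np.empty((b.n, len(grid)))
        for g in np.unique(b.gains):
            m1 = b.gains[:, 0] == g
            m2 = b.gains[:, 1] == g
            L1[m1] = _log_evidence_oracle(r1[m1], spec, [g], grid)
            L2[m2] = _log_evidence_oracle(r2[m2], spec, [g], grid)
        log_c = logsumexp(L1 + L2 + lp[None, :], axis=1)
        log_s = (logsumexp(L1 + lp[None, :], axis=1)
                 + logsumexp(L2 + lp[None, :], axis=1))
        assert np.max(np.abs(d_cf - (log_c - log_s))) < 1e-2


class TestVisualSearch:
    def test_single_item_llr_equals_local_llr(self):
        b = T.generate_trials("vs", "all_g", 50, seed=6)
        r = [b.split()[0]]
        d, d_i = ideal.vs_llr(r, T.VS_TARGET, b.specs[0])
        assert np.allclose(d, d_i[:, 0])

    def test_equal_local_llrs_pass_through(self):
        b = T.generate_trials("vs", "all_g", 20, seed=7)
        r0 = b.split()[0]
        d, d_i = ideal.vs_llr([r0, r0, r0], T.VS_TARGET, b.specs[0])
        assert np.allclose(d, d_i[:, 0], atol=1e-12)

    def test_quadrature_refinement(self):
        """Local LLRs at the default resolution vs. 10x finer, < 1e-4."""
        b = T.generate_trials("vs", "all_g", 300, seed=8)
        _, d1 = ideal.vs_llr(b.split(), T.VS_TARGET, b.specs[0], n_quad=720)
        _, d2 = ideal.vs_llr(b.split(), T.VS_TARGET, b.specs[0], n_quad=7200)
        assert np.max(np.abs(d1 - d2)) < 1e-4

    def test_zero_baseline_rejected(self):
        spec = T.make_tuning("vs", {"baseline": 0.0})
        with pytest.raises(ValueError):
            ideal.vs_llr([np.zeros((1, 20))], T.VS_TARGET, spec)


class TestStimulusDemixing:
    def test_invisible_source_keeps_prior(self):
        model = T.MixingModel.create(seed=1)
        model.weights[:, 2] = 0.0
        b = T.generate_trials("sd", "all_g", 30, seed=2, mixing=model)
        post = ideal.sd_posterior(b.inputs, model, mc=2000, seed=3)
        assert np.allclose(post[:, 2], 0.5, atol=1e-9)

    def test_single_source_matches_hand_bayes(self):
        """One source, one odorant, concentration grid of one point:
        two-hypothesis Bayes ratio computed by hand."""
        model = T.MixingModel(n_sources=1, n_odorants=1, n_per_odorant=2,
                              weights=np.array([[1.0]]),
                              f=np.array([[0.5, 1.0]]),
                              b=np.array([[0.2, 0.3]]),
                              conc_lo=4.0, conc_hi=4.0)
        r = np.array([[3, 1]])
        post = ideal.sd_posterior(r, model, seed=0, conc_grid=1)
        lam1 = 4.0 * model.f[0] + model.b[0]       # present at c=4
        lam0 = model.b[0]                          # absent
        def lik(lam):
            return np.exp(np.sum(r[0] * np.log(lam) - lam))
        expect = lik(lam1) / (lik(lam1) + lik(lam0))
        assert post[0, 0] == pytest.approx(expect, rel=1e-9)

    def test_mc_convergence(self):
        model = T.MixingModel.create(seed=4)
        b = T.generate_trials("sd", "all_g", 40, seed=5, mixing=model)
        p1 = ideal.sd_posterior(b.inputs, model, mc=10_000, seed=6)
        p2 = ideal.sd_posterior(b.inputs, model, mc=20_000, seed=7)
        assert np.max(np.abs(p1 - p2)) < 0.05

    def test_small_mc_rejected(self):
        model = T.MixingModel.create(seed=1)
        with pytest.raises(ValueError):
            ideal.sd_posterior(np.zeros((1, 40)), model, mc=50)


class TestLlrToProb:
    @pytest.mark.parametrize("d,odds,expect", [
        (0.0, 1.0, 0.5),
        (1e9, 1.0, 1.0),
        (0.0, 3.0, 0.75),
    ])
    def test_values(self, d, odds, expect):
        assert ideal.llr_to_prob(np.array([d]), odds)[0] == pytest.approx(expect)

    def test_probabilities_sum_to_one(self):
        d = np.random.default_rng(0).normal(0, 5, 100)
        p = ideal.llr_to_prob(d)
        assert np.all((p >= 0) & (p <= 1))
        assert np.allclose(p + ideal.llr_to_prob(-d), 1.0, atol=1e-12)
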