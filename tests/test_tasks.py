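"""Trial generation: gain sets, Poisson statistics, reproducibility."""

import numpy as np
import pytest

from genppc import tasks as T


class TestGainConditions:
    def test_cc_all_g_is_exact_25_pair_grid(self):
        r = T.gain_conditions("cc", "all_g")
        pairs = {tuple(p) for p in r.gain_sets}
        expect = {(a, b) for a in (0.25, 0.5, 0.75, 1.0, 1.25)
                  for b in (0.25, 0.5, 0.75, 1.0, 1.25)}
        assert pairs == expect

    def test_cc_restricted_pairs(self):
        r = T.gain_conditions("cc", "restricted_g")
        assert {tuple(p) for p in r.gain_sets} == {(0.25, 0.25), (1.25, 1.25)}

    def test_bc_six_gains_equal_frequency(self):
        r = T.gain_conditions("bc", "all_g")
        assert sorted(r.gain_sets.ravel()) == sorted(T.BC_GAINS)
        g = r.sample(60_000, np.random.default_rng(0))
        _, counts = np.unique(g, return_counts=True)
        assert counts.min() > 0.9 * 10_000 and counts.max() < 1.1 * 10_000

    def test_bc_restricted_single_gain(self):
        r = T.gain_conditions("bc", "restricted_g")
        assert r.gain_sets.ravel().tolist() == [1.68]

    def test_ci_all_g_cardinality(self):
        r = T.gain_conditions("ci", "all_g")
        assert len(r.gain_sets) == 25
        assert set(np.unique(r.gain_sets)) == {0.5, 1.0, 1.5, 2.0, 2.5}

    def test_kf_uniform_range(self):
        r = T.gain_conditions("kf", "all_g")
        g = r.sample(1000, np.random.default_rng(0))
        assert g.shape == (1000, T.KF_T)
        assert g.min() >= 0.3 and g.max() <= 3.0

    def test_vs_per_stimulus_gains(self):
        g = T.gain_conditions("vs", "all_g").sample(500, np.random.default_rng(1))
        assert set(np.unique(g)) == {0.5, 3.0}
        # independent per stimulus: all four columns vary
        assert all(len(np.unique(g[:, i])) == 2 for i in range(4))
        gr = T.gain_conditions("vs", "restricted_g").sample(500, np.random.default_rng(1))
        assert all(len(np.unique(row)) == 1 for row in gr)

    def test_unknown_regime_raises(self):
        with pytest.raises(ValueError):
            T.gain_conditions("cc", "bogus")


class TestTuning:
    def test_mt_speed_default_parameters(self):
        spec = T.make_tuning("mt_speed")
        assert spec.extra == {"r0": 0.5, "A": 5.0, "s0": 1.0, "sigma": 1.0,
                              "B": 10.0, "alpha": 10.0, "beta": 2.0,
                              "gamma": 3.0}

    def test_zero_amplitude_means_zero_rates(self):
        spec = T.make_tuning("cc", {"amplitude": 0.0})
        lam = T.mean_rates(spec, np.array([0.0, 3.0]), 1.7)
        assert np.all(lam == 0.0)

    def test_coherence_baseline_population_rate_matched(self):
        """Summed mean rate, averaged over the stimulus grid, is the same
        at every coherence as at c = 1."""
        spec = T.make_tuning("coherence_baseline")
        grid = np.linspace(-T.STIM_RANGE, T.STIM_RANGE, 201)
        ref = T.mean_rates(spec, grid, 1.0).sum(axis=1).mean()
        for c in (0.05, 0.3, 0.8):
            tot = T.mean_rates(spec, grid, c).sum(axis=1).mean()
            assert tot == pytest.approx(ref, abs=1e-9)

    def test_mt_speed_peak_rate_and_location_shift_with_contrast(self):
        spec = T.make_tuning("mt_speed")
        s = np.linspace(0.2, 30, 500)
        curves = {c: T.mean_rates(spec, s, c)[:, 25] for c in (0.2, 0.9)}
        peaks = {c: (curves[c].max(), s[np.argmax(curves[c])])
                 for c in curves}
        assert peaks[0.9][0] > peaks[0.2][0]      # peak response grows
        assert peaks[0.9][1] != peaks[0.2][1]     # preferred speed moves

    def test_negative_rate_override_rejected(self):
        with pytest.raises(ValueError):
            T.make_tuning("cc", {"amplitude": -1.0})

    def test_unknown_task_rejected(self):
        with pytest.raises(ValueError):
            T.make_tuning("nonsense")


class TestEncodePoisson:
    def test_zero_gain_gives_zero_counts(self, cc_spec):
        r = T.encode_poisson(np.zeros(10), 0.0, cc_spec, 3)
        assert np.all(r == 0)

    def test_poisson_mean_matches_rate(self, cc_spec):
        """A neuron probed at its preferred stimulus with amplitude 1 and
        gain 2 fires 2 spikes on average."""
        j = 25
        s = np.full(100_000, cc_spec.preferred[j])
        counts = T.encode_poisson(s, 2.0, cc_spec, 11)[:, j]
        se = counts.std() / np.sqrt(len(counts))
        assert abs(counts.mean() - 2.0) < 3 * se

    def test_mean_variance_ratio_all_families(self):
        """Poisson moment check: empirical mean ~ variance per neuron."""
        for task in ("cc", "vs", "bc"):
            spec = T.make_tuning(task)
            s = np.full(100_000, float(np.median(spec.preferred)))
            counts = T.encode_poisson(s, 1.0, spec, 5)
            m, v = counts.mean(0), counts.var(0)
            busy = m > 0.5
            assert np.all(np.abs(v[busy] / m[busy] - 1) < 0.05)


class TestGenerateTrials:
    def test_identical_seed_identical_batch(self):
        a = T.generate_trials("ci", "all_g", 100, seed=9)
        b = T.generate_trials("ci", "all_g", 100, seed=9)
        assert np.array_equal(a.inputs, b.inputs)
        assert np.array_equal(a.stimuli, b.stimuli)
        assert np.array_equal(a.gains, b.gains)

    def test_kalman_stationary_variance(self):
        """AR(1) with decay gamma and unit drive has stationary variance
        sigma_eta^2 / (1 - (1-gamma)^2) = 5.263."""
        b = T.generate_trials("kf", "all_g", 50_000, seed=1, pop_size=3)
        v = b.stimuli[:, -1].var()  # t=25 >> mixing time from U[-10,10] start
        expect = T.KF_SIGMA_ETA2 / (1 - (1 - T.KF_GAMMA) ** 2)
        # start-prior variance 33.3 decays by 0.9^50 ~ 0.005 -> negligible
        assert v == pytest.approx(expect + 33.3 * 0.9 ** 50, rel=0.02)

    def test_conflict_zero_means_identical_cues(self):
        b = T.generate_trials("cc", "high_g_restricted", 500, seed=2,
                              conflict=0.0, strict_conflict=False)
        assert np.allclose(b.stimuli[:, 0], b.stimuli[:, 1])

    def test_strict_conflict_rejects_offgrid_offset(self):
        with pytest.raises(ValueError):
            T.generate_trials("cc", "all_g", 10, seed=0, conflict=1.23,
                              strict_conflict=True)

    def test_visual_search_structure(self):
        b = T.generate_trials("vs", "all_g", 300, seed=3)
        assert b.inputs.shape == (300, 4 * 20)
        assert len(b.pops) == 4
        present = b.target == 1
        # target-present displays contain the target orientation
        assert np.all(np.any(np.isclose(b.stimuli[present], T.VS_TARGET),
                             axis=1))

    def test_ct_target_is_sum(self):
        b = T.generate_trials("ct", "all_g", 50, seed=4)
        assert np.allclose(b.target, b.stimuli.sum(axis=1))

    def test_sd_counts_nonnegative_and_mixture_consistent(self):
        b = T.generate_trials("sd", "all_g", 200, seed=5)
        assert b.inputs.min() >= 0
        assert b.target.shape == (200, 4)
        model = b.meta["mixing"]
        assert np.all(model.weights >= 0)
        assert np.all(model.f > 0) and np.all(model.b > 0)

    def test_n_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            T.generate_trials("cc", "all_g", 0, seed=0)


class TestSimulateSubject:
    def test_full_lapse_is_pure_guessing(self):
        s = np.random.default_rng(0).normal(0, 5, 20_000)
        choices = T.simulate_subject(s, 1.0, lambda sig: np.full_like(sig, 2.0),
                                     lapse=0.5, seed=1)
        assert abs(choices.mean() - 0.5) < 3 * 0.5 / np.sqrt(len(s))

    def test_no_lapse_deterministic_given_measurement(self):
        """With lapse 0 and a fixed boundary, rerunning with the same seed
        reproduces choices exactly (noise is in the measurement only)."""
        s = np.linspace(-10, 10, 500)
        a = T.simulate_subject(s, 2.0, lambda sig: np.full_like(sig, 3.0),
                               lapse=0.0, seed=7)
        b = T.simulate_subject(s, 2.0, lambda sig: np.full_like(sig, 3.0),
                               lapse=0.0, seed=7)
        assert np.array_equal(a, b)

    def test_opt_boundary_matches_ideal_accuracy(self):
        """A lapse-free subject using the OPT boundary at matched noise is
        as accurate as the measurement-level ideal observer."""
        from genppc import heuristics as H
        rng = np.random.default_rng(3)
        n = 40_000
        label = rng.integers(2, size=n)          # 0 -> class 1
        sd = np.where(label == 0, T.BC_SIGMA1, T.BC_SIGMA2)
        s = rng.normal(0, sd)
        sigma = 2.0
        opt = H.BoundaryModel("OPT", np.array([]), 0.0)
        choices = T.simulate_subject(s, sigma, opt, lapse=0.0, seed=4)
        acc = np.mean(choices == (label == 0))
        # ideal observer on the same internal-measurement model
        x = s + sigma * np.random.default_rng(4).standard_normal(n)
        k = opt.threshold(np.full(n, sigma))
        acc_ideal = np.mean((np.abs(x) < k) == (label == 0))
        assert abs(acc - acc_ideal) < 3 * np.sqrt(0.25 / n) * 2

    def test_lapse_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            T.simulate_subject(np.zeros(3), 1.0, lambda s: s, lapse=0.7, seed=0)
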