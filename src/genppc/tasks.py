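"""Synthetic trial generation for the psychophysical task battery.

Each task presents one or more stimulus variables to populations of
independent Poisson neurons whose mean rates are given by parameterized
tuning curves scaled by trial-to-trial gain variables ``g`` (higher gain =
more spikes = more reliable evidence).  Supervised targets are the actual
stimulus values (continuous tasks) or the correct class labels (categorical
tasks) -- never probabilities.

Tasks
-----
``cc``   linear cue combination (two cues, common stimulus)
``cc3``  three-cue combination (used by the modular experiments)
``ct``   coordinate transformation (target = s1 + s2)
``kf``   Kalman filtering / tracking of an AR(1) signal
``bc``   binary categorization (equal-mean, unequal-variance classes)
``ci``   causal inference (same source vs. different sources)
``sd``   stimulus demixing (odor-source presence in mixtures)
``vs``   visual search for a target among heterogeneous distractors

Encoding variants ``coherence_baseline`` and ``mt_speed`` implement
non-multiplicative reliability codings for the cue-combination task.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

CONTINUOUS_TASKS = ("cc", "cc3", "ct", "kf")
CATEGORICAL_TASKS = ("bc", "ci", "sd", "vs")
TASKS = CONTINUOUS_TASKS + CATEGORICAL_TASKS
ENCODING_VARIANTS = ("coherence_baseline", "mt_speed")

# population sizes per input population
_POP_SIZE = {"cc": 50, "cc3": 50, "ct": 50, "kf": 50, "bc": 50, "ci": 50,
             "vs": 20, "sd": 10}
_N_POPS = {"cc": 2, "cc3": 3, "ct": 2, "kf": 1, "bc": 1, "ci": 2, "vs": 4,
           "sd": 4}

#: default stimulus-prior half-width (a.u.) for cc/ct/kf and the tuning grid
STIM_RANGE = 10.0
TILE_RANGE = 12.0
SIGMA_F = 2.0

# binary categorization: equal means, unequal SDs (class 1 narrow).
# The tuning width is chosen so the six gain values map to sensory noise
# sigma between ~2 (full contrast) and ~7, the range the gain set was
# derived from; sigma(g) = sigma_f / sqrt(g * total rate).
BC_SIGMA1 = 3.0
BC_SIGMA2 = 12.0
BC_TILE = 40.0
BC_SIGMA_F = 10.0

# causal inference: Gaussian stimulus prior with precision J_s
CI_SIGMA_S = 10.0
CI_TILE = 30.0

# Kalman filtering AR(1) dynamics
KF_GAMMA = 0.1
KF_SIGMA_ETA2 = 1.0
KF_T = 25

# visual search
VS_N_ITEMS = 4
VS_KAPPA = 8.0
VS_BASELINE = 0.1
VS_TARGET = np.pi / 2


@dataclass
class TuningSpec:
    """Tuning-curve family for one input population.

    ``preferred`` holds the preferred stimuli (degrees or a.u.); ``width``
    is the Gaussian SD sigma_f (or, for von Mises, the concentration kappa
    lives in ``extra``); ``amplitude`` and ``baseline`` are peak and offset
    rates.  ``extra`` carries family-specific parameters.
    """

    family: str
    preferred: np.ndarray
    width: float = SIGMA_F
    amplitude: float = 1.0
    baseline: float = 0.0
    extra: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.preferred)


def _tile(lo: float, hi: float, n: int) -> np.ndarray:
    return np.linspace(lo, hi, n)


def make_tuning(task: str, overrides: Optional[dict] = None, n: Optional[int] = None) -> TuningSpec:
    """Default :class:`TuningSpec` for a task or encoding-variant name.

    Gaussian tuning for cc/cc3/ct/kf/bc/ci, von Mises for vs, linear for sd,
    and the two non-multiplicative variants for the robustness experiments.
    ``overrides`` are applied last (field name -> value).
    """
    overrides = dict(overrides or {})
    if task in ("cc", "cc3", "ct", "kf"):
        m = n if n is not None else _POP_SIZE[task]
        spec = TuningSpec("gaussian", _tile(-TILE_RANGE, TILE_RANGE, m))
    elif task == "bc":
        m = n if n is not None else _POP_SIZE["bc"]
        spec = TuningSpec("gaussian", _tile(-BC_TILE, BC_TILE, m),
                          width=BC_SIGMA_F)
    elif task == "ci":
        m = n if n is not None else _POP_SIZE["ci"]
        spec = TuningSpec("gaussian", _tile(-CI_TILE, CI_TILE, m))
    elif task == "vs":
        m = n if n is not None else _POP_SIZE["vs"]
        # preferred orientations tile [0, pi); endpoint excluded (circular)
        pref = np.arange(m) * np.pi / m
        spec = TuningSpec("von_mises", pref, baseline=VS_BASELINE,
                          extra={"kappa": VS_KAPPA})
    elif task == "coherence_baseline":
        m = n if n is not None else _POP_SIZE["cc"]
        spec = TuningSpec("coherence_baseline", _tile(-TILE_RANGE, TILE_RANGE, m))
        spec.extra["beta"] = _solve_coherence_beta(spec)
    elif task == "mt_speed":
        m = n if n is not None else _POP_SIZE["cc"]
        # preferred speeds, log-spaced (speed is a positive quantity)
        pref = np.geomspace(0.25, 8.0, m)
        spec = TuningSpec("mt_speed", pref, extra={
            "r0": 0.5, "A": 5.0, "s0": 1.0, "sigma": 1.0, "B": 10.0,
            "alpha": 10.0, "beta": 2.0, "gamma": 3.0})
    else:
        raise ValueError(f"unknown task {task!r}")
    for k, v in overrides.items():
        if k in ("family", "preferred", "width", "amplitude", "baseline"):
            setattr(spec, k, v)
        else:
            spec.extra[k] = v
    if spec.amplitude < 0 or spec.baseline < 0:
        raise ValueError("tuning override produced negative rates")
    return spec


def _solve_coherence_beta(spec: TuningSpec) -> np.ndarray:
    """Baseline vector beta for f(s,c) = c f(s) + (1-c) beta.

    beta is chosen so the population-summed mean rate, averaged over the
    stimulus grid, is independent of the coherence c.  With a uniform beta
    the constraint sum_j beta_j = <sum_j f_j(s)>_s solves this exactly for
    every c.
    """
    grid = np.linspace(-STIM_RANGE, STIM_RANGE, 201)
    f = _gaussian_rates(spec, grid)  # (G, n)
    mean_total = f.sum(axis=1).mean()
    return np.full(spec.n, mean_total / spec.n)


def _gaussian_rates(spec: TuningSpec, s: np.ndarray) -> np.ndarray:
    s = np.atleast_1d(np.asarray(s, dtype=float))
    d = s[:, None] - spec.preferred[None, :]
    return spec.baseline + spec.amplitude * np.exp(-0.5 * (d / spec.width) ** 2)


def _von_mises_rates(spec: TuningSpec, s: np.ndarray) -> np.ndarray:
    s = np.atleast_1d(np.asarray(s, dtype=float))
    kappa = spec.extra["kappa"]
    d = 2.0 * (s[:, None] - spec.preferred[None, :])
    return spec.baseline + spec.amplitude * np.exp(kappa * (np.cos(d) - 1.0))


def _mt_speed_gain(spec: TuningSpec, c: np.ndarray) -> np.ndarray:
    e = spec.extra
    return 1.0 / ((e["alpha"] * np.asarray(c, float)) ** (-e["beta"]) + e["gamma"])


def mean_rates(spec: TuningSpec, s, g=1.0) -> np.ndarray:
    """Mean firing rates f(s, c) for stimulus values ``s`` (shape (m,)).

    For multiplicative families ``g`` scales the rates; for
    ``coherence_baseline`` and ``mt_speed`` the second argument is the
    contrast/coherence c acting through the family-specific rule.
    Returns an array of shape (m, n_neurons).
    """
    s = np.atleast_1d(np.asarray(s, dtype=float))
    gv = np.asarray(g, dtype=float)
    g = gv.reshape(-1, 1) if gv.ndim else float(gv)
    if spec.family == "gaussian":
        return g * _gaussian_rates(spec, s)
    if spec.family == "von_mises":
        return g * _von_mises_rates(spec, s)
    if spec.family == "coherence_baseline":
        c = np.atleast_1d(np.asarray(g, dtype=float)).reshape(-1, 1)
        if np.any((c < 0) | (c > 1)):
            raise ValueError("coherence c must lie in [0, 1]")
        return c * _gaussian_rates(spec, s) + (1 - c) * spec.extra["beta"][None, :]
    if spec.family == "mt_speed":
        e = spec.extra
        c = np.atleast_1d(np.asarray(g, dtype=float)).reshape(-1, 1)
        gc = _mt_speed_gain(spec, c)
        pivot = e["B"] * gc * spec.preferred[None, :] + e["s0"]
        z = np.log((s[:, None] + e["s0"]) / pivot)
        return e["r0"] + e["A"] * gc * np.exp(-0.5 * (z / e["sigma"]) ** 2)
    raise ValueError(f"unknown tuning family {spec.family!r}")


def encode_poisson(s, g, spec: TuningSpec, rng) -> np.ndarray:
    """Independent Poisson spike counts, mean ``g * f(s)`` per neuron.

    ``rng`` may be an integer seed or a :class:`numpy.random.Generator`.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    lam = mean_rates(spec, s, g)
    if np.any(lam < 0):
        raise ValueError("negative mean rate: broken TuningSpec")
    return rng.poisson(lam)


# ---------------------------------------------------------------------------
# gain regimes


@dataclass
class GainRegime:
    """Training/testing gain conditions for one task.

    ``gain_sets`` is either an explicit list of per-population gain tuples
    (sampled uniformly per trial) or, for per-step/per-source continuous
    regimes, the string ``"uniform"`` together with ``lo``/``hi`` bounds.
    """

    task: str
    regime: str
    gain_sets: Optional[np.ndarray] = None  # (n_conditions, n_pops)
    lo: Optional[float] = None
    hi: Optional[float] = None
    per_step_choices: Optional[tuple] = None

    def sample(self, n: int, rng: np.random.Generator, n_steps: int = KF_T) -> np.ndarray:
        """Per-trial gain tuples, shape (n, n_pops) or (n, T) for kf/sd-style."""
        if self.task == "kf":
            if self.per_step_choices is not None:
                return rng.choice(self.per_step_choices, size=(n, n_steps))
            return rng.uniform(self.lo, self.hi, size=(n, n_steps))
        if self.task == "sd":
            k = _N_POPS["sd"]
            if self.gain_sets is not None:
                idx = rng.integers(len(self.gain_sets), size=n)
                return np.asarray(self.gain_sets)[idx]
            return rng.uniform(self.lo, self.hi, size=(n, k))
        if self.regime == "all_g" and self.task == "vs":
            return rng.choice(self.per_step_choices, size=(n, VS_N_ITEMS))
        idx = rng.integers(len(self.gain_sets), size=n)
        return np.asarray(self.gain_sets)[idx]


def _pairs(vals: Sequence[float], k: int = 2) -> np.ndarray:
    grids = np.meshgrid(*([np.asarray(vals)] * k), indexing="ij")
    return np.stack([g.ravel() for g in grids], axis=1)


#: high-gain set used in the cue-combination generalization experiment
CC_HIGH_GAINS = (5.0, 10.0, 15.0, 20.0, 25.0)
BC_GAINS = (0.148, 0.36, 0.724, 1.128, 1.428, 1.6)
BC_RESTRICTED_GAIN = 1.68


def gain_conditions(task: str, regime: str) -> GainRegime:
    """The gain sets of the training/testing conditions, per task.

    ``all_g`` is the full test range; ``restricted_g`` the impoverished
    training range; ``high_g``/``high_g_restricted`` the high-gain sets of
    the cue-combination generalization experiment.
    """
    if task in ("cc", "ct"):
        if regime == "all_g":
            return GainRegime(task, regime, _pairs((0.25, 0.5, 0.75, 1.0, 1.25)))
        if regime == "restricted_g":
            return GainRegime(task, regime, np.array([[0.25, 0.25], [1.25, 1.25]]))
        if regime == "high_g":
            return GainRegime(task, regime, _pairs(CC_HIGH_GAINS))
        if regime == "high_g_restricted":
            return GainRegime(task, regime, np.array([[5.0, 5.0], [25.0, 25.0]]))
    if task == "cc3":
        if regime == "all_g":
            return GainRegime(task, regime, _pairs((0.25, 0.5, 0.75, 1.0, 1.25), 3))
        if regime == "restricted_g":
            return GainRegime(task, regime,
                              np.array([[0.25] * 3, [1.25] * 3]))
    if task == "kf":
        if regime == "all_g":
            return GainRegime(task, regime, lo=0.3, hi=3.0)
        if regime == "restricted_g":
            return GainRegime(task, regime, per_step_choices=(0.3, 3.0))
    if task == "bc":
        if regime == "all_g":
            return GainRegime(task, regime, np.array(BC_GAINS)[:, None])
        if regime == "restricted_g":
            return GainRegime(task, regime, np.array([[BC_RESTRICTED_GAIN]]))
    if task == "ci":
        if regime == "all_g":
            return GainRegime(task, regime, _pairs((0.5, 1.0, 1.5, 2.0, 2.5)))
        if regime == "restricted_g":
            return GainRegime(task, regime, np.array([[0.5, 0.5], [2.5, 2.5]]))
    if task == "sd":
        if regime == "all_g":
            return GainRegime(task, regime, lo=2.0, hi=9.0)
        if regime == "restricted_g":
            return GainRegime(task, regime,
                              np.array([[2.0] * 4, [9.0] * 4]))
    if task == "vs":
        if regime == "all_g":
            return GainRegime(task, regime, per_step_choices=(0.5, 3.0))
        if regime == "restricted_g":
            return GainRegime(task, regime,
                              np.array([[0.5] * 4, [3.0] * 4]))
    raise ValueError(f"unknown task/regime combination ({task!r}, {regime!r})")


# ---------------------------------------------------------------------------
# stimulus demixing mixing model


@dataclass
class MixingModel:
    """Linear odor-mixing model: o_i = sum_k w_ik c_k s_k.

    Four sources mix into four odorants; each odorant is encoded by a
    linear-tuning Poisson population with random positive tuning vector
    ``f`` and baseline ``b``.  Source presence is an independent Bernoulli
    per source; concentrations c_k are uniform on [2, 9].
    """

    n_sources: int = 4
    n_odorants: int = 4
    n_per_odorant: int = 10
    weights: np.ndarray = None  # (n_odorants, n_sources), nonneg
    f: np.ndarray = None        # (n_odorants, n_per_odorant), positive
    b: np.ndarray = None        # (n_odorants, n_per_odorant), positive
    source_prior: float = 0.5
    conc_lo: float = 2.0
    conc_hi: float = 9.0

    @classmethod
    def create(cls, seed: int, **kw) -> "MixingModel":
        m = cls(**kw)
        rng = np.random.default_rng(seed)
        m.weights = rng.uniform(0.0, 1.0, size=(m.n_odorants, m.n_sources))
        m.f = rng.uniform(0.1, 1.0, size=(m.n_odorants, m.n_per_odorant))
        m.b = rng.uniform(0.1, 1.0, size=(m.n_odorants, m.n_per_odorant))
        return m

    def rates(self, presence: np.ndarray, conc: np.ndarray) -> np.ndarray:
        """Mean rates for all odorant populations, shape (n, n_odorants*n_per)."""
        o = (presence * conc) @ self.weights.T  # (n, n_odorants)
        lam = o[:, :, None] * self.f[None] + self.b[None]
        return lam.reshape(len(presence), -1)


# ---------------------------------------------------------------------------
# trial batches


@dataclass
class TrialBatch:
    """One batch of supervised trials for a task.

    ``inputs`` holds the concatenated Poisson count vectors, shape (n, d)
    for feedforward tasks and (n, T, d) for the Kalman task.  ``pops``
    gives the per-population column slices.  ``target`` is the supervised
    signal: stimulus value(s) for continuous tasks, 0/1 labels for
    categorical tasks (a 4-vector per trial for stimulus demixing).
    """

    task: str
    stimuli: np.ndarray
    gains: np.ndarray
    inputs: np.ndarray
    target: np.ndarray
    seed: int
    pops: list = field(default_factory=list)
    specs: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.inputs)

    def split(self):
        """Per-population count arrays."""
        return [self.inputs[..., sl] for sl in self.pops]


CONFLICT_OFFSETS = (-2.0, -1.5, -1.0, -0.5, 0.5, 1.0, 1.5, 2.0)  # in units of l
CONFLICT_L = 4.0


def generate_trials(task: str, regime, n: int, seed: int,
                    conflict: Optional[float] = None,
                    strict_conflict: bool = False,
                    tuning_overrides: Optional[dict] = None,
                    pop_size: Optional[int] = None,
                    mixing: Optional[MixingModel] = None) -> TrialBatch:
    """Generate ``n`` supervised trials for ``task`` under a gain regime.

    ``regime`` is a :class:`GainRegime` or a regime name.  ``conflict``
    (cue combination only) offsets the second cue by a fixed amount Delta:
    s1 is drawn uniformly from an interval of length ``CONFLICT_L`` and
    s2 = s1 + Delta.  Identical seeds give bit-identical batches.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if isinstance(regime, str):
        regime = gain_conditions(task, regime)
    if conflict is not None and task != "cc":
        raise ValueError("cue conflict only applies to cue combination")
    if conflict is not None and strict_conflict:
        allowed = np.array(CONFLICT_OFFSETS) * CONFLICT_L
        if not np.any(np.isclose(conflict, allowed)):
            raise ValueError("conflict offset outside the standard set")
    rng = np.random.default_rng(seed)
    variant = None
    if task in ENCODING_VARIANTS:
        variant, task_eff = task, "cc"
    else:
        task_eff = task

    if task_eff in ("cc", "cc3", "ct"):
        k = _N_POPS[task_eff]
        spec = make_tuning(variant or task_eff, tuning_overrides, n=pop_size)
        gains = regime.sample(n, rng)
        if task_eff == "ct":
            stim = rng.uniform(-STIM_RANGE, STIM_RANGE, size=(n, 2))
            target = stim.sum(axis=1)
        elif conflict is not None:
            s1 = rng.uniform(-CONFLICT_L / 2, CONFLICT_L / 2, size=n)
            stim = np.stack([s1, s1 + conflict], axis=1)
            target = stim.mean(axis=1)
        else:
            s = rng.uniform(-STIM_RANGE, STIM_RANGE, size=n)
            stim = np.tile(s[:, None], (1, k))
            target = s
        counts = [rng.poisson(mean_rates(spec, stim[:, i], gains[:, i]))
                  for i in range(k)]
        inputs = np.concatenate(counts, axis=1)
        m = spec.n
        pops = [slice(i * m, (i + 1) * m) for i in range(k)]
        return TrialBatch(task, stim, gains, inputs, target, seed, pops,
                          [spec] * k, {"conflict": conflict})

    if task_eff == "kf":
        spec = make_tuning("kf", tuning_overrides, n=pop_size)
        gains = regime.sample(n, rng)  # (n, T)
        T = gains.shape[1]
        s = np.empty((n, T))
        s[:, 0] = rng.uniform(-STIM_RANGE, STIM_RANGE, size=n)
        for t in range(1, T):
            s[:, t] = (1 - KF_GAMMA) * s[:, t - 1] \
                + rng.normal(0.0, np.sqrt(KF_SIGMA_ETA2), size=n)
        lam = gains[:, :, None] * (
            spec.baseline + spec.amplitude
            * np.exp(-0.5 * ((s[:, :, None] - spec.preferred[None, None, :])
                             / spec.width) ** 2))
        inputs = rng.poisson(lam)
        return TrialBatch(task, s, gains, inputs, s, seed,
                          [slice(0, spec.n)], [spec], {})

    if task_eff == "bc":
        spec = make_tuning("bc", tuning_overrides, n=pop_size)
        gains = regime.sample(n, rng)[:, 0]
        label = rng.integers(2, size=n)  # 0 -> class 1 (narrow), 1 -> class 2
        sd = np.where(label == 0, BC_SIGMA1, BC_SIGMA2)
        s = rng.normal(0.0, sd)
        inputs = rng.poisson(mean_rates(spec, s, gains))
        target = (label == 0).astype(float)  # P(C = 1)
        return TrialBatch(task, s, gains, inputs, target, seed,
                          [slice(0, spec.n)], [spec],
                          {"sigma1": BC_SIGMA1, "sigma2": BC_SIGMA2})

    if task_eff == "ci":
        spec = make_tuning("ci", tuning_overrides, n=pop_size)
        gains = regime.sample(n, rng)
        common = rng.integers(2, size=n) == 0
        s1 = rng.normal(0.0, CI_SIGMA_S, size=n)
        s2 = np.where(common, s1, rng.normal(0.0, CI_SIGMA_S, size=n))
        stim = np.stack([s1, s2], axis=1)
        r1 = rng.poisson(mean_rates(spec, s1, gains[:, 0]))
        r2 = rng.poisson(mean_rates(spec, s2, gains[:, 1]))
        inputs = np.concatenate([r1, r2], axis=1)
        m = spec.n
        return TrialBatch(task, stim, gains, inputs, common.astype(float),
                          seed, [slice(0, m), slice(m, 2 * m)], [spec] * 2,
                          {"sigma_s": CI_SIGMA_S})

    if task_eff == "sd":
        if mixing is None:
            mixing = MixingModel.create(seed=seed + 1)
        presence = (rng.random(size=(n, mixing.n_sources))
                    < mixing.source_prior).astype(float)
        conc = regime.sample(n, rng)
        inputs = rng.poisson(mixing.rates(presence, conc))
        m = mixing.n_per_odorant
        pops = [slice(i * m, (i + 1) * m) for i in range(mixing.n_odorants)]
        return TrialBatch(task, presence, conc, inputs, presence, seed, pops,
                          [], {"mixing": mixing})

    if task_eff == "vs":
        spec = make_tuning("vs", tuning_overrides, n=pop_size)
        gains = regime.sample(n, rng)
        present = rng.integers(2, size=n) == 1
        stim = rng.uniform(0.0, np.pi, size=(n, VS_N_ITEMS))
        loc = rng.integers(VS_N_ITEMS, size=n)
        stim[present, loc[present]] = VS_TARGET
        counts = [rng.poisson(mean_rates(spec, stim[:, i], gains[:, i]))
                  for i in range(VS_N_ITEMS)]
        inputs = np.concatenate(counts, axis=1)
        m = spec.n
        pops = [slice(i * m, (i + 1) * m) for i in range(VS_N_ITEMS)]
        return TrialBatch(task, stim, gains, inputs, present.astype(float),
                          seed, pops, [spec] * VS_N_ITEMS,
                          {"target": VS_TARGET})

    raise ValueError(f"unknown task {task!r}")


# ---------------------------------------------------------------------------
# synthetic psychophysical subject (binary categorization)


def simulate_subject(stimuli: np.ndarray, sigma: np.ndarray, boundary,
                     lapse: float, seed: int) -> np.ndarray:
    """Binary choices of a synthetic observer on categorization trials.

    The observer takes a noisy internal measurement ``x = s + sigma*eps``,
    reports class 1 when ``|x|`` falls below the decision boundary
    ``k(sigma)``, and lapses into a coin flip: with lapse rate ``lam`` the
    choice is ``lam + (1 - 2 lam) * rule`` so that ``lam = 0.5`` is pure
    guessing.  ``boundary`` is anything with a ``threshold(sigma)`` method
    (a :class:`genppc.heuristics.BoundaryModel`) or a callable.
    """
    if not 0.0 <= lapse <= 0.5:
        raise ValueError("lapse must lie in [0, 0.5]")
    rng = np.random.default_rng(seed)
    stimuli = np.asarray(stimuli, float)
    sigma = np.broadcast_to(np.asarray(sigma, float), stimuli.shape)
    x = stimuli + sigma * rng.standard_normal(stimuli.shape)
    thr = boundary.threshold(sigma) if hasattr(boundary, "threshold") else boundary(sigma)
    rule = (np.abs(x) < thr).astype(float)
    p1 = lapse + (1.0 - 2.0 * lapse) * rule
    return (rng.random(stimuli.shape) < p1).astype(float)


def bc_sigma_from_gain(spec: TuningSpec, g) -> np.ndarray:
    """Effective sensory noise implied by a gain in the categorization task.

    The Poisson population with Gaussian tuning carries Gaussian likelihood
    information with variance sigma_f^2 / (expected total count); this maps
    each gain to the sigma of the equivalent internal-measurement model.
    """
    grid = np.linspace(-3 * BC_SIGMA1, 3 * BC_SIGMA1, 31)
    total = mean_rates(spec, grid, 1.0).sum(axis=1).mean()
    return spec.width / np.sqrt(np.asarray(g, float) * total)
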