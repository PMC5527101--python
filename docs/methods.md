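# Methods

## The problem

Psychophysical tasks such as cue combination, coordinate transformation,
evidence tracking, categorization under variable sensory noise, causal
inference, odor-source demixing and visual search all require inference
from noisy population activity whose reliability changes from trial to
trial.  The Bayes-optimal observer for each task uses the trial's actual
reliability; the question this package addresses is whether *generic*
rectified-linear networks, trained only with error feedback (the true
stimulus value or class label), come to perform this probabilistic
inference — and, if so, how the trained networks represent uncertainty.

## Generative models of the tasks

Every task presents stimuli through populations of independent Poisson
neurons, `r ~ Poisson(g · f(s))`, where the gain `g` varies per trial (or
per time step) and controls reliability.  Tuning curves `f` are Gaussian
bumps for the continuous and categorization tasks, von Mises (with angle
doubling, period pi) for visual search, and linear in odorant
concentration for demixing.  Defaults:

| parameter | value | note |
|---|---|---|
| neurons per population | 50 (20 visual search, 10 per odorant) | |
| preferred stimuli | even tiling of [−12, 12] a.u. | [−30, 30] for causal inference, [−40, 40] for categorization |
| tuning width σ_f | 2 a.u. | 10 for categorization (see below) |
| stimulus prior | uniform [−10, 10] a.u. | Gaussian N(0, 10²) for causal inference, class-conditional N(0, 3²)/N(0, 12²) for categorization |
| tracking dynamics | s_t = 0.9 s_{t−1} + N(0, 1), 25 steps | stationary SD ≈ 2.29 |
| gain sets | per task, all-gain vs restricted-gain | e.g. 25 pairs from {0.25,…,1.25} for cue combination |

The categorization tuning width is set so that the six published gain
values map onto sensory noise σ(g) = σ_f/√(g · Σf) between ≈2 (full
contrast) and ≈7, the regime in which the narrow/wide classes genuinely
overlap and boundary-shaped decision models are distinguishable.

What the generator does *not* emulate: overdispersed (non-Poisson)
variability, correlated noise, temporal spiking structure within a count
window, and naturalistic stimulus statistics.  Passing tests therefore
show that the learning phenomena hold for idealized Poisson population
codes, not that they survive realistic response correlations.

## Ideal observers

Closed forms are implemented as published: the spike-weighted preferred
stimulus for cue combination under a flat prior; the natural-parameter
recursion for tracking; the log-likelihood ratios for categorization,
causal inference, and visual search (whose per-item integral over
distractor orientation is a 720-point composite rule on [0, pi); gain
cancels from that ratio exactly).  These forms are exact only in the
dense-tiling regime where the population-summed rate is stimulus-
independent; the package therefore also computes posteriors numerically
on stimulus grids (resolution ≤ σ_f/4), marginalizing the unknown gain
over the regime's gain set (16-point grid for continuous gain ranges),
and uses the numeric posterior as the reference "optimal" estimator
everywhere performance is scored.  Demixing posteriors enumerate all 2⁴
source configurations and integrate concentrations by fixed-seed Monte
Carlo (10⁴ draws by default; a product grid is available for tests).
Degenerate zero-count trials fall back to the prior.

## Networks and training

Feedforward `r_hid = [W_in r_in + b]_+` with a linear (continuous) or
sigmoidal (categorical) readout; recurrent variants add `W_rec r_hid,t`;
the excitatory–inhibitory variant constrains each presynaptic column's
sign (4:1 E:I) by projection after every update, receives the input
spread over 10 steps at gain g/10 (equating total input information), and
is read out at the final step.  Its recurrent matrix is spectrally
normalized to radius 0.8 at initialization — Dale-signed magnitudes
otherwise have a large positive leading eigenvalue and 10-step ReLU
dynamics diverge.  Gradients are exact (backpropagation / BPTT) and
checked against central differences for every architecture × loss.

Training uses Adam (step 10⁻³ unless stated) on freshly generated
mini-batches: 10 trials for categorization, 500 for visual search, 100
otherwise; 200 hidden units in the main experiments.  Weights start at
SD √(2/(fan_in+fan_out)), biases at SD 0.1 — the only scale the source
material prints (for the random-feature control), reused for trainable
networks.  The online variant updates after every trial with rate
η₀/(1+γt) and records pre-update choices.

## Non-probabilistic reference models

Continuous tasks: decode each cue optimally (gain-marginalized posterior
mean per population), then average with equal weights; the tracking
variant averages prediction and momentary estimate.  Categorical tasks:
the optimal rule with each input's count-dependent reliability replaced
by one common reliability, chosen on a gain grid to minimize information
loss.  The boundary-model family (FIX/LIN/QUAD/OPT/OPT-P, each plus a
lapse rate with P(choice) = λ + (1−2λ)·rule) is fitted to binary choices
by multi-start L-BFGS-B maximum likelihood; nested families are
additionally seeded with the simpler family's solution so log-likelihood
nesting holds; AIC = 2k − 2 log L.

## Metrics

Fractional RMSE: `100 (RMSE_net − RMSE_opt)/RMSE_opt` on shared trials.
Fractional information loss: mean KL from the true posterior to the
decoder output, normalized by the shared-sample mutual-information
estimate `E[KL(p(C|r) ‖ p(C))]`; the prior decoder scores exactly 100%
by construction, per-source losses are summed for demixing, and decoder
outputs are clipped at 10⁻¹².  Sparsity is the non-excess kurtosis
m₄/m₂² of hidden activity across units within a trial (only the ordering
matters for the correlations; trials with constant hidden activity are
dropped and counted); it and the mean hidden rate are correlated with
the mean input rate across an evaluation set spanning all gain
conditions.  Parameter statistics are reported in units of the
input-weight SD, matching the mean-field parameterization.

## Mean-field model

The net input to a typical hidden unit is modeled as
N(gμ + μ_b, g² + σ_b²) (input SD = 1 fixes the units), giving the
rectified-Gaussian mean response μ̄(g) and the sensitivity functional
T_var = ∫|μ̄′(g)|dg with an analytic derivative under adaptive
quadrature.  The constraint (gain-averaged μ̄ = K) is enforced by solving
for μ_b by 1-D root finding (μ̄ is strictly increasing in μ_b), leaving
an unconstrained search over (μ, σ_b): a coarse grid plus Nelder–Mead.
The gain range is (1, 10): a decade, so both extremes engage the
rectifier.  This matters — over a narrow range such as (0.25, 1.25) the
formal optimum is a degenerate unit whose input never crosses threshold
(μ → 0⁻, arbitrary small T_var), which says nothing about rectification.
At K = 2 the optimum is μ ≈ −0.64, μ_b ≈ 1.0, σ_b at the top of the
searched box ([0.1, 5]): firing probability falls with gain while the
suprathreshold mean rises, leaving μ̄ within ±10% — the mechanism behind
the sparsity code.

## Experiment recipes and problem sizes

All headline computations are packaged as seeded recipes
(`genppc.experiments`); the sizes below are the package's defaults,
chosen for single-CPU runs.

- **Few-shot gain generalization** (cue combination): 50 training
  examples — fixed (stimulus, gain-pair) conditions at (5,5)/(25,25),
  Poisson responses redrawn every presentation, stimuli on the
  cue-conflict interval of length l = 4 — trained with an Adam schedule
  (10⁻³ ×5k, 10⁻⁴ ×4k, 10⁻⁵ ×2k epochs), input-weight init scaled by
  1/25 (the largest training gain) and bias SD 1.0; tested on 6000
  trials over all 25 pairs from {5,…,25} against the gain-marginalized
  numeric posterior mean.  The frozen-trials reading of "50 examples" is
  not implementable: reaching ~11% excess RMSE needs the regression
  function to ~0.01 a.u., below the estimation floor of 50 noisy
  samples.  Seed-to-seed spread of this experiment is large (per-seed
  values roughly 8–30%); the median over 16 seeds is reported together
  with the spread.
- **Sparsity experiments**: coordinate transformation and causal
  inference networks (200 hidden units, all-gain regimes, 40k/20k
  batches), evaluated on 4000–5000 trials spanning all gain pairs.
  Trained CT networks reach ~2–3% fractional RMSE with sparsity–input
  correlation ≈ 0.75–0.81 and a weak *negative* mean-rate correlation
  (−0.1 to −0.3 depending on budget — a mild overshoot of gain
  invariance; the sparsity-vs-mean ordering, not the sign, is the
  robust feature); causal-inference networks show the reversed pattern
  (mean-rate correlation ≈ 0.75, sparsity ≈ 0.1).
- **Controls**: frozen-random-hidden-layer networks on cue combination
  (readout trained 15k batches) lose well over 100%; the EI recurrent
  network's gap to feedforward is reported with no hard bar.
- **Efficiency scan**: coordinate transformation at d ∈ {20, 60, 180}
  total inputs, hidden sizes doubling from 2 to 64, 3 seeds, threshold
  10% fractional RMSE, median rule; the log–log slope of n*(d) is the
  result.
- **Learning dynamics**: categorization streams with per-trial σ implied
  by the gain; online network subjects; boundary families fitted per
  trial window and tallied by AIC winner.  A synthetic boundary subject
  (any family + lapse) replaces external behavioral data; an optional
  loader accepts a documented CSV layout.

## Numerical choices and degenerate inputs

Log-likelihoods are computed with clipped log rates (10⁻³⁰⁰ floor) and
log-sum-exp reductions; logistic transforms are evaluated in the stable
branch per sign.  Zero-count trials: flagged by the linear estimate,
prior fallback in grid posteriors, zero observation precision in the
tracking recursion.  Ties in the n* scan resolve to the smallest n.
Identical seeds give bit-identical trial batches, training histories and
recipe outputs.

## Known limitations

The few-shot generalization error depends on inductive bias and run-to-
run variability far more than any other quantity here; its seed spread
is reported rather than hidden.  The early-training window of the
learning-dynamics experiment is best fit by FIX/OPT-P boundary subjects
at our scales, not QUAD.  The excitatory–inhibitory control is trained
at a reduced budget and its gap to feedforward (tens of percent) would
shrink with longer training.  Closed-form/oracle agreement is asserted
in the dense-tiling regime where those forms are derived; with the
production tiling the numeric posterior is the authority.
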