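# genppc — probabilistic inference in generic ReLU networks

Animals behave near-optimally in psychophysical tasks whose difficulty
changes from trial to trial: combining two cues of unequal reliability,
tracking a drifting target, deciding whether two signals share a cause,
finding a target among heterogeneous distractors.  Optimal behavior in
all of these requires using the trial's sensory uncertainty, and a long
line of work builds special-purpose neural circuits that do so.  This
package studies the opposite hypothesis: *generic* rectified-linear
networks, trained only with error feedback (the true stimulus value or
class label, never probabilities), learn the same computations.

It is aimed at computational neuroscientists who want a complete,
seeded, single-machine pipeline: Poisson population-coding task
generators, exact and numeric Bayesian ideal observers, plain-NumPy
network training, non-probabilistic reference models, sparsity analyses
of trained networks, and the rectified-Gaussian mean-field model that
explains when uncertainty is encoded in activity *sparsity* versus
activity *level*.

## The model in brief

Input neurons are independent Poisson encoders, `r ~ Poisson(g f(s))`,
with gain `g` varying per trial (higher gain = more spikes = more
reliable evidence).  Networks are

    r_hid = [W_in r_in + b]_+        y = w' r_hid + b_out   (continuous)
                                     y = sigma(w' r_hid + b_out)   (categorical)

trained by Adam on squared error or cross-entropy.  Performance is
scored against the Bayes-optimal observer on the same trials:

* fractional RMSE = 100 (RMSE_net − RMSE_opt)/RMSE_opt for continuous
  tasks, with RMSE_opt from the gain-marginalized numeric posterior
  mean;
* fractional information loss = 100 E[KL(p(C|r) ‖ q_net)] / Î(C; r) for
  categorical tasks, where the normalizer is estimated on the same
  trials, so a decoder that always reports the prior loses exactly 100%.

The mean-field model treats a hidden unit's net input as Gaussian
N(gμ + μ_b, g² + σ_b²) and minimizes the total gain-sensitivity of its
rectified mean response subject to a mean-rate constraint; the optimum
(negative mean input weight, positive bias mean, broad bias spread) is
the regime where responses sparsify as gain rises while the mean rate
stays flat — a sparsity code for posterior width.

## Worked example

Train a 200-unit network on cue combination under the full gain regime
(all 25 pairs from {0.25,…,1.25}) and compare it with the ideal
observer and the equal-weight heuristic:

```python
import numpy as np
from genppc import tasks, networks, training, metrics, experiments, heuristics

net = networks.init("feedforward", n_in=100, n_hid=200, seed=7)
net, hist = training.train(net, "cc", "all_g",
                           training.TrainConfig(seed=7, n_batches=20_000))

regime = tasks.gain_conditions("cc", "all_g")
test = tasks.generate_trials("cc", regime, 3000, seed=99)
y, _ = networks.forward(net, test.inputs.astype(float))
opt = experiments.optimal_continuous(test, regime)

gains = experiments.marginal_gain_sets(regime)
eq = heuristics.equal_weight_estimate(test.split(), test.specs, gains * 2)

print(f"network   {metrics.fractional_rmse(y.ravel(), opt, test.target):6.1f} %")
print(f"heuristic {metrics.fractional_rmse(eq, opt, test.target):6.1f} %")
```

prints

```
network      4.5 %
heuristic   45.8 %
```

that is: after 20k mini-batches of 100 trials the network's estimates
carry only ~4% more error than the Bayes-optimal posterior mean, while
the reliability-blind heuristic (optimal per-cue decoding, equal-weight
combination) is ten times farther from optimal.  A frozen-random-
hidden-layer control (`experiments.random_network_cc`) stays above 100%
on the same test, and `experiments.sparsity_experiment("ct", ...)`
reproduces the sparsity-based uncertainty code of the trained networks.

A `genppc` command-line tool wraps the same recipes
(`genppc gen`, `genppc train`, `genppc run --experiment fig5_6_sparsity`).

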