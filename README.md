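# grazetrack

Behavioral-state classification of grazing livestock from high-frequency
GPS tracks alone.

Free-ranging cattle spend their time walking, grazing and resting, and
the mix of these behaviors is what links herds to pasture ecosystems.
Visual observation is expensive; GPS collars are cheap.  `grazetrack`
infers the per-position behavioral state from fixed-interval GPS
positions (nominally one fix every 20 s), for movement ecologists who
want behavioral budgets and state-labeled tracks without accelerometers
or continuous observation.

## What it does

**Multi-scale movement metrics.**  From a planar track the package
derives the two basic metrics — step distance and turning angle — and
extends them over multiple time steps: cumulative (path) and linear
(straight-line) distances, backward and forward of each position at
every multiple of the fix interval Δ up to a 5-minute horizon, their
backward/forward means, and centered means of the absolute turning angle
over 3, 5, 7, … positions.  At Δ = 20 s this yields 87 distance and 15
turning-angle predictors per position; rebuilt at 60 s, 27 and 5.

**Imbalance-aware classifiers.**  Behavioral states are heavily
unbalanced (roughly 5% walking, 70% grazing, 25% resting), so the
model grid pairs classifiers with training-data balancing: random
forests without balancing, with per-tree random undersampling (each tree
trained on a fresh draw of every class down to the smallest class size),
or with SMOTE; a linear discriminant analysis and an RBF-kernel SVM on
SMOTE-balanced data; and a frequency-matched null model.  Per-state
permutation variable importance is averaged over forest realizations.

**A switching random-walk state-space model.**  Movement is modeled as a
hidden 3-state Markov chain where state *s* emits a step length
*d* ~ Weibull(k_s, λ_s) and a turning angle θ ~ wrapped Cauchy(μ_s, ρ_s),
with fixed switching probabilities Q between states.  The model is
fitted by MCMC (forward-filtering backward-sampling for the latent
states, conjugate Dirichlet updates for Q, random-walk Metropolis for
the emission parameters; 3 chains × 700 iterations with 200 burn-in),
convergence is checked with Gelman–Rubin R̂, and each position is
decoded as its most frequent state across posterior draws.

**Evaluation.**  Leave-one-sequence-out validation: each observed
sequence is predicted from models fitted to the remaining sequences;
accuracy is reported per sequence and jointly, with per-state
accuracies, row-normalized confusion matrices, behavioral budgets and
paired t-tests between models.

**Synthetic data.**  A simulator — the exact generative twin of the
state-space model, plus isotropic GPS noise calibrated to a stationary
device test (95th-percentile relative error ≈ 2.45 m) — makes every
stage testable without field data.

## Worked example

```sh
python examples/classify_with_imbalance.py
```

```
model B (unbalanced forest): joint 84.1%  per-state {'walking': 100.0, 'grazing': 94.7, 'resting': 36.2}
model C (RUS forest): joint 77.9%  per-state {'walking': 100.0, 'grazing': 78.7, 'resting': 67.8}
```

Six bouts are simulated with the default cow kinematics (mean speeds
0.41 / 0.06 / 0.04 m/s for walking / grazing / resting, 5/70/25% state
frequencies, 1 m GPS noise); two are held out.  The unbalanced forest
(model B) maximizes joint accuracy by over-predicting the majority state
— grazing is classified at 94.7% but resting collapses to 36.2%.
Undersampling inside the forest (model C) trades a few points of joint
accuracy (84.1% → 77.9%) for far more even state-specific accuracies
(resting 36.2% → 67.8%), which is what matters when the behavioral
budget, not the majority state, is the quantity of interest.

Other examples: `build_metric_catalog.py` (the 87+15 / 27+5 predictor
catalogs), `simulate_cow_track.py` (per-state kinematic summaries),
`fit_state_space_model.py` (MCMC fit, R̂ diagnostics and modal-state
decoding), `device_noise_calibration.py` (absolute vs relative GPS error
percentiles).

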