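# Methods

## The model

`priorpop` simulates how a population of rate neurons can learn to represent
and use prior knowledge about its sensory environment from trial-by-trial
error feedback alone, without ever being told a probability.

**Encoder.** A one-dimensional stimulus `s` (think of an orientation) is
encoded by `N = 50` independent Poisson neurons with Gaussian tuning curves

    lambda_i(s) = c * exp(-(s - phi_i)^2 / (2 sigma^2)),

with peaks `phi_i` evenly spaced on `[-20, 20]` (both endpoints included),
tuning width `sigma^2 = 10` (stimulus units squared), and a global contrast
`c >= 0` that scales every rate and therefore controls the reliability of the
input: more contrast, more spikes, lower decoding variance. Spike counts are
`r_i ~ Poisson(lambda_i(s))`.

**Tasks.** Two generative regimes define the prior to be learned:

* *Classification*: the stimulus comes from class 1 or class 2, Gaussian with
  means -5 / +5 and shared variance 25. The class prior
  `pi = P(C=1) ∈ {0.25, 0.33, 0.5, 0.67, 0.75}` is realised purely as the
  relative frequency of the two classes during training. Contrasts
  `{0.5, 1.2, 1.9, 2.6, 3.3, 4.0}`, drawn uniformly per trial (the sampling
  rule is a package choice; nothing suggested blocking). In the cued variant,
  a per-trial cue (two cues, equiprobable) selects `pi = 0.25` or `0.75`.
* *Estimation*: the stimulus comes from a zero-mean Gaussian prior with
  variance `sigma_s^2 ∈ {100, 50, 25, 10, 5}`; contrasts
  `{0.30, 0.72, 1.45, 2.26, 2.86, 3.2}`.

**Network.** A dense layer maps the 50 spike counts to `K = 200` rectified
linear units, `h_k = max(0, (W^T r)_k + b_k)`; a linear readout `U` produces
either two softmax class probabilities or a single unbounded stimulus
estimate. There is no readout bias (the trainable set is exactly `W, b, U`
plus, in cue experiments, the cue parameters). In cued networks each hidden
unit carries a cue-indexed gain modulation and bias,

    h_k = max(0, (1 + g_cue,k) * ((W^T r)_k + b_k + b_cue,k)),

so the cue perturbs the gain (around a structural baseline multiplier of 1)
and the threshold of a computation that is otherwise shared across cue
contexts. We parameterise the gain as a modulation rather than a free
per-cue multiplier deliberately: with a free multiplier initialised near
zero, the product `g * (...)` *is* the hidden activity, the two cue contexts
effectively learn separate input pathways through `g`, and the cue's prior
is stored in the gain-row pattern — the shared-computation structure the cue
architecture is meant to probe never forms. With the modulation form the
cued network reduces exactly to the plain network at the neutral values
`g_cue = b_cue = 0`.

**Training.** Adam (beta1=0.9, beta2=0.999, eps=1e-8), learning rate 2e-4,
minibatches of 10 trials, 1000 iterations per epoch, all parameters
initialised from `U(-sqrt(1/N_in), +sqrt(1/N_in))` with `N_in` the layer
fan-in (50 for `W`, `b` and the cue vectors, 200 for `U`). The loss is
binary cross-entropy on the softmax pair (probabilities floored at 1e-12
inside the log; a pure numerical guard, inactive at trained accuracy) or
squared error for estimation. Gradients are hand-derived for this
one-hidden-layer architecture and verified against central finite
differences in the test suite.

*Budgets.* The reference budget is 100 epochs. Classification networks are
trained at a 20-epoch desk-scale protocol throughout the tests and the
reproduction scripts: every classification-side effect (calibration,
accuracy orderings, sparsity, the threshold mechanism, the cue mechanism) is
fully developed there. Estimation networks always use the full 100-epoch
budget: the tuning-geometry and sparsity effects of the continuous prior are
asymptotic properties of the representation and are not yet formed at 20
epochs (at that point the sparsity ordering across priors is still
inverted). A full estimation run takes ~25 s on one CPU in this
implementation, so the full budget is also the cheaper choice scientifically.

**Learning-signal statistic.** To quantify how strongly a trial of a given
class still drives plasticity late in training, we log the hypothetical Adam
step for that single trial's input-weight gradient, given the optimizer's
current moment estimates: `mean |Delta W|` per trial, with class metadata,
over the final 10 epochs (every 10th iteration). This attributes an update
magnitude to an individual trial without altering the actual minibatch
training. Likely-class trials produce smaller updates than unlikely-class
trials.

## Ideal observers

For dense, uniform tuning the summed rate `sum_i lambda_i(s)` is nearly
constant in `s`, and the Poisson population likelihood is Gaussian in the
stimulus with

    mu_r = phi^T r / (1^T r),    sigma_r^2 = sigma^2 / (1^T r).

Classification combines this with the Gaussian class densities into the
posterior log-odds

    d = [2 mu_r (mu_1 - mu_2) + mu_2^2 - mu_1^2] / [2 (sigma_r^2 + sigma_C^2)]
        + log(N_1 / N_2),        P(C=1|r) = 1 / (1 + e^{-d}),

with `N_1/N_2` taken as the expected class frequencies `pi/(1-pi)` (training
realises the prior as frequencies, so expected and realised counts agree to
Monte-Carlo error). Estimation uses the Gaussian-prior MAP estimate

    s_MAP = (mu_r sigma_s^2 + mu_s sigma_r^2) / (sigma_r^2 + sigma_s^2).

Rather than trusting the intermediate algebra, both closed forms are
validated against brute-force grid computations (`priorpop.gridref`) that
integrate `exp(sum_i r_i log lambda_i(s))` against the prior on a fine
stimulus grid; the test suite requires agreement to 1e-3 in posterior
probability and one grid step (0.01 stimulus units) in the MAP estimate.
Zero-spike trials are treated as likelihood-free: the posterior equals the
prior and the MAP estimate equals the prior mean (the `sigma_r^2 -> inf`
limit, which is exact). Because the constant-summed-rate approximation fails
near the edges of the tiled range, all evaluation sweeps stay within
`[-10, 10]`.

## Held-out evaluation

Held-out sets are freshly sampled with dedicated seeds: 1000 trials per
(prior, contrast) cell for classification; for estimation, trials drawn from
the training prior truncated to the tested range `[-10, 10]`. Grid sweeps
(tuning curves, bias curves) present each grid stimulus repeatedly at a
fixed contrast.

A caveat that matters for interpreting the estimation results: a sharp prior
(`sigma_s^2 = 5`, SD ~2.2) essentially never generates `|s| > 8` during
training, so the network's response there is unconstrained extrapolation. In
our runs (at 20 and at 100 epochs, across seeds) the network *overshoots*
beyond `|s| ~ 5` — its estimates there are biased away from, not toward, the
prior mean, unlike the MAP rule. Within the prior's effective support the
match to the MAP estimate is excellent (per-trial RMSE ~0.2 stimulus units
at top contrast). Directional claims about the perceptual bias are therefore
asserted on grid stimuli within two prior SDs of the prior mean (excluding
the symmetric +-1 neighbourhood of the mean where the bias crosses zero),
and the prior-weighted MAP-match RMSE uses the truncated-prior held-out set.

## Representation analyses

* **Activity statistics:** per evaluation cell, the mean number of hidden
  units with `h > 0` and the mean population activity; optionally binned by
  the ideal posterior (10 equal bins on [0, 1]).
* **Template match:** pooled pre-activation values `W^T r + b` per contrast,
  summarised by their interdecile range; higher contrast separates matches
  from mismatches, so the dispersion grows monotonically with contrast.
* **Subpopulations:** `H1 = {k : U_k(C=1) > U_k(C=2)}` and its complement
  (ties, a measure-zero event, go to H2). Group comparisons of biases, mean
  input weights and mean readout weights use Welch's two-sided
  unequal-variance t test at alpha = 0.01. Exact p-values are not treated as
  quantitative targets, only their position relative to alpha.
* **Cue attribution and ablation:** per-cue means of `g_cue` and `b_cue` per
  subpopulation; ablating a channel replaces each unit's per-cue values with
  that unit's across-cue mean (preserving average drive). The cued accuracy
  asymmetry is the mean over cues of (favoured-class minus unfavoured-class
  accuracy).
* **Tuning curves:** grid step 0.25 over [-20, 20], 200 Poisson draws per
  grid point at the highest contrast, 5-point moving-average smoothing.
  Peak = smoothed argmax; maximal-slope location = interior grid point of
  largest absolute central difference (an argmax-of-second-derivative
  variant is selectable); FWHM requires half-max crossings on both flanks
  (linearly interpolated) and is otherwise flagged invalid; units whose peak
  response never exceeds 1e-3 are excluded as silent. The protocol
  (grid step, repeats, smoothing, floor) is a package choice — stable
  derivative estimates at desk cost.
* **Expected vs unexpected units:** units with a valid maximal-slope
  location within one prior SD of the prior mean vs the rest; the bias
  difference is tested by Welch and by a 10,000-draw label permutation. For
  `sigma_s^2 = 5` only ~20 of 200 units fall in the expected group, which
  leaves the comparison underpowered at desk scale; the moderate prior
  (`sigma_s^2 = 10`) is the powered condition and the one asserted in the
  directional test suite.
* **Peak bimodality:** the sharp prior splits the peak-location density into
  two lobes flanking the prior mean. Tested by a 2-component vs 1-component
  Gaussian-mixture likelihood ratio with a parametric bootstrap (199
  resamples) under the single-Gaussian null, alpha = 0.05.

## What the synthetic generator does and does not emulate

The generator *is* the study's world: class-conditional and Gaussian
stimulus priors, contrast-scaled Poisson spiking on smooth homogeneous
tuning curves. It does not emulate heterogeneous tuning widths, non-Poisson
count dispersion, temporal spike structure, or correlated noise across
neurons. Passing tests therefore demonstrate the learning and representation
phenomena *within this idealised encoding model*, not that biological
populations realise them; the value of the exercise is the mechanistic
prediction (threshold coding of priors, slope-density allocation), which is
what an experiment would test.

## Numerical choices and degenerate inputs

Probability floors (1e-12) keep the cross-entropy finite; a non-finite loss
aborts training with a diagnostic. Zero contrast is legal everywhere and
produces all-zero rates (posterior = prior, MAP = prior mean). Degenerate
subpopulation or expected/unexpected splits (an empty side) are flagged and
excluded from testing instead of raising. Tuning-curve grids shorter than
the smoothing window are configuration errors.

## Known limitations

* Results are reported for one trained network per condition (matching the
  study design); single-network variation is real. Per-class accuracies of a
  trained classifier can sit 1-3 percentage points from the ideal-observer
  curve with a seed-dependent sign, and a π=0.5 network retains a small
  (~2 pp) class asymmetry at the desk-scale budget. Directional conclusions
  are robust; exact margins are not.
* The network's behaviour outside the training prior's support is
  unconstrained (see the extrapolation caveat above).
* Only the rectifier activation path is exercised by the directional tests;
  leaky-rectifier and sigmoid variants are available but not validated
  beyond unit level.
* The learning rule is standard backpropagation; no biologically plausible
  credit-assignment variant is provided.
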