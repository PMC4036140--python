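# Methods

## The signal model

Each CA1 unit is modeled as a threshold-crossing spiking neuron
observed in discrete 2 ms bins. A latent membrane potential
`w(t) = u(t) + a(t) + ε` combines a synaptic potential `u` driven by
the CA3 inputs, a spike-triggered after-potential `a` driven by the
unit's own recent output, and standard-normal noise; a spike occurs
when `w` crosses a threshold. Because only `(k0 − θ)/σ` is identified,
the noise scale is fixed at 1 and the threshold at 0, the zeroth-order
kernel absorbing the threshold; the Gaussian noise then makes the
per-bin spike probability a probit link, `p(t) = Φ(u(t) + a(t))`.

`u` is a second-order Volterra expansion of each input's spike history
(first-order kernels plus second-order *self* kernels; cross kernels
between inputs and third-order terms are out of scope). `a` is a
first-order kernel over output lags 1..M_h. Both memories default to
2 s (1000 bins).

**Laguerre expansion.** Kernels are represented on discrete orthonormal
Laguerre functions generated by the stable ladder recursion (pole
`alpha`, orders 0..J−1). Defaults: J = L = 3 basis functions and
`alpha = 0.98` for both feedforward and feedback bases. The pole was
chosen as the largest value at which the truncated 1000-bin basis is
still numerically orthonormal (Gram deviation ~6e−5; at 0.99 the
truncation error reaches ~0.07 and the basis functions no longer decay
within the memory). Projection between kernel and coefficient space
uses least squares rather than plain inner products, so
expand-then-project round trips are exact to machine precision even
under truncation.

**Estimation.** Coefficients minimize the penalized probit negative
log-likelihood with a group-LASSO penalty: one group per input's
first-order block, one per its second-order block; intercept and
feedback are never penalized, so an input can be removed wholesale
while the unit's own excitability is always modeled. The optimizer is
an outer IRLS (Fisher-scoring) quadratic approximation with an inner
block coordinate descent; penalized blocks take majorized group
soft-threshold steps, unpenalized blocks are solved exactly, and a
step-halving line search guarantees a monotone objective. Tolerance
1e−6 on relative objective change, at most 200 outer iterations.
The MIMO workflow uses the *adaptive* (two-stage) group LASSO by
default (``MIMOConfig.adaptive``): a pilot CV fit sets per-group
penalty weights `w_g ∝ 1/‖ĉ_g‖` (zeroed groups get infinite weight and
stay zero), then the penalty is re-cross-validated and the model
refitted with those weights. The single-stage fit leaves 20–40%
shrinkage bias on weakly excited inputs at the CV penalty, while a
fully unpenalized refit on the selected support lets the
weakly-identified second-order coefficients blow up — for binary
inputs `x² = x`, so the diagonal of the second-order kernel is nearly
collinear with the first-order kernel and the MLE has large variance
along that direction. The adaptive weights sit between the two:
strong first-order groups are barely shrunk, weak second-order groups
stay regularized. Teacher forcing (feedback features from the observed output) is used
for estimation — the standard point-process-GLM practice — and
free-run Monte Carlo simulation for prosthesis-style prediction; both
are exposed.

**Penalty selection.** The grid is 30 log-spaced values descending four
decades from the analytic `lambda_max` (the largest group gradient norm
at the null model, where every penalized group is exactly zero by the
KKT conditions). Two-fold cross-validation over contiguous blocks of
trial segments picks the penalty minimizing held-out per-bin NLL, ties
to the sparser side. A `rule="1se"` option implements the
one-standard-error rule; it exists because the min-rule CV curve is
characteristically flat (differences of ~1e−4 per bin across two
decades of penalty) so the minimizer retains vanishingly small spurious
groups. Prediction-oriented fits use the min rule; the
support-recovery experiment uses the 1-SE rule, which is the standard
selector when the scientific question is *which inputs matter* rather
than raw predictive likelihood.

**Convolution bookkeeping.** Perievent windows are not contiguous in
real time, so all convolutions (feature building, intensity prediction,
simulation) reset their history at every trial-segment boundary. Bins
are half-open `[t0+iΔ, t0+(i+1)Δ)`, multiple spikes per 2 ms bin clip
to 1, and feedback uses lags ≥ 1 only.

## The memory decoder

Spatio-temporal patterns (N neurons × 2000 bins, −2..+2 s around the
sample lever press) are projected per neuron onto clamped B-splines
with uniform interior knots on the bin-index domain [0, 1999]; degree
d = 3 by default, J = m + d + 1 functions. Clamping gives partition of
unity, and the degree-0 recursion base uses half-open intervals with
the last interval closed so unity holds at the knots. The basis is
evaluated with scipy's B-spline design matrix; the Cox–de Boor
recursion (0/0 := 0) is asserted against it in the tests.

L1-penalized logistic regression on the N·J features (bias unpenalized)
is fitted by IRLS plus cyclic coordinate descent with soft-thresholding
and active-set iteration; features are not standardized because all
are inner products of binary trains with same-scale basis functions.
Tolerance 1e−7 on the objective. The penalty grid descends four decades
from the analytic `lambda_max = max_j |Σ_i z_ij (y_i − ȳ)|`; stratified
four-fold CV maximizes held-out accuracy, ties to the sparser side.
J can be selected from a candidate set in [5, 100] by CV accuracy (ties
to smaller J); the workflow default is J = 20, the value that recurs as
optimal for this kind of data. Label convention: left = 1, right = 0;
an exact P = 0.5 boundary maps to label 0.

Reported accuracies are nested cross-validation estimates: an outer
stratified four-fold split scores held-out trials only, with the
penalty re-chosen by an inner four-fold CV inside each training split.
When a second pattern set is evaluated with "the same weights" (the
re-encoding test), each outer fold's decoder is applied unchanged to
the held-out trials of both sets, and the weight digests are compared
before and after to prove no refit occurred.

## Goodness of fit

The time-rescaling KS test integrates the conditional intensity between
successive spikes and compares `1 − exp(−ISI)` with the uniform
distribution. Two discrete-time corrections are applied. First, the
per-bin intensity mass is `−ln(1 − p)`, not `p`. Second — and
decisively — each spike's within-bin arrival time is drawn (seeded)
from its conditional exponential distribution, the randomized
discrete-time rescaling: without it the rescaled intervals live on a
lattice and the test rejects a *correct* model almost surely once the
spike count is large relative to the bin probability (measured: 0%
null coverage at p ≈ 0.03–0.05 with ~3000 spikes, ~95% with the
randomization). The raw deterministic transform remains available via
`jitter_seed=None`. Bands are the asymptotic `1.36/√n` (95%) and
`1.63/√n` (99%). Accuracy summaries use Wilson binomial intervals.

## The synthetic generator

Real recordings of this kind are not publicly deposited, so the
generator emulates their stated shape: on the order of 100 trials
(about half left, half right, assigned by a seeded permutation with
exact counts), tens of neurons per region, −2..+2 s windows at 2 ms.
CA3 units fire as inhomogeneous Bernoulli processes, 10 Hz baseline,
with side-dependent Gaussian rate-gain bumps — the experimental knob
for how decodable the memory is. CA1 is generated by a known sparse
Laguerre-domain ground-truth model (random first-order kernels of
per-input norm ~0.8, small second-order terms, a projected negative
exponential feedback kernel giving refractory suppression, intercept
~−2 for a 5–15 Hz output rate) driven by the generated CA3 trains, so
the fitting stage faces a well-specified truth and generated CA1 *is*
the model output, bit for bit. Spikes are written at bin centers, so
perievent extraction reproduces the generating matrices exactly.

Presets pin the study conditions. `easy`: 8 CA3 → 4 CA1, 200 trials,
six of eight CA3 neurons modulated ×3 peak gain over ~500 ms (three
left-preferring, three right-preferring, centers staggered at −0.5, 0,
+0.5 s), 25% of input groups zeroed in the ground truth. `null`: the
same geometry with zero modulation amplitude — left and right trials
are statistically identical and decoding must sit at chance. `hard`:
weak modulation (×1.5 peak), 5 CA3 / 3 CA1 neurons.

What the generator does **not** emulate: place-field geometry, theta
rhythm and other oscillatory structure, cross-neuron noise
correlations beyond those induced by shared inputs, across-session
nonstationarity, spike-sorting errors, and cross-input second-order
interactions (absent from the model class by design). Tests passing on
these sessions therefore certify the estimation and decoding machinery
— identifiability, sparsity recovery, re-encoding logic — not
biological realism of hippocampal codes.

## Problem sizes and numerical choices

The benchmark fit (4 outputs × two-fold CV over a 30-point penalty
path on 400k bins × 76 features) runs in a few minutes on one CPU;
test and acceptance runs use these sizes, with examples scaled to
40–60 trials for quick reading. Probabilities are clipped to
[1e−12, 1−1e−12] inside likelihoods; IRLS weights are floored at
1e−10; the KS harness clips intensities into (0, 1). Free-run
simulation draws each realization's feedback independently and resets
state at segment bounds; the predicted-pattern path decodes a single
realization by default (closest to the prosthesis use case), with the
mean-over-realizations-thresholded-at-0.5 variant also emitted — note
that at physiological rates the 0.5 threshold on a mean indicator
yields very sparse patterns, which is why it is not the default.

## Known limitations

* Second-order cross kernels and third-order kernels are out of scope,
  as is real-time operation and any stimulation control.
* Only binary (two-category) decoding is implemented; multinomial or
  alternative classifiers are not.
* The min-rule CV penalty is prediction-consistent but not
  selection-consistent; use the 1-SE rule when interpreting support.
* The adaptive second stage inherits whatever support the pilot
  selected; a falsely zeroed group stays zero.
* For binary inputs, first-order kernels and the diagonal of the
  second-order kernels are only jointly identified (`x² = x`); the
  penalty resolves the split, so per-component kernel errors include a
  small attribution ambiguity.
* The KS band is the large-n asymptotic; for fewer than ~50 spikes its
  coverage is approximate.
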