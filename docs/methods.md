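# Methods

## The model family

`suppfilt` fits four stimulus-encoding models of retinal ganglion cell
spiking, all expressed in one master cascade so that their components and
training are directly comparable:

    r(t) = f( [ ± Σ_i w_i g_i( Σ_τ k_τ X(t−τ) ) ± P(t) ] · M(t) + A(t) )

Time is discretized at the stimulus frame rate (60 Hz default; the axolotl
preset is 30 Hz) and `r(t)` is the expected spike count per bin of a Poisson
process (multiply by the frame rate for sp/s). Each stimulus branch is a
temporal filter `k` (unit Euclidean norm; the mean of its last five taps is
constrained to zero so filters decay) followed by a piecewise-linear
nonlinearity written in a tent (hat) basis `g_i` on 15 uniform knots spanning
[−3, 3] — the natural range of a unit-norm filter applied to unit-variance
noise. The output rectifier is a parametrized softplus
`f(x) = m·ln(1 + e^{ax+b}) + c`.

The four kinds differ only in how branch signals combine:

- **LN** — a single excitatory branch: `r = f(E)`.
- **Subtractive** — a second filter branch with a monotone nonlinearity whose
  output is subtracted before rectification: `r = f(E − S)`. The fixed
  negative sign plus the monotone shape guarantee the branch acts
  suppressively.
- **Divisive** — the second branch's nonlinearity is constrained to a bump:
  nondecreasing for negative inputs, nonincreasing for positive inputs,
  values in [10⁻¹⁶, 1] with the center weight (input 0) pinned at exactly 1.
  Its output multiplies the excitatory signal: `r = f(E · S)`. Pinning the
  maximum at unity both removes a scale redundancy with the excitatory branch
  and makes the multiplication a pure gain reduction.
- **Feedback** — a filter applied to the model's own recent spike counts is
  added to the excitatory signal (GLM-style): `r(t) = f(E(t) + Σ_τ
  k_fb(τ)·n(t−1−τ))`. The history filter has no nonlinearity and no norm
  constraint (only the zero-tail constraint). The convolution reads the
  *previous* bin's count at lag 0: a bin's rate must not depend on its own
  sampled count, otherwise sequential free-running generation would be
  circular.

Filter-output values outside [−3, 3] are clamped to the boundary knot value.
The first `n_taps − 1` bins of every trace are warm-up (the causal
convolution is zero-padded there) and are excluded from every likelihood and
metric computation, so all kinds are scored on identical bins.

## Training

All kinds are trained by block-coordinate maximum likelihood on the Poisson
negative log-likelihood (rates floored at 10⁻¹² inside the likelihood). One
component (a filter, a weight vector, or the rectifier) is free at a time;
the frozen rest of the model enters as the per-frame signals P (additive
before the multiplication), M (multiplicative) and A (additive after).
Blocks are visited in a fixed order — excitatory filter, excitatory weights,
then suppressive filter and weights (or the feedback filter), then the
rectifier — with up to 10 constrained optimizer steps per block (SLSQP for
filters and weight vectors with their equality/inequality constraints,
L-BFGS-B for the rectifier with a, m > 0), analytic chain-rule gradients
throughout. After each block update the parameters are projected exactly
onto their constraint set (tail-centering + renormalization for filters;
pool-adjacent-violators for the monotone and bump weight classes). The
renormalization implicitly rescales the downstream nonlinearity's input
axis; this is accepted because the nonlinearity is refit in the next block.
A candidate block update is kept only if it does not increase the training
objective, which makes the outer objective trace non-increasing by
construction.

The outer loop runs until 100 iterations or until the relative change of the
negative log-likelihood between consecutive outer iterations falls below
0.01% (interpreted per outer iteration, not per block). Training restarts
five times from a grid of initializations built from spike-triggered
statistics — the STA, the first and last eigenvectors of the spike-triggered
covariance with the STA direction projected out, standard-normal noise — and
weight templates (a soft-rectifier template `0.1·ln(1+e^{10u})` and a
unit-height bell over ≈2 SDs of the knot range, each with N(0, 0.1) knot
jitter, projected onto the shape constraints). The rectifier always starts
at `10·ln(1+e^{0.1x})`. The restart with the lowest training negative
log-likelihood is returned. Per-restart randomness derives deterministically
from the master seed plus the run index. The feedback filter is trained
teacher-forced (observed training spikes feed the history filter) — standard
GLM practice; free-running generation is used only at evaluation.

The `ln(n!)` term is included in reported negative log-likelihoods; it
cancels in every difference-based metric.

## Evaluation

- **Information per spike** (bits/spike): the log-likelihood gain of the
  model prediction over a constant mean-rate predictor on the same bins,
  divided by the total spike count times ln 2. Negative values are possible
  on held-out data and are not clipped. For the feedback kind the prediction
  is stochastic, so the metric is averaged over 100 free-running forward
  passes with distinct derived seeds.
- **Poisson explained variance**: `1 − dev(r, r̂)/dev(r, r̄)` with the
  Poisson deviance `dev = 2Σ[r ln(r/r̂) − (r − r̂)]` (0·ln 0 = 0), computed
  on trial-averaged frozen-noise firing rates.
- **R²** (`1 − SSres/SStot`) for the chirp sweeps, both globally and inside
  a 150 ms sliding window stepped one frame at a time (9-frame windows at
  60 Hz; a 480-frame sweep yields 472 windows). Each window is tagged with
  the contrast (%) or instantaneous frequency (Hz) at its start frame; the
  *performance range* reports the min/max axis values of windows with
  R² > 0 and, as its width, the measure of the qualifying set
  ((count − 1) × axis step). For contiguous qualifying sets this equals the
  min-to-max span; for noisy profiles it is robust to isolated lucky
  windows, which would otherwise stretch any model's span to nearly the
  full axis. The *low-frequency performance* is the mean R² of the first 10
  windows of the frequency sweep.
- **Cell characterization**: transiency (sustained-to-peak rate ratio of the
  preferred contrast step, transient strictly below 0.2), ON-OFF detection
  (U-shaped LN nonlinearity: line slopes sL, sR fitted to the two halves;
  ON-OFF iff sL/(|sL|+|sR|) < −0.2), excitation/suppression filter shift
  (argmax of the filter cross-correlogram; positive = suppression lags), and
  the asymmetry index of the divisive bump (|Σ_neg − Σ_pos| / Σ_total over
  the knot values excluding the center).
- **Unit selection** reports five independent flags: species-specific mean
  rate threshold (2 Hz axolotl, 5 Hz mouse/marmoset); split-half
  frozen-noise reliability (R² of one half-PSTH predicting the other,
  averaged over 20 random divisions, > 0.5); rate stationarity (|early −
  late| < 50% of the overall rate, first/last 30% of the recording); not
  ON-OFF; and held-out performance ≥ 60% of training performance for all
  fitted kinds ("performance" is information per spike, the headline
  metric). Split-half uses R² and partitions trials without replacement; an
  odd trial is left out.
- **Duplicate-unit removal**: zero-lag Pearson correlation of frame-binned
  rates; edges at r > 0.3; maximal cliques enumerated and resolved greedily
  largest-first, keeping the lowest index per clique.

## Stimuli

White noise draws one standard-normal value per frame (0 = mean luminance;
in the experiments the physical SD is 30% of the mean light intensity, so
100% contrast corresponds to 1/0.3 ≈ 3.33 model units — the default
`contrast_to_model_units`, exposed because the conversion used at test time
with real chirp recordings is a free choice). Recording schedules interleave
fresh training noise with a frozen test segment repeated after every block
(e.g., 150 or 300 frozen frames after every 750/900/1500), or use
pseudo-trials whose final fifth is held out. The chirp stimulus at 60 Hz is
120 background frames, 60-frame ON and OFF steps (±100% contrast), 60
background, a 480-frame frequency sweep (unit amplitude; linear-chirp phase
φ(t) = 2π·(f_max/2T)·t² with f_max = 15 Hz reached at the final frame), 60
background, a 480-frame contrast sweep (4 Hz sinusoid, envelope ramping
linearly 0→100%), and 60 background frames — 1380 frames (23 s) in total.
Frame indexing is 0-based with half-open intervals throughout.

## Synthetic ground truth

The synthetic module generates constraint-satisfying cells for end-to-end
testing: biphasic temporal filters as differences of two gamma kernels
(fast: peak ≈ 2 frames; slow: peak ≈ 5 frames; ON/OFF by sign), suppressive
filters either delayed copies of the excitatory filter (the delayed
gain-control motif of divisive suppression; the divisive preset uses a
2-frame delay) or independent biphasic filters (the subtractive preset pairs
fast excitation with slow suppression — a regime a single-filter LN cannot
absorb), and a moderate exponentially-decaying spike-history filter for the
feedback preset (peak −0.8, 1.5-frame decay ≈ 13 ms at 60 Hz). The rectifier
offset is calibrated by root finding (secant iterations on the free-running
rate for the feedback kind) so each cell fires at its target mean rate —
10 sp/s by default, within ±10% — on white noise.

The default recording scale is 12 blocks of 1500 fresh + 300 frozen frames
at 60 Hz: 18,000 training and 3,600 held-out bins (≈5 + 1 min), comparable
to the typical ≈7 min of training data per recorded cell and large enough
for reliable filter recovery at desk scale. Chirp responses are simulated as
15 independent Poisson trials.

What the generator does *not* emulate: spatial receptive-field structure,
non-Poisson spiking (bursting, true refractoriness beyond the feedback
kind), adaptation across the recording, spike-sorting artifacts, and
cell-to-cell correlations. Passing recovery tests therefore demonstrates the
correctness and self-consistency of the fitting machinery, not that real
ganglion cells obey these models.

## Numerical choices and degenerate inputs

- Softplus is evaluated as `max(z,0) + log1p(e^{−|z|})` (no overflow);
  rates are floored at 10⁻¹² only inside likelihoods and deviances.
- Free-running rates are capped at 10⁴ counts/bin: the spike-history filter
  carries no sign constraint, so a fitted filter can be net self-exciting,
  and the sequential rate → count → rate loop would otherwise diverge.
- Tent-basis derivative at a knot uses the right-hand slope; clamped inputs
  have derivative 0.
- A degenerate all-zero filter projects to a unit impulse rather than
  dividing by zero.
- Histogram-LN empty bins inherit the nearest nonempty bin's value so the
  lookup stays defined at extreme filter outputs.
- PCA filter-classification component signs are aligned so each component's
  largest-magnitude loading is positive; the ON/OFF meaning of score signs
  must be checked against class-mean filters. PCA uses centering only, no
  scaling.
- Zero-variance R² windows return NaN and are excluded from profiles.
- Cross-correlogram ties (filter shift) resolve to the smallest lag visited
  first (ascending order).

## Known limitations

- The divisive branch's bump nonlinearity makes the likelihood multimodal;
  the five spike-triggered restarts mitigate but cannot guarantee the global
  optimum. When the suppressive filter is a delayed copy of the excitatory
  filter, the product E(y_t)·S(y_{t−d}) admits near-equivalent
  re-parameterizations, and on some data realizations maximum likelihood
  genuinely prefers such an alternative mode (the generating parameters can
  have a *higher* training negative log-likelihood than both fitted modes),
  so filter recovery is not guaranteed even with matched model kind.
- Teacher-forced block-coordinate training of the feedback kind can fall
  into a deep local basin in which the history filter saturates against a
  compensating small rectifier slope; because the history filter starts at
  zero while the excitatory branch is still poor, restarts do not always
  escape it.
- The feedback kind's held-out evaluation is stochastic; on data generated
  by a Poisson feedback cascade the expected free-running information per
  spike of even the *generating* model falls short of a well-fitted LN
  (conditioned on the stimulus, the free-running rate realization is
  independent of the recorded spikes, so only the marginal statistics of the
  log-rate enter, at a Jensen penalty). Real cells carry history structure
  far stronger than Poisson-GLM data, which is where spike-history feedback
  pays off.
- Teacher-forced training of the feedback filter optimizes one-step-ahead
  prediction, not the free-running objective used at evaluation.
- Sliding-window R² is noisy for windows with few spikes; profiles should be
  read alongside the PSTHs.
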