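# Methods

## Signal model and processing chain

A session is a `T x 15` matrix of odor-feature values (default `T = 300`,
1.8 s sample period) with phase cuts at samples 100 and 200 separating
pre-exposure air (A), odor exposure (B), and post-exposure air (C). The 15
features come from averaging the member channels of each group in the 4x16
sensor grid; each feature has exactly 3 member channels, and the 19
reference positions (4 in arrays 1/3/4, 7 in array 2) are validated but
never used numerically — the device documents them "for calibration", but
no calibration formula is defined, so REF-based correction is out of scope.

Per feature column, in order:

**Savitzky–Golay smoothing** (window 51, degree 3). Each sample is replaced
by the value of the degree-3 least-squares polynomial over its centred
51-sample window. Edge handling is polynomial extension (`scipy`'s
`mode="interp"`): the first/last complete window's polynomial is evaluated
at the edge positions, so output length equals input length. The filter is
linear and exact on polynomials of degree ≤ 3.
`tune_smoother` grid-searches window x degree under a per-signal latency
budget; its objective is the MSE against a held-out repeat of the same
signal, which is the only objective of the "reconstruction vs latency"
family that does not degenerate to the identity filter. The default budget
is 100 ms and configurable.

**Drift correction.** The nanotube baseline sags slowly and roughly
linearly under continuous stimulation. An OLS line `a + b·t` is fit to the
first `fit_window = 100` samples (all of phase A; sample index origin 0)
and removed over the whole session, re-adding the first sample so the
corrected trace keeps its physical level:
`corrected[t] = x[t] − (a + b·t) + x[0]`.
The fit window must not extend past phase A — exposure samples in the
baseline fit would absorb part of the response as "drift". Related caveat:
the 51-sample smoother leaks the exposure onset ~25 samples back into phase
A, so on near-step responses a fit over all 100 baseline samples picks up a
small spurious slope. This is inherent to the published stage order
(smooth, then fit); analyses that need an unbiased slope on sharp steps can
pass a shorter `fit_window` (≤ 75) or fit on the raw column.

**Normalization.** Centre-reduction per column over the full session with
population σ (divisor T), matching the StandardScaler convention. Scope is
per column per session: the goal is comparable signal *shapes* across
sessions, not a global scale. Zero-variance columns raise rather than
emitting zeros — a flat chemiresistor column is a dead channel, and the
check uses a relative tolerance (σ ≤ 1e-12·max(1, |μ|)) because smoothing
a flat trace leaves O(eps) float residue.

## Indicators

`R` = max over phase B; `R0` = mean over phase A; `Rq` (q = 10, 25, 50, 75)
= mean over the exposure prefix of `ceil(q% · |B|)` samples. The prefix-mean
reading (rather than a point value) makes the cheap indicators robust to
single-sample noise, which is what makes them attractive at low latency.
`Ind1 = R − R0`, `Ind2 = Ind1 / R0`, and
`Ind3 = Ind2 / sqrt(Σ_{i=0}^{N−1} ((R0_i − R_i)/R0)²)` with `R0_i` the
drift-line prediction and `R_i` the drift-corrected sample, `N` the session
length (300 terms under the standard protocol — an upper index of N over an
N-sample signal is resolved as 0..N−1).

Indicators are computed on the **drift-corrected, pre-normalization**
signal: `R0` keeps its physical scale (so `Ind2` is a meaningful relative
amplitude and scaling a raw column by `a > 0` scales `R, R0, Rq, Ind1` by
`a` while leaving `Ind2` invariant), and the Ind3 residuals compare signal
and drift line in the same units. When a zero response makes both the Ind3
numerator and denominator vanish, Ind3 is defined as 0; a zero denominator
with a nonzero numerator raises.

Two table granularities exist because the protocol's sample accounting
(6000 time points, 2000 exposure) is only consistent with per-sample rows,
while `R`/`R0` are per-session scalars: `session` granularity (one row per
session, the chosen indicator per odor feature) feeds the indicator-by-model
comparison; `timepoint` granularity (one row per normalized sample, tagged
with its phase) feeds the "raw normalized data" baseline and SMOTE.

## SMOTE

Synthetic exposure rows are `x + u·(x_nn − x)` with `u ~ U[0,1]` and `x_nn`
one of the k = 4 nearest minority neighbours of `x` (Euclidean). Synthesis
runs per substance inside the minority selection, which guarantees the
balanced per-substance split (+500 rows each for the default protocol);
pooled-minority SMOTE cannot. Neighbour ties break by row index and all
draws come from a seeded generator, so augmentation is fully deterministic.
The implementation is in-package: it is small, and the determinism and
per-class guarantees above are part of its contract.

In cross-validation the default placement is leakage-free: folds are
stratified over real rows and synthetic rows are generated from (or joined
to) training folds only. A `pooled` mode reproduces the simpler
augment-then-split procedure; the run manifest records which mode was used.

## Classifier harness

Five scikit-learn models with two named hyperparameter variants:
`default` (library defaults: GaussianNB; L2 logistic regression with
lbfgs, `max_iter=100`; 100-tree Gini random forest; `(100,)`-unit adam MLP;
RBF C-SVM) and `compact` (identical except the MLP: one hidden layer
of 5 relu units, lbfgs — the compact network suited to edge deployment).
Stochastic models receive the run seed. Accuracy is the plain fraction
correct under stratified 5-fold CV (stratification because per-class counts
are small); the indicator-by-model table appends arithmetic row and column
averages. Convergence warnings from logistic regression/MLP at their
default iteration caps are expected and left as-is — raising the caps would
silently change the models under comparison.

## Synthetic data generator

Each class has a 15-vector of steady-state response amplitudes (a
"signature") with first-order kinetics: phase B adds
`sensitivity · amplitude · (1 − exp(−t/rise_tau))`, phase C decays with
`decay_tau` toward `(1 − recovery_fraction) · plateau` above baseline
(incomplete recovery = sensor saturation), all on a linearly drifting
baseline with i.i.d. Gaussian noise. Exponential kinetics are the simplest
dynamics consistent with the observed session shapes; no physical
nanotube-adsorption model is attempted.

Default study conditions (chosen once, as a realistic desk-scale emulation
of the measurement design): 4 substances x 5 campaigns x 300 samples;
baseline 1000 resistance units; drift slope −0.05 units/sample (the
continuously decreasing trace); noise sd 2.0 units; per-campaign
sensitivity falling 1.00 → 0.85 (saturation across a measurement day);
whiskey-like rise/decay constants 15/40 samples with recovery fraction 0.8.
The preset holds three overlapping "whiskey-like" signatures (amplitudes
25–45 units, differing by ~5–15 units per feature, i.e. ≥ 5 noise sd in
several features) plus one well-separated "acetone-like" signature (90–140
units, faster kinetics), mirroring the hard 3-class and easy 2-class tasks.

What the generator does **not** emulate: temperature/humidity coupling,
non-linear drift, inter-campaign environmental variability beyond the
sensitivity schedule, or correlated channel noise. Passing tests therefore
demonstrate that the pipeline recovers structure *of this kind*; they do
not certify accuracy on real recordings, whose class overlap is set by
chemistry, not by a preset.

## Streaming inference

The smoother needs a full 51-sample window, so the stream warms up for 50
frames and emits its first prediction at frame 51, then one per frame: the
Savitzky–Golay polynomial of the current buffer is evaluated at the newest
sample and the model classifies that 15-vector. A replayed `T`-frame
session yields `T − 50` predictions, identical to batch recomputation over
the same windows (tested). Phase-complete indicators (`R`, `Ind3`) need a
finished session and are not available in stream mode; timepoint-granularity
models are the streaming default. Malformed frames are logged and skipped
without touching the buffer.

## Problem sizes and numerical choices

Tests and the acceptance script run the full standard protocol (20 sessions
x 300 frames) for dataset accounting and classification, and smaller
fixtures (150–400 samples, 12-row SMOTE tables) for brute-force oracle
comparisons — sizes at which exhaustive checks (windowed-OLS smoothing,
segment-membership search) are exact and fast. Oracle agreement is asserted
at 1e-9, identities at 1e-12, and statistical checks (chance-level
accuracy) at 3 binomial standard errors; cross-validated accuracy of a
random forest on label-free noise is pessimistically biased below chance,
which the 3-SE band absorbs at these sample sizes.

## Known limitations

- Drift is modelled and removed as linear only; real drift is not perfectly
  linear, and residual curvature leaks into the indicators.
- REF channels are validated but unused (no published calibration rule).
- The session CSV round-trip preserves values to 9 significant digits, not
  bit-exactly.
- `Ind3`'s residual definition follows the printed formula; its literature
  provenance was not re-derived.
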