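# Methods

This note documents the models, the numerical choices, and what the
synthetic experiments do and do not demonstrate.

## Signal model and preprocessing

Trials are epoched multichannel EEG, `X ∈ ℝ^{c×T}`, cue onset at `t = 0`,
labels ±1 for left/right-hand motor imagery.  The decodable signal is an
event-related power change of sensorimotor rhythms, so everything outside
8–30 Hz is discarded by a 6th-order Butterworth band-pass.  Filtering is
applied forward and backward (zero phase): the effective magnitude response
is the squared Butterworth response and latencies are undistorted.  Edge
transients are absorbed by odd-reflection padding of up to one second
(never less than 3× the design order).  Crop windows are half-open
`[t_start, t_end)` with sample count `round((t_end−t_start)·fs)`.
Subband filters inside the filter banks use order 4 rather than 6: at
250 Hz sampling a 4–9 Hz-wide band-pass of order 6 is numerically fragile,
and the −3 dB semantics of the band edges are unchanged.  Band edges are
design corner frequencies, not brick walls.

## Euclidean alignment

For each subject, `R̄ = (1/N) Σ_i X_i X_iᵀ / T` (the per-trial covariance is
normalized by the sample count so its scale is variance-like), and every
trial is replaced by `R̄^(−1/2) X_i`.  The inverse square root is the
principal one, via symmetric eigendecomposition with an eigenvalue floor of
`1e−10 ×` the largest eigenvalue; a rank-deficient `R̄` additionally gets a
ridge of `1e−8 · tr(R̄)/c` on the diagonal, with a warning.  Alignment is
label-free and pools all of a subject's trials — it is a distribution-level
correction, not a discriminative one — and sits after band-pass/cropping
and before filter-bank decomposition.  Aligning aligned data is a no-op.

## Regularized CSP

Per-trial covariances are trace-normalized before class averaging, making
trials commensurate under amplitude drift; class means therefore have unit
trace.  CSP solves `C⁺ w = λ (C⁺ + C⁻) w`; eigenvalues lie in (0, 1) and
the `n_pairs` largest and smallest (default 2 + 2 for c = 8) are kept.
Columns are scaled so `Wᵀ(C⁺+C⁻)W = I` on the kept subspace and signed so
each filter's largest-magnitude entry is positive, which makes results
independent of the eigensolver's sign conventions.

The regularized class covariance interpolates between the target subject's
own estimate (β = 1) and the pooled source-subject estimate (β = 0), then
shrinks toward the average-eigenvalue identity `(tr/c)·I` by γ.  The
shrinkage target is fixed once as a named constant (`SHRINKAGE_TARGET` in
`micross.spatial`); shrinking toward the average eigenvalue is the standard
small-sample covariance remedy and keeps the result SPD for all
(β, γ) ∈ [0,1]².

Two covariance-calibration modes exist because strict leave-one-subject-out
testing leaves no labeled target trials to estimate `C̄_t` from:

* **source-only** (default): β is forced to 0; no target label is touched.
* **calibration**: a leading fraction (default 20%) of the target's trials
  enters the covariance mixture and a few-shot weight update, and is
  excluded from testing.

The mode, and everything else fitted per fold, is recorded in the result's
provenance and audit trail.

(β, γ) are not fixed by the method definition; they are chosen per fold by
inner 5-fold stratified cross-validation on the training (source) trials
over the grids γ ∈ {0, 0.001, 0.01, 0.1} and, in calibration mode,
β ∈ {0, 0.1, …, 0.9}.  The inner classifier is a ridge classifier — exactly
the single-task specialization (μ = 0, Σ = I, fixed λ) of the multi-task
update below — because the full multi-task fit needs several subjects and
would be circular inside one pooled training set.

## Feature extraction

Log-variance features per band: project through `W`, take per-filter
variance `v_j` (the mean square of the zero-mean filtered signal), return
`log(v_j / Σ_j v_j)`.  The ratio normalization makes features invariant to
per-trial amplitude scaling.  Since `v_j = w_jᵀ (XXᵀ/T) w_j`, the harness
computes features directly from cached per-trial covariance matrices; the
signal route and the covariance route agree exactly and a test asserts it.
The band-power baseline (`BP`) uses `log` mean-square amplitude per channel
of the 8–30 Hz signal, floored at `1e−12`.

## Subband selection

Per band, the Fisher score `f_s = Tr(S_B)/Tr(S_W)` of the feature vectors
(`ε = 1e−12` guards the denominator).  Because EEG band power falls with
frequency, scores are reweighted, `ξ_n = w(n)·(f_sⁿ)²` with
`w(n) = n^(−a) + b`, and the band with maximal ξ is selected (ties go to
the lowest band index; `k_bands > 1` concatenates the top bands'
features).  The method definition leaves open how to judge one (a, b)
against another — ξ values are not comparable across weightings — so the
grid (a ∈ {0, 0.5, 1, 1.5, 2}, b ∈ {0, 0.5, 1}) is scored by the same
inner-CV accuracy as above, with ties resolved to the lexicographically
smallest (a, b).  Distinct (a, b) cells that select the same bands share
one CV evaluation, so the grid search costs a handful of ridge fits.

### A bandwidth bias worth knowing about

On synthetic data with an effect planted exactly at 18–26 Hz (VFB band 6),
selection lands on band 5 (16–25 Hz) or band 6 — both beta subbands —
rather than always on band 6.  The cause is measurable: the within-class
scatter of the non-discriminative filter dimensions of the log-variance
vector scales like `1/(bandwidth × duration)`, so of two bands capturing
the same effect the wider one gets a slightly higher Fisher score.  With an
oracle spatial filter (the true unmixing row) the Fisher score peaks at
band 6 decisively; a test pins that.  Recovery statements in the tests and
the acceptance report therefore count either of the two overlapping beta
subbands as a hit.

## Multi-task linear classification

Each training subject `s` is a regression task (`F_s`, `y_s`), features
with an appended constant-1 bias column, labels ±1.  The objective is

    L = (1/λ) Σ_s ‖F_s w_s − y_s‖² + Σ_s [(w_s−μ)ᵀΣ⁻¹(w_s−μ) + log det Σ]

— a Gaussian observation model with noise scale λ and a shared Gaussian
prior N(μ, Σ) on the task weights.  The penalty is written so that the
closed-form per-task update

    w_s = ((1/λ) Σ F_sᵀF_s + I)⁻¹ ((1/λ) Σ F_sᵀ y_s + μ)

is its exact minimizer in `w_s`; published variants of this framework
differ by constant factors on the penalty, which are absorbed into λ.
Block coordinate descent alternates this update with the prior update
μ = task mean, `Σ = (scatter + ε₀ I)/S` (divisor S, ε₀ = 1e−6).  The
constant ridge is an inverse-Wishart-style regularizer: `Σ` is then the
exact minimizer of `L + ε₀·tr(Σ⁻¹)`, so the monitored objective is
guaranteed non-increasing even when there are fewer tasks than feature
dimensions and the raw ML covariance would be singular (where the
unregularized `L` is unbounded below).  A trace-scaled ridge was rejected
because it changes the descent objective between iterations and measurably
breaks monotonicity in that regime.  Initialization is fixed (μ = 0,
Σ = I), convergence is a relative objective change below 1e−6 (default cap
100 iterations), so fits are deterministic.  λ defaults to 1.0.

Prediction for the unseen subject uses the prior mean, `ŷ = sign(F μ)`,
with score 0 mapping to +1; in calibration mode the few-shot update on the
calibration trials supplies a target-specific `w_t` instead.

## Evaluation protocol

Leave-one-subject-out: preprocessing (band-pass, crop, per-subject EA) is
label-free and target-independent, so it is applied once; spatial filters,
subband choice, regularization strengths and the classifier prior are
fitted inside each fold from the remaining subjects only.  An audit trail
lists, per fold, exactly which subjects (and how many declared calibration
trials) entered fitting; tests assert the target never appears.  Accuracy
is percent correct; Cohen's kappa is computed from the same confusion
matrix with κ = 0 when expected agreement is 1.  Results report per-subject
values and cohort mean ± sd, both to two decimals.

The `FBCSP` variant concatenates plain-CSP log-variance features of all ten
CFB bands without mutual-information selection — a documented
simplification of that baseline's classic form.

## Synthetic cohorts

The generator emulates the structure the pipeline assumes: one latent
source band-limited to `planted_band` (default 18–26 Hz) whose variance is
multiplied by `effect_size` (default 3.0) for class +1 — a multiplicative
ERD/ERS analogue — plus `c−1` unit-power broadband background sources,
mixed to `c = 8` channels by `A_subj = A₀(I + subject_shift·P_subj)` with a
shared well-conditioned `A₀` (singular values clipped to [0.7, 1.5]) and
per-subject unit-spectral-norm perturbations (default shift 0.3), plus
white sensor noise of σ = 0.1 (≈ −20 dB relative to source power, a
realistic floor that leaves single-trial band power clearly but not
perfectly observable).  Band-limiting uses the pipeline's own zero-phase
Butterworth machinery.  Defaults follow the study design the pipeline
targets: 9 subjects, 72 trials per class, 250 Hz, 3 s epochs.  Everything
is a pure function of `(seed, subject_index)`.

What the generator does **not** emulate: 1/f background spectra,
non-stationarity within and across sessions, eye/muscle artifacts,
volume-conduction-realistic mixing, class-dependent timing structure, and
per-trial natural power fluctuation of the discriminative source (each
trial's source is variance-normalized, so class separations are cleaner
than in real EEG).  Passing the simulation study therefore demonstrates
correctness of the machinery and the expected qualitative behavior
(alignment helps under covariance shift; selection finds the planted band;
nothing decodes a null effect) — not real-data accuracy levels.

## Experiment sizes in tests and the acceptance report

* Decodability and null calibration run on full default cohorts
  (9 × 144 trials); the null check pools three independent cohorts per
  variant and bounds the grand mean by 50 ± 3 percentage points, because
  LOSO folds share 8/9 of their training data and their accuracies are
  strongly correlated — the pooled-trial binomial interval would
  understate the spread (measured cohort-level sd ≈ 2.3% vs binomial
  1.4%).
* The alignment-benefit experiment pairs alignment-on/off over 20 seeds at
  effect 1.5, shift 0.6, 5 subjects × 60 trials: at the default effect 3
  both arms saturate at 100% and no contrast is measurable, so the
  comparison is run in a deliberately harder, non-saturated regime.
* Planted-band recovery uses 20 independent single-subject simulations at
  defaults.

## Known limitations

* Multiclass decoding, other RCSP flavors (Tikhonov, weighted Tikhonov),
  kernelized or fully Bayesian multi-task variants are out of scope.
* The GDF adapter is a thin optional wrapper (epoching + label mapping);
  it performs no artifact handling and is not exercised offline.
* Inner-CV model selection uses a single shared seed per run; selection
  variance across CV reshuffles is not averaged out.
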