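# Methods

`chillconn` implements a brain-network predictive-modeling pipeline for
music-evoked chills: short pre-listening resting-state epochs are reduced
to partial-correlation connectivity features between an auditory seed
network and other functional networks, and nested cross-validated LASSO
models decode chills-related targets — the reported duration of chills,
the event-locked skin-conductance response, and region-wise event-locked
BOLD amplitude.  This note records the model, its assumptions, the
numerical choices, and what the synthetic cohorts do and do not emulate.

## The decoding model

For units *i* (participants, or trials) with feature vectors
*x<sub>i</sub>* (Fisher-z partial correlations) and target *y<sub>i</sub>*
(seconds of chills, or an intensity score), the decoder solves

    min_w  (1/2n) Σ_i (y_i − x̃_i·w − b)²  +  λ Σ_j |w_j| ,

where *x̃* is the feature vector standardised with mean/SD learned from
the training units only.  Accuracy is estimated by nested leave-one-out
cross-validation: the outer loop holds out one unit; inside each outer
training fold, an inner leave-one-out evaluates every penalty on the
fixed grid λ ∈ {0.001, 0.01, 0.1, 1, 10, 100, 1000} by the Pearson
correlation between the inner held-out predictions and their actual
values; the best penalty (ties broken toward stronger shrinkage) is
refit on the full training fold and predicts the held-out unit.  The
reported accuracy is the Pearson *r* between the *n* held-out predictions
and the actual targets.

Assumptions worth making explicit:

* the relation between connectivity and target is linear and sparse in
  z-transformed edges;
* standardisation statistics, penalty selection and weights never see
  the held-out unit (enforced structurally and by a mutation test);
* degenerate folds (constant predictions) yield an undefined correlation
  and are reported as NaN with a flag, not coerced to 0.

### Exact penalty paths instead of per-penalty coordinate descent

Single fits (`lasso_fit`) use scikit-learn's coordinate descent.  The
cross-validation loops instead walk the LARS-lasso homotopy path: the
LASSO solution is piecewise linear in λ, so one pass from λ_max down to
the smallest grid value yields the exact minimiser at every grid penalty
for a fold at once (`chillconn/_solver.py`, numba-compiled, incremental
Cholesky of the active-set Gram with a 1e-10 diagonal jitter).  On the
strongly collinear feature sets this pipeline produces, coordinate
descent needs 10⁵–10⁶ sweeps to converge at λ = 0.001 whereas the path
is exact in ~70 knots; agreement between the two routes is asserted in
the test suite.  This is what makes 1,000-permutation re-runs of the
full nested CV practical on one CPU (~0.6 s per nested CV at n = 38,
96 features).

### Inference

* **Permutation test** — the entire nested CV (penalty selection
  included) is re-run on targets permuted without replacement;
  p = (1 + #{null ≥ observed}) / (1 + n_perm), which never returns 0.
  Desk-scale default 1,000 permutations.
* **FDR** — Benjamini–Hochberg step-up across network pairs or edges
  (statsmodels), validated against an exhaustive implementation.  For
  the pair-level analysis the inference order matters: the correlation
  test serves only as an economical *screen* (it is anticonservative
  for cross-validated accuracies — held-out predictions are not
  independent draws), permutation tests are run for the screened pairs,
  and FDR is applied to the permutation p-values with unscreened pairs
  entering at p = 1.
* **Correlation p-values** — the exact null of Pearson's r (beta/t with
  n−2 df).  `critical_r` inverts it (Brent root-finding, 1e-9), and
  `min_n_for_r` scans n upward for the minimal significant sample: at
  the observed accuracy r = 0.53, n = 11 is the smallest sample with a
  one-sided critical value (0.5214 → 0.52 at two decimals) below it.
* **Model comparison** — bootstrap of the difference between two
  predictors' correlations with the same outcome (resampling units with
  replacement; percentile 95% CI; two-sided CI-inversion p; degenerate
  resamples skipped and counted).
* **Pre-task vs intrinsic edges** — a per-edge paired t test on
  participant-level condition means with BH-FDR across edges.  This is a
  deliberate simplification of a trial-level mixed model; trial-level
  connectivity remains exportable for users who want to refit one.

## Connectivity features

Rest epochs are linearly detrended and band-passed 0.008–0.09 Hz
(2nd-order Butterworth, forward–backward, hence zero phase); music
epochs are detrended and high-passed at 0.008 Hz only, so event-locked
responses survive.  Windows are half-open `[start, end)` in seconds and
are cut *after* filtering the full epoch; a volume belongs to a window
iff its onset time falls inside.

Connectivity between ROIs i and j is the partial correlation
−P<sub>ij</sub>/√(P<sub>ii</sub>P<sub>jj</sub>) from the precision matrix
P = Σ̂⁻¹.  With ~20 volumes and 288 ROIs the sample covariance is
singular, so Σ̂ shrinks toward a scaled identity; the coefficient comes
from the Ledoit–Wolf formula by default (recorded in the feature
object), with an explicit override for sensitivity analyses.  Values
pass through Fisher's r-to-z before modeling (|r| ≥ 1 clipped to
1−10⁻⁷ with a warning).

The conditioning set is the full ROI set of the series; edges are
selected afterwards.  The single-hemisphere auditory–reward models are
the exception: their 45 edges come from a 10-ROI (6 auditory + 4 reward)
partial-correlation matrix computed over that subset only
(`conditioning="subset"`), matching how such compact models are
estimated.  Edge identity and ordering are fixed as the row-major upper
triangle over *sorted* ROI ids, so exported weight vectors align across
runs and cohorts by identity, not by column position.

Per participant, per-trial z-matrices are averaged over available trials
(missing trials skipped and counted) before edge selection.  The
feature sets are: cross-network edges only for network pairs (12
auditory × 8 reward = 96), the full upper triangle for hemispheric
(C(10,2) = 45) and whole-brain (C(288,2) = 41,328) models.

## Behavioral targets

Button events (neutral / pleasure / chill / tear; chill+tear may
co-occur) are cleaned in two ordered steps: presses shorter than 1 s are
dropped, then consecutive same-label presses merge into one event whose
duration is the sum of the merged presses.  Because dropping precedes
merging, a sub-second press between two same-label presses bridges them.
Per-trial totals per label, and their mean across a participant's
trials, are the decoding targets.  Trial-level analyses first remove
trials more than 3 SD *above* the mean duration (one-sided screen).

## Physiology and event-locked BOLD

* **Rates** — pulse and respiration peaks (scipy `find_peaks` with a
  channel-appropriate refractory distance), inverse inter-beat intervals
  placed at the second peak of each pair, cubic-spline interpolation to
  a uniform 10-Hz grid with constant extension beyond the outermost
  peaks.
* **Skin conductance** — the trace is low-passed at 1 Hz, downsampled to
  10 Hz, and split into a tonic level — a smoothed 20-s running minimum
  (a low-pass absorbs response amplitude; the lower envelope does not) —
  and a phasic remainder.  The nonnegative phasic driver is recovered by
  FISTA-projected least squares against the Bateman impulse response
  h(t) = e^(−t/τ₂) − e^(−t/τ₁) (τ₁ = 0.75 s, τ₂ = 2 s) with a small
  Tikhonov penalty (10⁻³) and 400 iterations; driver excursions whose
  reconstructed response peaks below 0.05 μS are zeroed.  This is a
  deterministic, testable stand-in for continuous decomposition
  analysis: on noiseless input it recovers impulse times to ±0.5 s and
  reconstructs the response to within ~4% L2 error.
* **Event-locked sums** — per event, baseline = mean of the 1 s before
  onset; score = Σ(value − baseline) over the event window; events
  starting inside the baseline window are skipped with a warning.
  Outlier events are screened at 3 SD using leave-one-out reference
  statistics: with the handful of events a participant contributes, an
  inclusive screen can never trigger (max attainable z = (n−1)/√n).
  Skin-conductance totals are log(1+x)-transformed (admits zero totals).
* **BOLD percent signal change** — event windows shift by +4 s for
  hemodynamic delay (the signal is not resampled).  The baseline is the
  mean of the volumes at onset−2 and onset+2 volumes, skipping the
  onset-adjacent ±1 volumes; the adjacent-volume reading is available
  via `baseline_volumes="adjacent"`.  PSC = 100·(x − baseline)/baseline;
  a non-positive baseline raises an error naming the ROI; scores are
  summed over the shifted event window and screened as above.

## The synthetic cohorts

A latent coupling g — N(0, 0.7²) per participant plus N(0, 0.2²)
trial jitter — drives everything:

* **Rest covariance.**  The base ROI correlation template has
  within-network r = 0.3, cross-network r = 0.1.  A *shared component*
  spanning the auditory and reward ROIs with variance
  0.1·e^(1.5g) is added to every pairwise covariance in that block (ROI
  variances stay 1).  Every auditory–reward cross edge therefore rises
  monotonically with g, and the matrix is positive definite for any g —
  a uniform block shift cannot inject a signal of this size (its
  spectral norm is PSD-capped below the estimation noise of 20
  band-passed volumes), and a shared-state component is the more
  plausible physiology anyway.  Volumes follow an AR(1) with lag-1
  correlation 0.25 around the template.
* **Behavior.**  Chills duration per trial =
  clamp(50 + 50·g + N(0, 25²), [0, song − 10]) seconds, yielding a
  population mean ≈ 50 s and between-participant SD ≈ 35 s.  Event
  trains realise that duration exactly after cleaning: 1 + Poisson(2)
  chill events with log-normal (median 10 s) durations rescaled to the
  target, the remaining timeline filled with neutral/pleasure/tear
  presses; the generator also plants sub-second spurious presses,
  contiguous same-label double presses, and chill+tear co-occurrences to
  exercise the cleaning rules.  Durations under the 1-s press threshold
  are treated as zero chills.
* **Music epochs** carry the base (uncoupled) covariance plus
  double-gamma HRF responses at chill onsets in the reward ROIs, with
  amplitude ∝ max(0, 1 + 0.5g) — about 1% signal change at g = 0 over a
  baseline of 1000 units.
* **Physiology** — electrodermal: tonic drift plus Bateman-convolved
  impulses at chill onsets with amplitude ∝ (1 + 0.5g); pulse: Gaussian
  bumps at slowly modulated inter-beat intervals (65 bpm); respiration:
  a noisy 0.25-Hz oscillation.  Default sampling 100 Hz.
* **Intrinsic rest** (optional, 10 min) uses the base covariance with
  *no* coupling: the planted signal is a pre-listening state, not a
  stable trait, so decoders transfer across cohorts from task rest but
  not from intrinsic rest.

What the generator does **not** emulate: head motion, scrubbing and
non-linear scanner drift; spatially structured noise; hemispheric
asymmetry (the shared component loads both hemispheres equally, so left
and right 45-edge models behave alike — the package's asymmetry
machinery is exercised, but no lateralised effect is planted);
heart-rate/respiration coupling to the events (those decoders should
stay at chance); non-stationarity within an epoch beyond linear drift.
Passing tests therefore demonstrate procedure correctness and
recoverability under the planted model, not performance on real
recordings.

## Problem sizes

The acceptance-grade checks run the planted-recovery analysis at the
full design (38 participants × 8 trials, 288 ROIs, 40-s rest at TR 2 s,
1,000 permutations); type-I calibration uses 200 null cohorts of 14
participants × 2 trials with a 6-ROI parcellation at 200 permutations
each; transfer generalization uses 20 replicate cohort pairs (24 → 11
participants) on a 22-ROI parcellation.  Unit-test cohorts shorten songs
to 60 s and physiological sampling to 20–25 Hz; the 40-s rest epochs,
TR, and preprocessing are everywhere those of the full design.

## Known limitations

* With n ≪ p and strongly collinear edges, the inner accuracy criterion
  often prefers very small penalties; under the null this yields dense,
  meaningless supports — significance must come from the permutation
  test, never from support size.
* Ledoit–Wolf shrinkage makes short-window partial correlations
  systematically smaller in magnitude than their population values;
  window-length sweeps therefore confound window information content
  with estimator bias, exactly as they do in practice.
* The trial-level "following rest" variant attributes the next trial's
  pre-listening rest to the previous song and drops each session's last
  trial; with 2 sessions of 4 trials this removes a quarter of trials.
* The SCR deconvolution is intentionally simple; it is validated against
  its own forward model, not against continuous decomposition analysis.
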