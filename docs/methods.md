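# Methods

## Model

A heartbeat is modelled as the difference between the transition
probabilities of two collective myocardial groups.  Individual AP
transitions (threshold crossings) are treated as a time-series point
process with Gaussian timing; the population is large, so the fraction of
the anodic (endocardial-side, positive-EMF) or cathodic (epicardial-side,
negative-EMF) group that has depolarised by time *t* is a Gaussian CDF
`Φ((t − μ)/σ)` scaled by a weight *k* (mV).  Repolarisation is the
complementary process, the falling curve `k (1 − Φ)` — called the
"inverse CDF" in this context; it is *not* the quantile function.  The
difference of the anodic and cathodic curves approximates the lead
voltage: `f_Rp − f_Rn` for the R wave, `f'_Tp − f'_Tn` for the T wave.
An additive level β is applied to the difference (not inside the CDFs);
whether the original formulation placed it elsewhere is indeterminable
from differences alone, and the additive choice keeps β a plain baseline.

Falling components are parameterised explicitly as `k (1 − Φ)` with
σ > 0 and a direction flag, rather than as a reversed-argument Φ, so
spreads stay positive and monotonicity is explicit.

**RT-separate** fits the R and T differences independently on the QRS
window `[QRS onset, J]` and the T window `[T onset, T end]`; each segment
has seven free parameters (μp, μn, σp, σn, kp, kn, β), giving two levels
βR, βT per beat.  **RT-bulk** fits one equation over `[QRS onset, T end]`:
each group is an AP-like trapezoid `k_Rx Φ_Rx − k_Tx Φ_Tx`, the waveform is
the anodic minus the cathodic trapezoid plus a single β, and the plateau
constraint ties T weights to R weights.  During the depolarised plateau
the bulk waveform sits at `k_Rp − k_Rn + β`, the model's ST level.

Temporal ordering μRp ≤ μRn ≤ μTn ≤ μTp is the physiologic regime.  It is
checked and reported, never enforced or silently repaired: inverted fits
are flagged, because inversions (the cathodic falling curve outlasting the
anodic one, detected as the latest `f'_Tp = f'_Tn` crossing with
`f'_Tn > f'_Tp` afterwards) are themselves clinically meaningful.  Crossing
detection scans a 1 ms grid over `[μTn − 3σTn, μTp + 4σTp]` and refines the
latest sign change by bisection.

The time reference is QRS onset per beat; published tables constrain only
μ *differences*, so absolute means are reconstructed from the interval
metrics with a configurable μRp reference (100 ms by default).

## Estimation

Bounded trust-region-reflective least squares (SciPy `least_squares`,
`trf`).  Defaults: σ ∈ [1, 200] ms, k ∈ [0, 20] mV, β ∈ [−2, 2] mV, μ
inside the fitted window ± 50 ms; tolerances 1e−12.  Initial values come
from the fiducials: R-pair means straddle the R peak by a quarter QRS
width, T-pair means straddle the T peak, σ initialised at QRS/4 (R legs),
T/4 (σTp) and T/2 (σTn) reflecting the population ordering
σRn < σRp ≪ σTp < σTn, weights from the R/T amplitudes over the PQ
baseline.  Three deterministically perturbed restarts (seeded) guard
against local minima; identical inputs, configuration and seed give
bit-identical results.

The bulk plateau constraint is `hard` by default (kTp := kRp, kTn := kRn;
9 free parameters).  `penalty` mode adds `λ[(kTp−kRp)² + (kTn−kRn)²]` to
the cost (11 free parameters).  When no λ is given, it is set adaptively:
an unpenalised fit estimates the residual MSE, then `λ = 10 · n · MSE`.  A
fixed λ proportional to signal power measurably biases noiseless fits
(σTp error of ~3% on the population-mean round trip), whereas the adaptive
weight vanishes on clean signals and approaches `10 n σ²_noise` on noisy
ones — stabilising the T-weight direction exactly when the data cannot
identify it.

Extended mode augments the QRS window with up to two extra anodic/cathodic
rising pairs (delta waves, deep S waves, J waves); more than two is
refused as unidentifiable.  It is a two-stage fit — canonical solution
first, then a joint QRS refit starting from it with zero extra weights —
so the extended cost never exceeds the canonical cost.  A cancelling pair
(equal μ's) leaves its weight unidentifiable; a tiny ridge
(`1e−3 · sqrt(n · mean(y²))` per weight) resolves that flat direction to
k = 0 without materially biasing genuine notch fits.

Fit quality is `r² = 1 − SS_res/SS_tot` per window plus overall, with the
sample SD of residuals; a constant observed window has undefined r² and
returns NaN.  Fits that fail to converge, stick at bounds, or score
r² < 0.5 are flagged and masked out of downstream tensors.

## Segmentation

The delineator is deliberately transparent and rule-based (an external
detector can be substituted by supplying `FiducialPoints` directly).
R peaks: 20 ms moving average (nulls 50 Hz mains), squared-derivative
energy integrated over 30 ms, peaks ≥ 25% of maximum with a 200 ms
refractory period, refined to the local raw maximum.  QRS onset / J point:
first/last crossing of 10% of the maximum absolute derivative within
±80 ms of the R peak, QRS clamped to ≤ 200 ms.  T onset: J + 40 ms.
T end: tangent at the steepest descent of the T limb intersected with the
PQ baseline (median of the 40 ms before QRS onset), QT clamped to
≤ 600 ms.  ST level: mean over [J+60, J+80] ms minus the PQ baseline.
Out-of-order or missing landmarks flag the beat unusable; fiducials only
set fit windows and initial values, so landmark error at this scale does
not propagate into the decomposition (verified end-to-end in the tests).

Leads with a net-negative QRS are fitted after sign inversion and flagged;
the canonical model assumes a positive main deflection (lead II / V5-like
projections).

## Synthetic data

The generator produces records from the forward model itself, so every
test has exact ground truth.  Defaults represent a healthy lead-II
recording: population-mean parameters, 1000 Hz, RRI 820 ± 20 ms, no noise
or drift.  Model-implied fiducials use envelope rules: QRS onset at
μRp − 3σRp, J at μRn + 3σRn, T onset at μTn − 3σTn (clamped past J), and
T end at μTp + (√(2π)/2)σTp ≈ μTp + 1.25σTp — the point where the tangent
at the steepest anodic descent meets its asymptote, i.e. the model-side
analogue of the clinical tangent T end (a Gaussian tail has no finite
endpoint; the 1.25σ convention reproduces the printed QT of the
early-repolarisation case to ~2 ms, where 2σ or 3σ conventions overshoot
by 20–50 ms).

Scenarios: *ischemia* ramps σTn 60 → 104 ms over 50 beats, with an ST
depression (kRn + 0.1 mV) and QT prolongation arriving only later —
early-repolarisation-spread drift preceding conventional signs, as during
coronary occlusion; *ers* replays the published 10-beat-block parameter
sequence of the early-repolarisation case with beat-to-beat σTn alternans
(± 6 ms) superimposed in its peri-fibrillation sections.  The ischemia
scenario also carries within-subject beat-to-beat jitter (σTn ± 1.3 ms,
intervals ± 3 ms, weights ± 0.015 mV) sized from the row-to-row spread of
the published case blocks; this gives ST and QT their physiologic
beat-to-beat wander, without which any reference window is unrealistically
quiet.

What the generator does *not* emulate: P waves, QRS notching outside the
extended-mode fixtures, respiratory baseline modulation of amplitudes,
QT–RR rate adaptation, electrode artefacts, and non-Gaussian noise.
Passing round-trip tests therefore demonstrate estimator correctness under
the model's own assumptions, not clinical validity on real recordings.

## Tensor and anomaly scoring

The parameter tensor is a plain 4-way container, beat × lead ×
component (Rp, Rn, Tp, Tn) × metric (μ, σ, k); β and the derived intervals
live in companion arrays rather than on the metric axis.  Masked
(non-converged) beats propagate as missing and are never interpolated —
interpolation would fabricate beats for downstream distance scoring.
Per-participant style averages exclude masked beats.  The tabular CSV form
round-trips losslessly, masked cells serialising as empty.

Threshold rules ship with the case-derived defaults (σTp 45/35 ms,
σTn 80/70 ms).  They were set on a single intervention case, not
calibrated on a population, and are configurable.

Mahalanobis scoring: a reference beat window supplies mean and sample
covariance of a chosen parameter set; each beat's distance
`sqrt((x−m)ᵀ S⁻¹ (x−m))` is reported (the distance, not its square, for
interpretability).  The window must contain at least max(10, 2·dim) usable
beats.  σTn/σTp are highly correlated, so when the covariance condition
number exceeds 1e8 a ridge `1e−6 · trace/dim` is added (with an absolute
floor for all-constant references).  Parameters are used on their raw
scale; with an exact covariance the distance is affine-invariant, so
standardisation would only matter through the regulariser.  Reference and
target windows are explicit user input — each intervention segment is
scored against its own preceding quiet period; no change-point detection
is attempted.

## Numerical and scope choices

- Units are mV and ms throughout; WFDB gain/baseline honoured on read.
- The WFDB codec is a deliberately small hand-written subset (text header
  + format-16 int16 signal, single segment); CSV carries
  `# fs=... units=mV` metadata, and a record with unknown units or an
  underivable sampling rate is rejected, never guessed.
- All randomness flows through explicitly passed seeded generators; no
  global RNG state.
- No pre-filtering before fitting: the decomposition itself acts as the
  denoiser.  Optional baseline handling is limited to the PQ-median
  subtraction inside ST measurement.
- Test and example problem sizes (tens to a couple of hundred beats, one
  lead) are chosen to exercise every code path at interactive runtimes;
  the estimators are O(n) in samples per beat and trivially parallel over
  beats.

## Known limitations

- Whether the fitted transition statistics match true transmembrane AP
  timing is untestable from surface ECG alone; the package validates
  round-trip estimator behaviour, not electrophysiologic truth.
- The tangent T end on a composite limb with a very wide cathodic spread
  (σTn ≳ 90 ms) lands ~20 ms early; the decomposition, not the
  delineator, is the measurement of record for repolarisation timing.
- Conduction disturbances, extrasystoles and paced rhythms violate the
  point-process premise; such beats should be excluded upstream.
- The bulk plateau constraint trades a small timing distortion for
  stability; where bulk and separate modes disagree materially, the
  separate result is the more faithful one.
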