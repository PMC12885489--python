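# Methods

This note documents the models, estimators and numerical choices behind
`oscivar`, in the spirit of a statistical package's methods appendix.  It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## 1. Measurement model

Each recording emulates a 2-minute home oscillometry session: a 5 Hz
sinusoidal pressure forcing of amplitude A = 1.5 cmH₂O (typical clinical
practice; single-frequency to maximise signal-to-noise) superimposed on
spontaneous tidal breathing, sampled at 200 Hz (ample for a 5 Hz forcing;
typical for commercial devices).  The respiratory system is a single
compartment with instantaneous resistance R(t), elastance E and inertance I,
so the input impedance at the forcing angular frequency ω₀ = 2π·5 is

    Z(t) = R(t) + i X,   X = ω₀ I − E/ω₀ .

With the defaults E = 10 cmH₂O·L⁻¹ and I = 0.01 cmH₂O·s²·L⁻¹,
X ≈ −0.004 cmH₂O·s·L⁻¹ — small but non-zero, so the resistance estimator
must genuinely separate the real from the imaginary part rather than take a
magnitude.  Measured signals (inspiratory flow positive):

* flow = tidal flow + oscillatory flow, where tidal flow is a sinusoid
  scaled to the tidal volume (0.5 L, breath period 4 s by default) and
  oscillatory flow is A·|Z(t)|⁻¹·sin(ω₀t − θ(t)), θ = atan2(X, R(t));
* pressure = A·sin(ω₀t) + E·volume + R(t)·tidal flow + white noise
  (SD 0.01 cmH₂O; 0.002 L/s on flow).

### Within-breath resistance profile

R(t) = (daily level) × (per-breath factor) × (intra-breath modulation).
The per-breath factor is 1 + N(0, breath_cv), breath_cv = 0.08 by default
(a plausible breath-to-breath noise level, exposed as a knob — published
within-day statistics to pin it down are scarce).  The intra-breath
modulation encodes the two mechanisms that motivate mid-inspiratory
sampling:

* an **early-inspiratory surcharge** — a fractional elevation at
  inspiration onset decaying linearly to zero over the first 20 % of
  inspiration (airway re-opening, volume history);
* an **expiratory surcharge** — a constant fractional elevation throughout
  expiration (dynamic compression, expiratory flow limitation).

Defaults (early, expiratory): asthma (0.15, 0.25), healthy (0.05, 0.10),
COPD (0.25, 0.60) — largest in COPD, where flow limitation dominates.  The
central 20–80 % of inspiration is left unmodulated by construction, which is
exactly why the mid-inspiratory scheme recovers the clean daily level.

### Between-subject and between-day variation

Subjects are drawn from group-level truncated normal distributions
calibrated to the three study groups: baseline mid-inspiratory resistance
(mean ± SD, cmH₂O·s·L⁻¹) 3.72 ± 1.03 (asthma), 2.59 ± 0.50 (healthy),
5.08 ± 1.09 (COPD), floored at 0.5; true day-to-day CV 0.14 ± 0.05,
0.07 ± 0.02, 0.09 ± 0.04 respectively, floored at 0.005.  Daily resistance
levels are independent lognormal draws with median R_base and
σ_log = √ln(1 + day_cv²), which makes the population CV of the daily level
*exactly* day_cv (resistance is positive and right-skewed, making the
lognormal the natural choice).  Days are independent; no autocorrelation is
modelled, since no empirical autocorrelation information was available to
calibrate one.  This is a known limitation: real day series may carry slow
trends (treatment, season) that the generator does not emulate.

Adherence: each scheduled day yields a recording with probability 0.9 per
subject by default (home-monitoring adherence is typically >80 %); the
acceptance experiments use full adherence so that recovery error is not
confounded with missingness.

### Artifacts

`inject_artifacts` corrupts randomly selected breaths with one of three
failure modes observed in unsupervised home measurements: a ±5 L/s transient
flow spike (cough/swallow), an 85 % collapse of the oscillatory pressure
component (mouthpiece leak), or hard flow clipping at 15 % of the breath
peak.  All randomness (hit mask, artifact kinds, spike parameters) is drawn
up front, so on a fixed seed the corrupted set grows monotonically with the
rate — and so does the number of rejected breaths downstream.

## 2. Signal processing

**Component separation.**  Breathing flow is a zero-phase low-pass of the
measured flow (cutoff 2 Hz); the oscillatory pressure and flow are zero-phase
band-passes (2–8 Hz).  Filtering is done spectrally with raised-cosine
transition bands (1 Hz wide at the low edges, 2 Hz at the high edge): the
response is exactly zero-phase on both channels — any inter-channel group
delay would bias the reactance — and for recordings spanning whole numbers
of forcing cycles the separation has no start-up transient, unlike
forward–backward IIR filtering.  For signals that are not exactly periodic
over the record the usual spectral-leakage caveat applies at the very edges.

**Impedance estimation.**  In sliding windows of one forcing cycle (0.2 s,
hop one cycle), both channels are least-squares projected onto
{cos ω₀t, sin ω₀t}; the complex ratio of the fitted phasors gives Z, with
R = Re Z and X = Im Z.  On uniformly sampled integer-cycle windows this
projection is identical to the single-bin DFT (the test suite verifies
agreement to 1e-9 and exactness to <1e-6 relative on constant-impedance
signals).  Windows whose oscillatory flow amplitude falls below 0.02 L/s are
flagged low-quality and withheld — the ratio is numerically meaningless
there.

**Breath segmentation.**  Breaths are delimited by negative→positive zero
crossings of the breathing flow with hysteresis: a crossing counts only if
the flow swings past ±5 % of the recording's flow amplitude within 0.2 s on
both sides (a crossing at the very first sample is admitted when the signal
starts near zero and rises, so a recording beginning at inspiration onset
keeps its first breath).  Breaths with duration outside [1.5, 15] s or
inspiratory fraction outside [0.2, 0.8] are rejected with a reason code.
The device's proprietary segmentation is unknown; hysteresis zero-crossing
is the standard transparent choice.

**Artifact rejection.**  A breath is rejected if any of: |flow| > 3 L/s
(spike); median oscillatory-pressure amplitude within the breath < 50 % of
the recording median (leak); any windowed R ≤ 0 or > 20 cmH₂O·s·L⁻¹
(non-physical); more than 20 % low-quality windows.  These thresholds are
package inventions designed to reproduce a realistic few-percent discard
rate on clean data while catching injected artifacts; all live in
`ProcessingConfig`.

**Intra-breath sampling.**  Per accepted breath, R is averaged over windows
whose centres fall in the full breath, the full inspiration, or the central
20–80 % of the *inspiratory time* (mid-inspiration).  Time fraction rather
than inspired-volume fraction is used because the volume criterion is not
well defined for every breath and the time criterion is; a volume-based
variant would require integrating flow with drift correction and is out of
scope.  Each scheme needs ≥2 good windows, else its value is missing.

## 3. Variability analysis

The daily value is the mean of the scheme's per-breath resistances over
accepted breaths, missing when fewer than 3 breaths survive.  Subjects
providing <70 % of scheduled recordings are excluded (the adherence
retention rule).  CVR at time scale n is computed in every sliding window of
n consecutive scheduled days holding at least min(n, max(3,
⌈(10/14)·n⌉)) present values (windows below the floor are skipped, never
imputed; the cap at n keeps the shortest scales computable); within a window
CVR = (sample SD, n−1 denominator) / mean, and the subject's value at that
scale averages CVR, SDR and meanR over eligible windows.  At the maximal
scale this reduces to the single-window two-week CVR with the ≥10-points
rule.  Averaging over all sliding windows (rather than using only the first
n days) uses all collected data; both conventions give identical results at
the full scale.  CVR is invariant under positive rescaling of the series —
the formal counterpart of "variability is not obstruction".

Estimator note: the sample CV at n = 14 underestimates the population CV by
roughly 2 % (the usual small-sample SD bias); the end-to-end recovery
tolerances absorb this known bias rather than correcting it, since the
clinical quantity is itself the uncorrected sample CV.

## 4. Diagnostic evaluation

* **AUC** is the rank-based Mann–Whitney estimate of P(asthma score >
  non-asthma score), ties counted ½, with a seeded 2000-resample bootstrap
  percentile CI.
* **AUC vs time scale** is fitted with the 3-parameter saturating
  exponential AUC(t) = A_plateau − (A_plateau − A0)·e^(−t/τ) (initialised at
  A_plateau = max AUC, A0 = first AUC, τ = span/3; τ bounded in (0, 10·span]);
  the minimum observation period is ⌈5τ⌉ days.  A 2-parameter form (fixing
  A0) was considered and rejected: the extrapolated scale-0 value is not
  knowable a priori.
* **Cutoff**: stratified 5-fold cross-validation; per fold the threshold
  maximising Youden's J = sensitivity + specificity − 1 on the training
  portion (candidates are midpoints between adjacent distinct scores plus
  ±∞; ties broken toward the smallest threshold, favouring sensitivity) is
  evaluated on the held-out portion.  Both the fold-averaged held-out
  performance and the pooled confusion matrix at the mean cutoff are
  reported — they answer slightly different questions and need not agree.
* **CIs**: Wilson for sensitivity/specificity; log-normal with Haldane 0.5
  correction for the diagnostic odds ratio; t-interval across folds for the
  cutoff.

## 5. Reproducibility and problem sizes

All randomness flows from one root seed through `numpy.random.SeedSequence`
spawning (per subject, then per day), so cohorts, reports and CLI outputs
are bit-reproducible; every output embeds the seed and a configuration hash.

The packaged experiments use 20 subjects per group × 14 daily 2-minute
recordings × 5 seeds for end-to-end recovery, and 200 replicates for the
group-normal AUC simulation — sizes at which the group-mean sampling error
(SE ≈ day_cv_SD/√100 ≈ 0.005 for the asthma CVR) sits comfortably inside
the 10 % recovery tolerance while a full run stays around a minute.

## 6. What passing tests do and do not show

The generator reproduces the *statistical structure* reported for the three
groups (group means/SDs of mid-inspiratory meanR and CVR, SD–mean coupling,
adherence, artifact prevalence) and the physical structure of the signals
(impedance at 5 Hz, spectral separation of breathing and forcing,
intra-breath phase effects).  It does not emulate: day-to-day
autocorrelation, exacerbations, medication effects, upper-airway shunt,
nonlinear mechanics, multi-frequency forcing, or device-specific artifact
morphologies.  End-to-end recovery therefore shows that the pipeline is an
accurate and unbiased estimator *under the stated model*, and that the
diagnostic machinery reproduces the published discrimination when fed the
published group statistics — not that the clinical effect sizes themselves
are re-derived from raw clinical data.
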