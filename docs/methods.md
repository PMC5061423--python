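# Methods

This note documents the models, parameter choices, and numerical
conventions behind the package, and what the synthetic validation does
and does not establish about real recordings.

## Time and sampling conventions

Timestamps are seconds (float) from session start. Every window and
bin is half-open `[t, t + w)`. The common analysis grid is 10 Hz; EEG
stays at its native 256 Hz; blink strength is native 128 Hz (stored on
disk binned to the grid by per-bin maximum, which preserves pulse
peaks); inter-beat intervals are an event series — each sample is the
RR interval *ending* at its timestamp, the moment it becomes
observable. Missing samples are explicit NaNs and are never
interpolated except through an explicitly chosen resampling method
(`hold`, `linear`, or `bin_mean`).

## Synthetic cohort: what it emulates

The generator produces the stimulus-response structure the analyses
assume, with every stream seeded through a `SeedSequence` keyed on
(seed, participant, trial, loop, channel), so identical configurations
are bit-identical.

**Stressor schedule.** Sessions default to 300 s with 8 non-overlapping
events of 5–10 s, ≥ 12 s apart, intensities 0.5–1 — roughly 20% of the
session under stressor, the coverage of corridor-section-like
stressors during a ride. Placement is exact stick-breaking, so
feasible packings never fail.

**Electrodermal activity.** Tonic level = per-participant baseline
(3–8 µS) plus three very slow sinusoidal drifts (~0.1 µS total;
bounded slope, so a noiseless rest trace yields zero slope events).
Each stressor adds a phasic response: the classic
difference-of-exponentials SCR kernel (rise τ = 0.75 s, decay τ = 4 s)
*convolved with the event window* — a sustained stressor sustains its
response, so the rising phase tracks the stressor duration rather than
the kernel's fixed rise time. Amplitude = 1.0 µS · intensity ·
habituation; onset lags the stimulus by 2.0 s; sensor noise SD
0.005 µS at 10 Hz.

**Inter-beat intervals.** Instantaneous IBI = baseline (0.7–1.0 s) ·
(1 + 0.02·sin 2π·0.1t + 0.02·sin 2π·0.3t) — LF and HF modulation at a
modest seated-task depth (SDNN ≈ 17 ms) — minus an event-locked drop
of 0.12 s · intensity (≈ +10 bpm) using the same sustained kernel,
lagged 6.5 s. Beats fire by integrate-and-fire; each RR reflects the
instantaneous IBI at its interval midpoint (one fixed-point pass) and
is stamped at its ending beat. Parameters driving IBI below 0.3 s are
rejected as non-physiological.

**EEG.** Each channel is 1/f background noise (RMS 25 µV) plus 10 Hz
alpha (10 µV). Stressor state modulates alpha in two ways: a bilateral
suppression (factor 1 − 0.2·state — arousal-related alpha blocking)
and a hemispheric shift (± 0.5·state/2: right up, left down); left
channels additionally gain an 18 Hz beta bump. Hemisphere differences
cancel the bilateral suppression, which is why all-channel alpha-ratio
features carry strictly more stressor information than left-minus-right
differences. The central response has no lag, but its stressor
modulation habituates with exposure like the autonomic channels.

**Blinks, lever, joystick, meditation.** Blinks are Poisson pulses
(base 0.25 Hz, rate ×(1+intensity) inside windows lagged 4.65 s,
raised-cosine pulses peaking 100–255, 0.25 s refractory). The lever is
intensity·valence inside event windows, smoothed 0.5 s. The joystick
is slow sinusoidal steering plus white jitter whose SD grows from 0.01
to 0.16 under stressor state. Meditation is 100·(1 − smoothed arousal)
at 1 Hz; the 4 s smoothing span mimics a consumer relaxation score's
sluggishness while keeping each stressor window visible.

**Habituation** multiplies all stressor-response amplitudes (GSR, IBI
drop, blink-rate gain, EEG modulation) by `habituation_rate^exposure`,
exposure incrementing over trials and loops. Default 0.8; the
magnitude of real habituation is not well constrained, so this is a
documented free parameter.

**What the generator does not emulate:** movement and ocular
artifacts, electrode drift and detachment, respiration–HRV coupling,
non-stationary blink styles, individual EEG spectra beyond 1/f+alpha,
or any vehicle dynamics. Passing tests therefore demonstrate that the
*analysis* recovers the structure it targets when that structure is
present at realistic signal-to-noise — not that real recordings
contain it.

## Characterizations

**LF/HF.** Per 20 s window the beat-wise RRs are linearly resampled to
4 Hz (spectral HRV requires uniform sampling), linearly detrended, and
Welch-analysed with a Hamming taper. The segment defaults to the full
window: a 20 s window is already at the resolution floor of the
0.04–0.15 Hz band — splitting it in two widens the mainlobe to 0.2 Hz
and leaks a pure 0.1 Hz tone into the HF band (measured LF/HF ≈ 3 on a
pure LF tone, vs ≈ 16 with the full-window taper). Longer windows are
averaged over overlapping segments. Band powers are trapezoid
integrals with the PSD interpolated at the exact band edges, so the
shared 0.15 Hz boundary contributes half-weight to each band. Windows
with < 2 beats or vanishing HF power are NaN-flagged.

**Tonic SCL** is a 30 s running median: the median rejects phasic
responses much shorter than the window, which a running mean would
smear into the baseline.

**Square-wave slope encoder.** The signal is smoothed by a centered
running mean (1 s for GSR; 0.1 s for the 128 Hz blink-rate proxy,
skipped when the stream is already coarser), the first-difference
slope is thresholded at k·1.4826·MAD(slope) with k = 3, candidate runs
closer than 0.3 s are merged, runs shorter than 0.5 s dropped, and
each surviving run becomes a rectangle (width = run duration, height =
peak amplitude inside the run). The MAD threshold makes detection
invariant to offsets and equivariant to positive scaling; for sparse
pulse trains whose slope MAD collapses to zero the plain SD is the
fallback scale.

**medianRRI** is the reciprocal of the median RR in a centered 5 s
window stepping at 0.1 s: reciprocal-of-median rather than a filtered
instantaneous rate, so a single ectopic-like RR cannot flip the value,
and the sign convention makes higher = more aroused. The 5 s width
tracks the ~6.5 s cardiac lag without oversmoothing.

**Alpha asymmetry** uses rectangular-window periodograms on 2 s
sliding windows (0.1 s step): power integrated over 8–13 Hz, averaged
over each hemisphere's three channels, right minus left. The
rectangular window keeps the estimate exactly checkable against a
direct-DFT oracle.

## Labels and classification

Characterizations are min-max normalized per participant-session
(Meditation keeps its native 0–100 scale against the fixed cutoff 50).
Interval means above the cutoff are labelled 2 (absence of a
stressor), below 1 (presence); ties go to 1 and trailing partial
intervals are dropped. Cutoffs: mean of the series for GSRsiginc,
GSRSCL and Joystick R², median for medianRRI, fixed 50 for Meditation.
Note the rule's polarity is uniform: for arousal-positive sources
(GSRsiginc, medianRRI, GSRSCL) event-dominated intervals land on the
">" side, i.e. label 2 — the label is a binary partition and the
classifier is indifferent to which class name marks arousal.

EEG for classification is zero-phase band-passed 3–50 Hz (5th-order
Butterworth, forward-backward), linearly detrended per segment,
epoched on the interval grid, and baseline-corrected by each epoch's
first-second mean. Features are periodogram power ratios
(8–13 Hz)/(4–30 Hz) per channel, or the three left-minus-right
differences of those ratios. Cross-validation is stratified 10-fold
(folds shrink if a class has < 10 members) with a fixed seed; LDA,
linear SVM (C = 1), and logistic regression (C = 1000, effectively
unregularized) share the same folds. Accuracy is the reported metric;
labels are imbalanced (~4:1 toward absence-of-event intervals under
the default schedule) and are not rebalanced, so the chance level used
in calibration checks is the pooled majority-class rate, not 50%.

## Correlation map

Spearman ρ is rank-based, so the Box-Cox transform (strictly monotone)
cannot change it; the transform is kept because the documented
procedure applies it before correlating, and it matters for the KS
normality screen. λ = "mle" maximizes the Box-Cox profile
log-likelihood on a 601-point grid over [−3, 3]; nonpositive inputs
are shifted (recorded in the returned parameters). p-values use the
t-approximation for n > 30 and a seeded permutation test for small
samples. Significance (p < 0.001 and |ρ| > 0.5) is applied to |ρ|, so
strong negative couplings (e.g. SCL–Meditation) qualify. Per-pair lags
— estimated by rank cross-correlation within ±10 s when `lags="auto"`
— are applied before correlating, compensating the 2/4.65/6.5 s
channel delays.

A useful calibration point: a square-wave series active a fraction
p of the time has a rank-correlation ceiling of about √(3p(1−p))
(≈ 0.69 at p = 0.2) against any continuous series, so ρ ≈ 0.6 between
GSRsiginc and a continuous characterization is near-ceiling coupling,
not a weak effect.

## EEG time-frequency counting

Band-power variances are standardized *across the six channels within
each dataset* (population SD, matching |z| = |(r − r̄)/std(r)|), and a
channel is counted for a dataset when the z-rule holds; counts
accumulate over datasets per condition and band. Standardizing each
channel against its own across-dataset distribution would remove
between-channel differences by construction and no hemispheric pattern
could ever emerge; the within-dataset axis is therefore the default,
with `axis="datasets"` available. The counting rule defaults to
|z| ≥ 2 (significantly *large* variances); because the printed
convention in this literature is ambiguous, `z_rule="lt2"` (its
complement) is selectable.

## Delay-recovery diagnostics

Three estimators serve ground-truth recoverability checks:
`estimate_delay` (rank cross-correlation; exact for injected shifts,
recovers 2.0/4.65/6.5 s within ±0.05 s at 10 Hz),
`estimate_response_delay` (matched filter against the sustained
response template; unbiased for kernel-shaped responses, ±0.05 s for
GSR and ±0.1 s for the cardiac channel via the midpoint tachogram),
and `estimate_rate_step_delay` (pooled count-difference for point
processes). The blink channel is a 0.25 Hz Poisson process: one event
window adds roughly one extra blink, so its delay carries an
irreducible ~0.3–0.4 s timing uncertainty even pooling tens of
sessions — blink-delay recovery is asserted at ±0.5 s, the information
limit, not at the ±0.2 s the continuous channels support.

## Problem sizes

Validation runs use 300 s sessions; cohort-scale checks use 15
participants for the correlation map, 6–8 for classification and
habituation, 20 sessions for event-recovery F1, and 100 seeds for the
correlation null — sizes at which every measured quantity is stable
across seeds while the full suite and the acceptance script each
complete in well under their runtime budgets on a single CPU.

## Known limitations

* The pipeline assumes stressors are time-limited and non-overlapping;
  sustained anxiety states without event structure would appear only
  in the long-term characterizations.
* LF/HF from 20 s windows is at the spectral resolution floor of the
  LF band; values are comparative indices, not precise sympathovagal
  ratios.
* The square-wave encoder detects slope *increases* only; response
  offsets/decays are not encoded, which bounds its rank correlation
  with symmetric-response channels.
* Classification accuracy under label imbalance should be read against
  the majority-class rate; per-class recall is logged but not
  optimized.
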