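# stressense

Multimodal physiological stressor detection for mobility-assistance
research: a tested pipeline that turns raw wearable-sensor streams —
skin conductance (GSR), inter-beat intervals (IBI), blink strength,
six-channel EEG (F3, FC3, C3, F4, FC4, C4), a continuous self-report
lever, and joystick traces — into time-scale-organized emotional-state
characterizations, correlation maps, EEG time-frequency summaries, and
cross-validated stressor-presence classifiers.

The package is aimed at researchers studying affective responses of
vehicle or powered-wheelchair users, where sudden, time-limited
stressors (a narrow corridor, an unexpected maneuver) drive transient
sympathetic arousal. Because such recordings are hard to share, the
package includes a first-class synthetic cohort generator that embeds
the exact stimulus-response structure the analyses assume, so every
stage can be validated against known ground truth.

## The analysis in brief

**Characterizations** are organized by time scale. Long-term (slow
state changes): `Blinkcount` (blink events per 2 s bin), `GSRSCL`
(tonic skin-conductance level, 30 s running median), `LFHF` (Welch
spectral ratio of IBI power in 0.04–0.15 Hz over 0.15–0.4 Hz per 20 s
window, Hamming-tapered), and the `Meditation` relaxation score.
Short-term (moment-to-moment): `GSRsiginc` and `Blinksiginc` encode
runs of significant slope increase (slope > k·1.4826·MAD of the slope,
k = 3) as square waves whose width is the run duration and height the
peak amplitude; `medianRRI` is the reciprocal of the windowed median
RR interval (higher = more aroused); `alphaAsym` is right-minus-left
hemispheric alpha (8–13 Hz) power.

**Correlation mapping** screens each series with a one-sample
Kolmogorov–Smirnov normality test, applies the one-parameter Box-Cox
transform yₜ = (y^λ − 1)/λ (log for λ = 0) to skewed series, and
computes pairwise Spearman ρ with per-pair lag compensation. Edges are
significant at p < 0.001 and |ρ| > 0.5, tiered as *primary* (touching
the evaluation-lever reference) or *secondary* (between two nodes each
linked to the reference). Physiological delays behind the lever —
GSR ≈ 2 s, heart ≈ 6.5 s, blink ≈ 4.65 s — are estimated by lagged
rank cross-correlation.

**EEG time-frequency** band-passes 8–25 Hz, builds a 0.1 Hz-resolution
spectrogram, condenses it into α1 (8–12 Hz), α2 (13–15 Hz) and β
(16–20 Hz) band-power series, and counts significantly activated
channels per condition and band via standardized z-scores of the
band-power variances.

**Classification** labels fixed stressor-intervals (2/4/5 s) as
presence (1) or absence (2) of a stressor by comparing each interval's
mean of a preprocessed characterization to a per-source cutoff, then
classifies 3–50 Hz band-passed EEG epochs with alpha-ratio features
(power 8–13 Hz ÷ power 4–30 Hz, per channel or as left-minus-right
differences) under stratified 10-fold LDA / linear SVM / logistic
regression.

## Worked example

Simulate one rider session, detect phasic skin-conductance events, and
map the short-term correlations against the self-report lever:

```python
import numpy as np
from stressense.synth import SimConfig, simulate_cohort
from stressense.shortterm import gsr_siginc, median_rri
from stressense.behavior import lever_preprocess
from stressense.corrmap import spearman_map
from stressense.series import ParameterSeries

cfg = SimConfig(n_participants=1, trials=1, loops=1, seed=7,
                session_duration=300.0)
session = simulate_cohort(cfg)[0]

sw = gsr_siginc(session["gsr"])          # square-wave SCR events
enc = sw.grid_encoding()
t = enc.timestamps
mrri = median_rri(session["ibi_event"], t_end=t[-1] + 0.1)
lever = lever_preprocess(session["lever"])
n = min(len(enc), len(mrri), len(lever))
series = {name: ParameterSeries(name, t[:n], s.values[:n])
          for name, s in [("GSRsiginc", enc), ("medianRRI", mrri),
                          ("lever", lever)]}
cm = spearman_map(series, reference="lever", lags="auto")

print(f"{len(sw)} SCR events detected "
      f"(schedule has {len(session.schedule.events)})")
for e in cm.edges:
    print(f"{e.a:>9s} - {e.b:<9s} rho={e.rho:+.2f}  lag={e.lag_s:+.1f}s  "
          f"p={e.p:.1e}  tier={e.tier}")
```

Output:

```
8 SCR events detected (schedule has 8)
GSRsiginc - medianRRI rho=+0.58  lag=+8.4s  p=2.7e-266  tier=secondary
GSRsiginc - lever     rho=+0.89  lag=-1.9s  p=0.0e+00  tier=primary
medianRRI - lever     rho=+0.66  lag=-10.0s  p=0.0e+00  tier=primary
```

Every simulated stressor produced a detected skin-conductance event;
the square-wave characterization correlates strongly with the
self-report lever (ρ = 0.89, primary edge; the −1.9 s lag is the GSR
channel trailing the lever by ~2 s), and the cardiac characterization
joins the map both directly and as a secondary edge through the
GSR–heart link.

The same stages are scriptable from the shell:

```bash
stressense simulate --out cohort/ --seed 7
stressense characterize --in cohort/ --participant P01 \
    --modality autonomous --condition wide --out P01.csv
stressense correlate --in P01.csv --set short --reference lever --out map.json
stressense run --config pipeline.yaml --out results/
```

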