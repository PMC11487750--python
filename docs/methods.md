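# Methods

## Overview

`swapet` models the association between non-REM slow-wave activity (SWA)
features of a split-night diagnostic polysomnogram and annualized amyloid
accumulation from two longitudinal PiB-PET scans.  The pipeline has four
stages: (1) PSG I/O and epoching, (2) slow-wave feature extraction
(relative band powers and half-wave downslopes), (3) PET aggregation,
annualization and centiloid scaling, (4) linear association models.  A
synthetic generator supplies recordings and cohorts with analytic ground
truth for every stage.

## Signal conditioning

EEG is analysed in µV on two derivations: Fz-Cz for spectral features and
Fz referenced to the earlobe average (A1+A2)/2 for slow-wave detection.
Both are bandpassed 0.5–35 Hz with a 2000-tap linear-phase FIR designed by
the Hamming-window method and applied forward–backward (`filtfilt`), which
realizes zero net phase shift at the cost of squaring the magnitude
response; a single-pass mode with group-delay compensation is selectable.
Recordings at other sampling rates are polyphase-resampled to 500 Hz, where
the 2000-tap filter and the 25-sample smoother are defined.

**Transition-band behaviour (important).**  With 2000 taps at 500 Hz the
Hamming design has a transition width of ≈0.83 Hz around each edge.  The
slow-oscillation band (0.5–0.9 Hz) therefore overlaps the lower transition
band: the forward–backward amplitude gain is ≈0.25 at 0.5 Hz, ≈0.75 at
0.7 Hz and ≈0.99 at 0.9 Hz.  This is a property of the stated filter, not
of the detector: a continuous 0.7 Hz train emerges with ~75% of its
amplitude (and downslope), and isolated 0.7 Hz transients are additionally
shape-distorted because their sub-0.5 Hz spectral content is removed.  The
package quantifies this with the closed-form frequency response
(`spectral.filter_gain`), and a test asserts that the full-chain measured
downslope of a continuous slow-oscillation train equals the analytic
4·A·f scaled by that gain.  Consequences: (i) oracle tests of the
*detector* feed it band-limited signals directly (the conditioning chain is
conceptually the identity for ideal in-band input); (ii) comparisons of the
*full chain* against ground truth use filter-aware expectations; (iii) on
real data, SO-band quantities are systematically attenuated relative to an
ideal filter — a constant of the measurement definition that cancels in
between-subject comparisons using the same pipeline.

## Spectral features

Per 30-s epoch, band powers are Welch estimates on the filtered Fz-Cz
signal (filtering runs on the continuous record first; windowing afterwards
avoids per-epoch edge transients).  Seven closed bands are used: SO
0.5–0.9, delta 1–3.9, theta 4–7.9, alpha 8–11.9, sigma 12–14.9, beta
15–29.9, low gamma 30–35 Hz; gap frequencies (e.g. 0.9–1.0 Hz) belong to no
band.  Relative power is each band's share of the seven-band total (×100).

**Welch segmentation.**  Default: 10-s Hamming segments with 50% overlap
(five segments per epoch, 0.1 Hz resolution).  The band edges are printed
at 0.1 Hz precision and all fall exactly on this frequency grid, and the
0.4-Hz-wide SO band can contain an in-band tone's full spectral mainlobe.
The more common 4-s segmentation (0.25 Hz resolution) is available via
parameter but leaves the SO band only two bins wide: even an on-bin SO tone
then leaks ~13% of its power into delta, so the 10-s default is the one
under which the analytic two-tone oracles hold to better than 0.1
percentage points.  A single-taper periodogram over the full epoch is also
selectable.

Summaries are unweighted means over eligible (non-artifact) epochs of a
study portion: over all NREM (N1–N3) epochs, or over N3 only, the latter
requiring at least 30 N3 epochs (15 min) and otherwise reported missing
with reason `insufficient N3`.

## Slow-wave detection

On the smoothed (50-ms moving average, shrinking at edges), filtered
Fz–earlobe signal, zero-crossings are located with linear interpolation of
the crossing instant (avoiding 2-ms quantization of slope denominators at
500 Hz).  A candidate wave is bounded by successive *descending*
(positive-to-negative) crossings; the separation — one full wave period —
classifies it: 1.1–2 s (0.5–0.91 Hz) as SO, 0.25–1.0 s (1–4 Hz) as delta.
A literal mode classifying by the negative half-wave's own crossing
separation exists, but 1.1–2 s half-waves correspond to 0.25–0.45 Hz full
waves, inconsistent with the SO band, so the period criterion is the
default.  The trough is the global minimum between the bounding crossings
(earliest sample on ties) and must reach −5 µV on the smoothed signal; the
downslope is |trough|/(t_trough − t_crossing), stored as a positive
magnitude.  Waves straddling an epoch boundary belong to the epoch holding
the trough.  Summaries average per band within each 30-s epoch and then
across NREM epochs with at least one detection (mean of epoch means;
detection-weighted pooling is selectable).

## PET quantities

Global SUVR is the (optionally weighted) mean over six amyloid-susceptible
ROIs: orbitofrontal, pre-frontal, anterior/mid-cingulate, posterior
cingulate/precuneus, parietal, temporal.  ROI weights are accepted as data
and default to equal, since volume weights are subject-specific inputs.
Annualized accumulation is (ln S₂ − ln S₁)/Δt (natural log, Δt in years),
identical per ROI.  The centiloid scale is the affine map
CL = 100·((−0.1620 + 0.9467·S) − 1.009)/1.067 — the bracketing is resolved
so that the cohort's median baseline SUVR of 1.44 maps to the printed
median of 18 CL (strictly increasing maps commute with odd-sample
medians).  The CL-scale rate is the difference of converted values per
year, not a conversion of the log rate.  Baseline positivity: SUVR ≥ 1.48,
inclusive.

## Association models

`SlowWaveAmyloidModel(data, outcome, exposures, covariates)` fits OLS with
intercept and classical (non-robust) standard errors; t-based 95% CIs;
per-term VIFs computed by auxiliary regressions.  Exposures are
standardized to sample-SD units (n−1 denominator) so coefficients read
"per 1 SD of feature"; covariates enter untransformed.  Backward
elimination drops the removable term with the largest p-value while it
exceeds 0.1 (the single-term partial-F p equals the t-test p); exposures
are always forced in, because reported exposure effects come from
parsimonious models that retain them.  Subgroup analyses are plain refits
on the amyloid-positive and -negative strata without interaction terms.
Paired diagnostic-vs-titration comparisons use the paired t-test with
Cohen's d = mean(diff)/SD(diff); SD(diff)² = s_a² + s_b² − 2·r·s_a·s_b, the
between-condition SD adjusted by the correlation between measures, which is
also how printed effect sizes are reconstructed from a mean difference and
its CI.  Predictions at feature quantiles evaluate the linear predictor at
the feature's sample quantiles with other terms held at a stated covariate
profile (defaulting to sample means).  No multiple-testing correction is
applied by default, matching the exploratory design; a Benjamini–Hochberg
adjustment can be applied downstream on the tidy coefficient table.

## Synthetic data

**Recordings.**  Per-stage mixtures of (a) continuous sinusoids, whose
per-epoch analytic relative PSD (A²/2 per tone, optionally filter-aware via
the closed-form gain) is the spectral oracle, and (b) isolated slow-wave
*events*: 1.5 cycles of A·sin(2πft) — a positive half-wave leading into one
full wave bounded by two descending zero-crossings exactly one period
apart, with trough −A and analytic downslope 4·A·f.  Events from all
components of an epoch share a non-overlapping randomized schedule, so
injected events are countable one-for-one against detections (a few
percent of inter-event gaps coincidentally satisfy a duration window; the
tests allow 2%).  Isolated packets are broadband, so they carry no
narrowband spectral oracle — continuous mode serves that purpose.  An
optional 1/f noise floor adds realism; one seeded generator drives all
draws, making outputs bit-reproducible.  The default stage architecture
approximates an elderly OSA diagnostic portion (TST 168 min; N1 25%, N2
48%, N3 16%, REM 11%).

**Cohorts.**  Slow-wave features are drawn multivariate normal with means
and SDs typical of an elderly OSA sample (SO% 25.7 ± 6.6, delta% 46.3 ±
5.4, SO-slope 95.1 ± 28.9, delta-slope 130.8 ± 34.8 µV/s) and the observed
correlation structure (slopes r = 0.88; bands r = −0.45).  Covariates: age
72.9 ± 7.5 y, APOE ε4 27%, baseline amyloid positivity 39%, log-normal scan
interval (median 2.7 y).  The outcome is a linear model with per-SD
coefficients defaulting to 0.0069 (SO-slope) and −0.0082 (delta-slope),
covariate effects (amyloid positivity 0.0117 — sized so the SO-slope effect
is ~59% of it — APOE 0.003, age 0.0003/y), intercept −0.022 and residual
SD 0.010, centring the outcome near 0.008 ± 0.013/y.  Paired titration
columns subtract the observed diagnostic-to-titration shifts (SO% 1.63,
SO-slope 12.5, delta-slope 16.2; SDs of differences reconstructed from the
printed CIs at n = 52).

**What passing tests do and do not show.**  The generator produces
stationary, noise-free-or-pink-noise mixtures of tones and stereotyped
events; real sleep EEG has nonstationary amplitude dynamics, spindles and
K-complexes, movement and respiratory artifacts, and slow waves of variable
morphology.  Passing oracles therefore validate the *algorithmic*
correctness of filtering, band integration, detection geometry, and the
statistical machinery — not the clinical accuracy of the features on real
recordings.

## Problem sizes

Test simulations use 5–30-minute nights at 500 Hz and cohorts of n = 64
(200 replicates for coverage, 5000 for consistency checks) — sizes chosen
so each oracle's Monte-Carlo error is well below its assertion tolerance.

## Known limitations

- EDF writing supports 16-bit continuous EDF with 1-s records and
  per-channel physical scaling; EDF+ discontinuous records and annotations
  are out of scope (hypnograms travel as TSV).
- The SO-band attenuation of the stated acquisition filter (above) means
  absolute SO%/SO-slope values are pipeline-specific; cross-pipeline
  comparisons need the documented gain curve.
- Artifact rejection is a deliberately simple amplitude/flatline rule plus
  externally supplied flags; it is not a substitute for visual or
  multi-criterion artifact scoring.
- Split-by-positivity models are subgroup refits; no interaction or
  mixed-effects modelling of more than two scans is provided.
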