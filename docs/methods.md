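# Methods

## Overview

`pulsekit` implements a smartphone-camera photoplethysmography (PPG)
pulse-interval pipeline and the statistical battery used to validate
such a pipeline against a reference ECG. The package has three parts:

1. **Extraction** — from raw per-frame luminosity to artifact-screened
   pulse intervals (`ppg`, `intervals`), and from raw ECG voltage to
   R-R intervals (`ecg`).
2. **Comparison** — time alignment and one-to-one beat pairing between
   the two modalities (`alignment`), and the agreement battery:
   Pearson correlation, intraclass correlation ICC(A,1), Bland-Altman
   limits of agreement with fixed- and proportional-bias tests
   (`agreement`).
3. **Simulation** — a paired ECG/PPG generator with known ground truth
   (`simulate`), so every stage is testable without participant data.

## PPG extraction chain

The chain is: regularize frame timestamps → (sign flip) → zero-phase
Butterworth band-pass 0.75–3 Hz → 5-frame unit-sum smoothing window →
180 Hz cubic-spline resampling → neighbour-comparison local maxima with
topographic prominences → global prominence filter (keep peaks above
30% of the mean prominence) → sliding 5-peak window filter (drop peaks
below 75% of the window-mean prominence) → boundary guard.

Parameter defaults and the reasoning where a choice was open:

| parameter | default | notes |
|---|---|---|
| band (Hz) | 0.75–3.0 | cardiac band: 45–180 bpm fundamentals |
| filter order | 2 | applied forward–backward (`sosfiltfilt`), so the effective attenuation is that of order 4 with zero phase shift — peak *times* are what matter downstream |
| smoothing window | Hann, length 5, unit sum | "convolution of a scaled window" is the classic smoothing recipe; a flat (moving-average) window is selectable |
| smoothing edges | reflection padding | avoids amplitude collapse at the record ends |
| resampling | 180 Hz cubic spline, not-a-knot | not-a-knot reproduces cubics exactly, which gives a clean test surface; 180 Hz puts peak-time quantization at 5.6 ms |
| peak rule | `v[i-1] < v[i] >= v[i+1]` | a plateau yields its first sample; deterministic and oracle-testable |
| global filter | prominence > 0.30 × mean prominence | the criterion is on *prominence*, not height |
| window filter | prominence ≥ 0.75 × mean of a 5-peak window | single pass over the input list; near the list ends the window is clamped to keep 5 peaks |
| edge guard | 0.8 s | see below |
| polarity | inverted | camera luminosity *dips* at systole (more blood absorbs more light), so the chain negates the signal before peak picking; set `invert=False` for sensors that report pulsatile amplitude directly |

Frame timestamps may jitter; the chain treats the series as uniform at
its nominal rate when every timestamp is within 20% of a frame period
of the nominal grid, and refuses the recording otherwise, because the
IIR filter requires uniform sampling.

### Boundary guard

Near the record ends two effects make peak decisions unreliable: the
zero-phase filter has boundary transients, and a peak's prominence
lacks full support (under a 0.75–3 Hz band limit the waveform around a
beat is reconstructed largely from the rhythm's harmonics, so a beat
without neighbours on one side loses roughly a quarter of its apparent
prominence — right astride the 75% window criterion). The chain
therefore discards detected peaks within 0.8 s (PPG) / 0.9 s (ECG) of
either record end. For a 5-minute recording this costs at most one
beat per edge.

## Interval screen

Pulse intervals are the durations (ms) between successive valid peaks.
The artifact screen has three stages, in order; stages mark rejection
codes and never modify values, so the valid set only shrinks:

1. **Quartile window** — valid intervals are windowed into consecutive
   blocks of 200; within each block, intervals outside
   `[Q1 − 1.5·IQR, Q3 + 1.5·IQR]` are rejected. The literal reading of
   the thresholds (everything outside `[Q1, Q3]`) removes ~50% of all
   beats by construction; the Tukey-fence form is the standard robust
   practice and the multiplier is configurable (`fence_multiplier=0`
   recovers the literal reading). Quartiles use linear interpolation
   between order statistics.
2. **Successive difference** — scanning valid intervals in time order,
   an interval is rejected if it differs by more than 20% from the
   most recent *accepted* interval (strict inequality). Rejected
   intervals never become the reference, so one artifact cannot
   cascade into rejecting its normal successors.
3. **Rate bounds** — intervals implying < 20 bpm (> 3000 ms) or
   > 200 bpm (< 300 ms) are rejected; bounds are exclusive, so exactly
   300 ms and 3000 ms survive.

## ECG R-wave detection

Designed for clean resting lab ECG and full oracle-testability rather
than ambulatory robustness: zero-phase 5 Hz high-pass (baseline
removal), 12 ms moving average (wideband noise), neighbour-comparison
maxima with prominences, threshold at 0.5 × a reference prominence,
250 ms refractory rule keeping the taller of two close detections, and
the boundary guard. The reference prominence is the median over the K
most prominent maxima, with K the beat count a 30 bpm rhythm would
produce: a median over *all* maxima would be dominated by noise
wiggles, and baseline noise dips make even small noise peaks
topographically prominent, so a global median is not a usable scale.
All thresholds are relative, making detection invariant to gain and
offset. Ectopy screening flags (never removes) intervals deviating
more than 30% from the running median of the 11 nearest intervals.

## Alignment and pairing

The PPG pulse arrives roughly one pulse-transit time (~100–300 ms)
after its R-wave. The lag is estimated by binning both event trains
onto a 10 ms grid, smoothing with a ±50 ms Hann kernel, and maximizing
the cross-correlation over ±2 s (ties resolve toward zero lag). Beats
are then matched one-to-one by greedy nearest neighbour within 500 ms;
an interval pair enters the comparison only when both its starting and
ending beats matched and both intervals are valid — so a missed or
rejected beat drops exactly its adjacent intervals, never producing a
mismatched (e.g. merged-vs-single) pair. A QC report (pairing
fraction, lag, median beat-time residual, flag below 90% pairing)
replaces the manual visual inspection a human rater would do.

## Agreement battery

All differences are ECG − PPG. For paired values the battery reports:

- Pearson r with the two-tailed p from the t transform (n − 2 df);
- ICC(A,1): single-rater, two-way random effects, absolute agreement,
  from the ANOVA decomposition
  `ICC = (MS_R − MS_E) / (MS_R + (k−1)MS_E + (k/n)(MS_C − MS_E))`,
  k = 2, with the F-based 95% CI using the Satterthwaite combination
  of MS_C (k−1 df) and MS_E ((n−1)(k−1) df) — the same construction
  SPSS and the R `psych` package use (cross-checked against `pingouin`
  in the test suite). A table with no between-subject variance reports
  ICC 0 with a degeneracy flag;
- Bland-Altman: mean difference (fixed bias; paired two-tailed t
  test), sample SD of differences, limits of agreement mean ± 1.96 SD
  (the 1.96 multiplier reproduces all three published caption
  intervals from their printed means/SDs), and proportional bias as
  the OLS slope of the difference on the pairwise mean (slope, SE,
  two-tailed p, R²).

Comparisons run at two levels: beat-by-beat within one subject, and
subject means (of mean pulse interval or SDNN) across a cohort. SDNN
uses the sample (n−1) standard deviation, the HRV-literature
convention. Reports round ms quantities to 1 decimal and correlations
to 2, keeping full precision internally.

## Simulator

The generator emulates a ~5-minute seated recording from a healthy
young adult next to a 500 Hz single-lead ECG.

**Beat process.** `RR_i = mean_rr + A_rsa sin(2π·0.25·t) +
A_lf sin(2π·0.1·t + φ) + ε_i`, with ε an AR(1) process (lag-one
correlation 0.8) and intervals truncated to (300, 3000) ms. Defaults
`mean_rr = 857` ms, `A_rsa = 50` ms, `A_lf = 82` ms, noise SD 25 ms
give SDNN ≈ 72 ms. The slow 0.1 Hz component and the autocorrelated
noise matter: real resting R-R series have RMSSD well below SDNN,
whereas white noise at SDNN 73 ms would imply RMSSD ≈ 100 ms — far
outside resting physiology — and would make the 20% successive-
difference screen reject several percent of legitimate beats.

**ECG.** Narrow Gaussian R spikes (σ = 10 ms) at beat times, optional
P/T bumps, optional white noise.

**PPG.** Per beat, a Gaussian systolic bump (σ = 80 ms) peaking one
transit delay (250 ms) after the R-wave and a dicrotic bump at 40% of
systolic height 250 ms after the apex (σ = 50 ms), subtracted from a
constant luminosity baseline (absorption sign convention), plus a slow
drift sinusoid (0.05 Hz), white sensor noise and optional timestamp
jitter. The dicrotic latency is fixed rather than proportional to the
local R-R because systole duration is nearly load-independent; a
proportional latency also makes the band-limited apex shift
RR-dependent, which would corrupt interval variability. The systolic
bump is symmetric so that its apex — the ground-truth peak time — is
invariant under the zero-phase band-pass; with an asymmetric bump the
0.75–3 Hz truncation shifts the apparent apex by ~10–15 ms, a known
property of band-limited PPG rather than a detector error.

**Record geometry.** One *supporter* beat (waveform only, excluded
from ground truth) continues the rhythm past the last true beat, and
the record ends 0.5 s after the supporter's apex. This gives every
ground-truth beat full two-sided support while the supporter itself
falls deterministically inside the pipeline's boundary guard, so
ground-truth beat counts are exactly recoverable, not boundary-luck.

**Artifacts.** A seeded fraction of intervals is corrupted by merges
(missed beat), splits (double detection) or spikes (×0.4 / ×2.5), with
per-interval labels, and beat times are rebuilt so the ground truth
stays self-consistent.

**Cohort.** Per subject, mean R-R is uniform over 679–1020 ms (the
59–88 bpm resting range) and the SDNN target is normal(73, 22) ms
floored at 25 ms, scaling all three variability components
proportionally.

What the simulator does **not** model: pulse-transit-time variability
(so synthetic beat-by-beat ECG/PPG agreement is nearly perfect, r ≈
0.999, whereas real per-participant r spans ~0.89–0.99), any
systematic device bias (synthetic cohort fixed bias is ≈ 0 ms, not the
small negative bias a real device shows), finger-pressure and motion
artifacts in the optical waveform itself (artifacts are injected at
the interval level), skin-tone optics, and realistic PQRST morphology.
Passing tests therefore demonstrate the pipeline's correctness and its
behaviour under controlled noise, not field performance.

## Problem sizes and numerical notes

The validation suites use 300 s recordings (≈ 350 beats) at 30 fps PPG
/ 500 Hz ECG, 20 seeds for recovery and artifact-efficacy checks, and
50 random instances per brute-force oracle comparison; the acceptance
script simulates a 14-subject cohort. Degenerate inputs are defined,
not accidental: a constant recording yields an empty peak set (the
band-passed residue is compared against a relative floor), zero
interval variance yields SDNN 0, a zero-variance Bland-Altman pair
yields zero limits and slope with p = 1, and an ICC table with no
subject variance reports 0 with a warning flag. Ties in the lag search
resolve toward the smallest absolute lag; equal-distance pairing
candidates resolve by scan order, deterministically.

## Known limitations

- The R-wave detector targets clean lab ECG; it is pluggable but not
  validated for ambulatory or pathological rhythms.
- The lag is a single constant per recording; slow transit-time drift
  is not tracked.
- Beat pairing assumes both series come from the same heart within a
  ±500 ms tolerance; gross clock drift must be fixed upstream.
- Edge beats within ~1 s of the record ends are deliberately not
  reported.
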