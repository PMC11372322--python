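# pulsekit

Smartphone cameras can measure the cardiac pulse: with a fingertip on
the lens, each video frame's mean luminosity dips slightly at every
systole (photoplethysmography, PPG). Whether the *beat-to-beat
intervals* extracted that way are accurate enough for heart-rate
variability (HRV) work has to be established against a reference ECG.
`pulsekit` is a tested implementation of that whole problem for
researchers in cardiovascular physiology and digital health:

- a **pulse-interval extraction pipeline** for 30 fps frame-luminosity
  recordings — 0.75–3 Hz zero-phase Butterworth band-pass, 5-frame
  smoothing, 180 Hz cubic-spline resampling, neighbour-comparison peak
  detection, and two prominence filters (peaks must exceed 30% of the
  global mean prominence, then 75% of the mean prominence in a sliding
  5-peak window, which strips dicrotic/diastolic bumps);
- a **multistep interval artifact screen** — per-200-interval quartile
  fences, a 20% successive-difference rule, and 20–200 bpm rate
  bounds;
- an **ECG reference path** — R-wave detection, R-R intervals, ectopy
  flagging;
- **beat alignment** — cross-correlation lag estimation (pulse transit
  delay) and one-to-one beat pairing;
- the **method-agreement battery** — Pearson r, intraclass correlation
  ICC(A,1) (two-way random effects, absolute agreement, with F-based
  95% CI), and Bland-Altman analysis: fixed bias d̄ with a paired
  two-tailed t test, limits of agreement d̄ ± 1.96·SD(d), and
  proportional bias as the OLS slope of d on the pairwise mean;
- a **paired ECG/PPG simulator** with known ground truth (beat times,
  R-R series, artifact labels) emulating 5-minute seated recordings —
  respiratory sinus arrhythmia, pulse-transit delay, dicrotic bumps,
  baseline drift, sensor noise, injectable artifacts.

See `docs/methods.md` for the model details and design rationale.

## Worked example

Simulate one subject's paired recordings, run both pipelines, align,
and compare:

```python
import pulsekit as pk

cfg = pk.SimConfig(duration_s=300, seed=42, ecg_noise_sd=0.05)
truth = pk.generate_rr_series(cfg)
ppg_peaks = pk.extract_ppg_peaks(pk.synthesize_ppg(truth, cfg))
r_peaks = pk.detect_r_peaks(pk.synthesize_ecg(truth, cfg))

ppg_iv = pk.clean_intervals(pk.compute_intervals(ppg_peaks))
ecg_iv = pk.compute_rr_intervals(r_peaks)
lag = pk.estimate_lag(r_peaks, ppg_peaks)
pairing = pk.pair_beats(ecg_iv, ppg_iv, lag)
rep = pk.compare_methods(pairing, "beat_by_beat")

h, ba = pk.hrv_summary(ppg_iv), rep.bland_altman
print("true beats:", truth.n_beats, "ppg:", len(ppg_peaks), "ecg:", len(r_peaks))
print(f"lag = {lag*1000:.0f} ms, pairs = {len(pairing)}")
print(f"PPG mean PI = {h.mean_pi:.1f} ms, SDNN = {h.sdnn:.1f} ms "
      f"(truth: {truth.rr_ms.mean():.1f}, {truth.rr_ms.std(ddof=1):.1f})")
print(f"r = {rep.agreement.pearson_r:.3f}, ICC = {rep.agreement.icc:.3f}")
print(f"bias = {ba.mean_diff:.2f} ms, LoA = ({ba.loa_lower:.2f}, {ba.loa_upper:.2f}) ms, "
      f"prop b = {ba.prop_slope_b:.4f} (R2 = {ba.prop_r2:.3f})")
```

which prints:

```
true beats: 350 ppg: 350 ecg: 350
lag = 250 ms, pairs = 349
PPG mean PI = 851.4 ms, SDNN = 71.0 ms (truth: 851.4, 71.7)
r = 0.999, ICC = 0.999
bias = 0.01 ms, LoA = (-6.21, 6.23) ms, prop b = 0.0091 (R2 = 0.042)
```

Every one of the 350 true beats was recovered from the 30 fps
luminosity trace; the estimated lag equals the simulated 250 ms pulse
transit delay; PPG-derived mean pulse interval and SDNN match the
ground truth to ~1 ms; and beat-by-beat agreement with the ECG is
near-perfect (r = ICC = 0.999, bias 0.01 ms) — as it should be for a
simulator without transit-time variability.

The same workflow is available from the shell:

```bash
pulsekit simulate --n-subjects 3 --seed 7 --out-dir sim/
pulsekit extract-ppg sim/subject01/ppg.csv --out-dir out1/
pulsekit compare sim/subject01/ecg.csv sim/subject01/ppg.csv --out-dir cmp1/
pulsekit report cmp1/pairs.csv cmp2/pairs.csv cmp3/pairs.csv --out-dir cohort/
```

`compare` writes the agreement JSON, the paired-beat CSV, and
scatter/Bland-Altman figures; `report` aggregates per-subject means
into the cohort-level battery. All configuration is available via
`--config` files and flags (`pulsekit show-config` prints every
default), inputs are plain CSV (`time_s,luminosity` and
`time_s,voltage`), and each run writes a manifest with config
snapshot, input digests and per-stage counts.

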