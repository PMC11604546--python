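# photolock

Behavior-locked analysis of fiber-photometry, slice-electrophysiology
and social-behavior data, built for studies that relate neural
population activity (e.g. somatostatin neurons of the lateral septum
recorded with GCaMP) to repeated social exposures, and neuropeptide
pharmacology (AVP, oxytocin agonists) to spike output.

The package implements, as tested reusable code:

- **Photometry processing** — dual-channel (465 nm GCaMP / 405 nm
  isosbestic) recordings are low-pass filtered (12 Hz), loess-smoothed,
  linearized with a moving-minima envelope, motion-corrected by
  regressing the signal channel onto the isosbestic control, and
  converted to ΔF/F = (F − F_fit)/F_fit and a z-score.
- **Transient analysis** — calcium transients are excursions of the
  z-score above +3 SD extended to the surrounding zero-crossings; each
  is quantified by its positive area under the curve (SD·s) and width
  at base (s), summarized per stimulus trial, and aligned to behavioral
  events (e.g. the subject turning away from a stimulus mouse) for
  peri-event averages and pre/post changes.
- **Responder classification** — spike rates as % of the pre-drug
  baseline; cells with less than a 10% change from baseline on
  consecutive timepoints are *insensitive*, cells persistently deviating
  are *responding*; Wilcoxon signed-rank change tests and exact
  responder-proportion comparisons.
- **Behavior statistics** — contact durations across five 5-min trials
  (same juvenile ×4, then a novel one), the trial-1 inclusion rules
  (< 15 s excluded; outside mean ± 2 SD of the group excluded),
  habituation/discrimination indices, rank tests and Cohen's d.
- **Synthetic data with ground truth** — a generator emulating
  photobleaching, shared motion artifacts, event-locked transients with
  group contrasts, drug-inhibition epochs and habituation patterns, so
  every stage is verifiable without animal data.

## Worked example

Simulate a 10-minute recording with 50 injected transients (peaks 5–8
noise-SD), process it, and detect transients:

```python
import photolock as pl

cfg = pl.SimConfig(duration_s=600, rate_hz=20, n_transients=50,
                   transient_amp_sd=6.5, transient_amp_jitter_sd=1.5,
                   noise_sd=1.0, quiet_start_s=90, seed=7)
rec, truth = pl.simulate_photometry(cfg)

trace = pl.process_recording(rec, pl.ProcessParams(
    cutoff_hz=None,            # 12 Hz is above Nyquist at 20 Hz
    loess_span=5 / len(rec),   # 0.25 s smoothing span
    minima_window_s=60.0,
    zscore_window_s=(10.0, 90.0),  # quiet baseline interval
))
trs = pl.detect_transients(trace, threshold_sd=3.0,
                           min_gap_s=0.5, min_width_s=1.0)
print(f"isosbestic fit: slope={trace.fit_slope:.3f}")
print(f"detected {len(trs)} transients (50 injected)")
```

This prints:

```
isosbestic fit: slope=0.008
detected 50 transients (50 injected)
```

The fitted slope is near zero here because the simulated recording has
no motion artifacts — there is nothing shared between the channels
beyond the (already detrended) bleach. All 50 injected transients are
recovered; their mean peak is 11.3 SD (the z scale is set by the quiet
baseline window, and smoothing raises peak-to-residual ratios above the
injected 5–8×), mean AUC 11.8 SD·s and mean width at base 2.63 s.

The same stages are scriptable from a shell:

```bash
photolock simulate --duration-s 600 --n-transients 20 --seed 1 --out-dir sim/
photolock process --input sim/recording.csv --loess-span 0.0005 \
    --zscore-window 10,90 --out processed.csv
photolock transients --processed processed.csv --events sim/events.csv \
    --trials sim/trials.csv --min-width-s 1.0 --out-dir results/
photolock run --seed 1 --out-dir run1/     # end-to-end with a manifest
```

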