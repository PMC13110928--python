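# meaosc

Analysis of **nested oscillations** in multi-electrode array (MEA)
recordings of 2D neuronal networks, built as a tested, reusable Python
pipeline with a synthetic data generator for end-to-end validation.

Cultured human neuronal networks on 16-electrode MEA wells develop slow
network bursts (NBs, sub-1 Hz coordinated population events) that can
carry faster rhythms — *nested oscillations* — in the delta (1–4 Hz),
theta (4–8 Hz) and alpha (8–13 Hz) bands. This package implements the
full chain from raw spike times to population-level statistics:

1. **Population signal** — spikes from all electrodes are binned at
   2 ms (500 Hz) and convolved with a double-exponential kernel shaped
   like a glutamatergic postsynaptic response
   (τ_rise = 2 ms, τ_decay = 25 ms, 300 ms window), giving a continuous
   waveform analogous to a local-field proxy.
2. **Oscillation detection** — per band: zero-phase FIR bandpass →
   Hilbert amplitude envelope → Gaussian smoothing (σ scaled with band
   center frequency and bandwidth) → dual-threshold detection at the
   50th/75th percentiles of the smoothed envelope, with per-band
   minimum cycle counts (8/16/24) and gap allowances (3/4/5 cycles).
3. **Spectral parameterization** — Welch spectra (4 s segments, 2 s
   overlap, 0.05–40 Hz) of events lasting ≥ 1 s, decomposed into an
   aperiodic 1/f component, `log10 P(f) = offset − exponent·log10 f`,
   plus up to 4 Gaussian peaks fitted on the flattened spectrum
   (peak width 1–8 Hz, min height 0.2, threshold 1.5 SD). Band peak
   frequency and aperiodic-corrected power are read off the flattened
   spectrum's in-band maximum.
4. **Burst metrics** — ISI-threshold bursts (≥5 spikes, ISI ≤ 100 ms),
   Poisson-surprise bursts (Legéndy–Salcman style, min surprise 5),
   pooled-ISI and envelope network bursts, synchrony index, and per-well
   summaries (spikes/burst, NB %, ISI CoV, % oscillatory NBs, ...).
5. **Emergence statistics** — a weighted binomial-logit GEE with
   exchangeable within-plate correlation models the fraction of
   oscillating wells per plate over weeks:
   `logit(p_ij) = β0 + β1·t_ij + β2·C80 + β3·C50 + β4·t_ij·C80 + β5·t_ij·C50`,
   with wells-per-plate as observation-level weights, robust (sandwich)
   standard errors, Wald χ² tests and odds ratios.

Because no public recordings accompany the analysis, a first-class
synthetic generator (`meaosc.synthetic_data`) produces MEA spike trains
with known injected NBs and nested rate modulation, power spectra with
known aperiodic/periodic parameters, and correlated binomial occurrence
tables with known coefficients — every stage is validated against that
ground truth or against exhaustive brute-force oracles.

## Worked example

Run the numbered analyses (each is a thin driver over the library):

```bash
python analysis/01_simulate_recordings.py --seed 1 --out results/
python analysis/02_detect_oscillations.py --results results/
python analysis/03_fit_spectra.py       --results results/ --seed 1
python analysis/04_summarize_metrics.py --results results/
python analysis/05_fit_gee.py           --seed 1 --out results/
```

With seed 1 this prints, among other lines:

```
simulated 20 wells (671132 spikes, 849 injected network bursts) -> results
theta recovery: 839/849 injected NBs (98.8%)
surrogate theta events at matched thresholds: 0 (0.0% of modulated rate)
annotated 2187 events; theta peak frequency 5.01 +- 0.08 Hz (5 Hz injected)
theta: 802 events, occurrence 8.02/min, mean duration 3.75 s, oscillatory NBs 99.2%
```

Reading: 98.8 % of the injected network bursts carry a detected
theta-band oscillation event; the fitted peak frequency recovers the
injected 5 Hz modulation to within 0.1 Hz; matched surrogate wells with
the same burst skeleton but no modulation produce no events when
screened at the matched well's calibrated thresholds. The GEE stage
(05) prints the coefficient table with odds ratios, e.g. a week effect
OR ≈ 2.24 [1.96, 2.55] against a generative (population-averaged)
target of e^0.758 ≈ 2.13.

Equivalent functionality is available in one call:

```python
from meaosc import PipelineConfig, run_pipeline
run_pipeline(PipelineConfig(seed=1, n_wells=4), "results/run1")
```

## File formats

* **Spike lists** — CSV with columns `well`, `electrode`, `time_s`
  (seconds from recording start, half-open `[0, duration)`), optional
  `duration_s`.
* **Event tables** — CSV: `well_id`, `band`, `start_s`, `end_s`,
  `duration_s`, `n_cycles`, `peak_envelope`, `peak_freq_hz`,
  `peak_power`, `offset`, `exponent`.
* **Occurrence tables** — CSV: `plate_id`, `condition`
  (`iGluta-alone`, `80:20`, `50:50`), `week`, `n_wells`,
  `n_oscillating`.

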