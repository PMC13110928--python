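# Methods

This note documents the models, parameter choices and numerical
decisions behind `meaosc`, and what the synthetic validation does and
does not establish about real recordings.

## Population signal

Spikes from all electrodes of a well are pooled into 2 ms half-open
bins (500 Hz) and convolved causally with
`k(t) = exp(−t/τ_d) − exp(−t/τ_r)` (τ_r = 2 ms, τ_d = 25 ms, 300 ms
support), the shape of a fast glutamatergic postsynaptic response. The
kernel is normalized to unit peak: every detection threshold downstream
is a percentile of the same recording, so the signal's absolute scale
is immaterial, and unit peak keeps worked examples readable. The
convolution output is truncated to the input length, preserving the
sample-index ↔ time mapping; the kernel's closed-form peak time
τ_r·τ_d/(τ_d−τ_r)·ln(τ_d/τ_r) ≈ 5.49 ms is used as a self-check.

## Oscillation detection

Per band (delta 1–4, theta 4–8, alpha 8–13 Hz):

* **Bandpass** — windowed-sinc FIR (Hamming), order = 3 cycles of the
  band's low edge rounded odd, applied symmetrically (zero phase) over
  a reflect-padded signal. Stopband attenuation exceeds 20 dB one
  octave outside each band edge.
* **Envelope** — magnitude of the analytic (Hilbert) signal.
* **Smoothing** — Gaussian with σ = c1/f_center + c2/bandwidth
  seconds, c1 = c2 = 0.25 by default and exposed in
  `DetectionParams`: the scaling couples the smoother to both the
  band's period and its inverse bandwidth; the exact functional form
  is a package choice.
* **Dual-threshold detection** — thresholds at the 50th and 75th
  percentiles (linear interpolation) of the *entire* recording's
  smoothed envelope, per well and band. Candidates are maximal runs
  strictly above the low threshold; sub-threshold gaps up to
  gap_allowance/f_center seconds (3/4/5 cycles) are merged *before*
  the acceptance tests; candidates must cross the high threshold at
  least once and span min_cycles/f_center seconds (8/16/24 cycles,
  arithmetic band-center frequency). Strict inequality makes the
  constant-envelope case unambiguous (no events).

Percentile thresholds make detection exactly invariant to positive
rescaling, but they also mean the detector always selects the
recording's top-quartile epochs: on a statistically homogeneous
recording it will report *something*. A null comparison between two
recordings each thresholded internally is therefore uninformative.
Surrogate testing in this package follows the standard protocol
instead: a surrogate (same burst skeleton, no nested modulation) is
screened against the thresholds calibrated on its matched original,
via the explicit `thresholds` override of `detect_events`. Under that
protocol unmodulated surrogates of the default generator produce zero
theta events while the modulated originals yield ~40 per well.

## Spectral parameterization

Welch spectra use 4 s Hann segments with 2 s overlap, constant
detrending, restricted to 0.05–40 Hz. Events shorter than one segment
(possible from 1 s up) fall back to a single full-length segment with
50 % overlap — a documented, configurable rule; the original analysis
settings are recovered whenever the event is ≥ 4 s.

The decomposition models log10 power as an aperiodic line in log
frequency ("fixed" mode, no knee) plus Gaussians: (1) least-squares
aperiodic fit; (2) robust refit on the lower-residual half of points,
so peaks cannot inflate the background; (3) iterative peak extraction
on the flattened spectrum — a maximum is accepted while it exceeds
both the absolute minimum height (0.2, log10 units) and 1.5 SD of the
current flattened spectrum, then fitted as a Gaussian with σ bounded
by half the 1–8 Hz width limits (bandwidth reported as 2σ) and the
center bounded near its guess so Gaussians cannot drift to soak
baseline curvature; (4) joint multi-Gaussian refit; (5) final robust
aperiodic refit on the peak-subtracted spectrum. Band peaks are the
in-band maximum of the flattened spectrum, ties resolved to the lower
frequency; a non-positive in-band maximum means "no peak".

On noise-free synthetic spectra the fit recovers offset and exponent
to ≤ 0.05; the recovery study (offsets 0–3, exponents 0.5–2.5, up to
three peaks with heights 0.3–0.8 and σ 0.5–1.5 Hz — typical narrowband
neural peaks — log-power noise SD 0.05) is run by the test suite and
the acceptance script rather than quoted here.

## Burst and network-burst detection

Two parameter sets mirror common MEA practice. ISI bursts: maximal
runs with every ISI ≤ 100 ms and ≥ 5 spikes. Pooled-ISI network
bursts: the time-merged train of active electrodes (≥ 5 spikes/min),
runs with pooled ISI ≤ 10 ms, ≥ 10 spikes, spanning ≥ 25 % of active
electrodes; ties in pooled time break by electrode id, and runs of
strictly zero duration (all spikes simultaneous) are discarded.
Envelope network bursts: 10 ms pooled rate histogram, Gaussian
smoothing (0.1 s), threshold at 2× the recording-mean rate, candidates
closer than 1 s merged, boundaries expanded within each candidate's
territory until it holds ≥ 75 % of the territory's spikes, then the
electrode filter. The vendor semantics of "burst inclusion" and of the
synchrony index are not public; both are explicit approximations here.
The synchrony index is, per active electrode pair, the fraction of
cross-spike lags within ±20 ms relative to lags within ±1 s, averaged
over pairs — near 1 for identical sparse trains, ≈ window/broad = 0.02
for independent stationary trains.

**Poisson surprise.** Bursts maximize
S = −log10 P(≥ n spikes in T | homogeneous Poisson at the train's
global mean rate), computed from the exact Poisson tail. Seeds are
runs of ≥ 3 consecutive ISIs below half the mean ISI; each seed is
greedily extended forward while S rises, then trimmed from the front
(never below 3 spikes), and accepted at S ≥ 5. The base-10 convention
makes S = 5 mean P < 10⁻⁵; under a natural-log reading the same
threshold (P < 6.7×10⁻³) would accept several clusters in every few
minutes of a homogeneous 1 Hz train, which would make the acceptance
threshold meaningless as a false-positive control. Even at P < 10⁻⁵ a
maximizing scan has an irreducible null hit rate: exhaustively scanning
all windows of 1 Hz × 300 s Poisson trains shows ~23 % of trains
contain some window with S ≥ 5 (null max-S median ≈ 4.5); the greedy
classical algorithm implemented here flags ~7 % of such trains. This
is a property of the statistic at that threshold, not a tunable of the
implementation.

## Summary metrics

Occurrence rate is events per minute. A network burst counts as
oscillatory in a band when any event of that band overlaps it with
positive measure. Percent change is 100·(post − baseline)/baseline,
undefined (with a warning) at non-positive baseline. WMFR is total
spikes / (duration × active electrodes) — an approximation of the
vendor metric, whose formula is not public. A well "oscillates" at a
timepoint when it has ≥ 1 event in any band (threshold configurable);
only wells with network bursting at the final week enter occurrence
denominators.

## Synthetic generator

`simulate_well` draws NB onsets as a hard-core renewal process
(Poisson candidates at `nb_rate` = 0.35/s thinned to a minimum
inter-onset interval of 4.2 s), each NB a half-sine rate envelope
(duration uniform within ±15 % of 3.5 s, truncated at the dead time)
whose rate is modulated by 1 + 0.8·sin(2π·5 Hz·t) for participating
electrodes (probability 0.9 of 16 electrodes, peak 25 spikes/s per
electrode, baseline 0.5 spikes/s outside NBs, 2 ms refractory
deletion). The half-sine avoids rate discontinuities that would ring
through the bandpass filters. Burst durations are long enough that a
single NB can satisfy the theta 16-cycle minimum (≥ 2.67 s); the
realized NB rate after dead-time thinning is ~0.14/s, slower than
typical real recordings — periods shorter than the cycle minima would
make single-NB theta events impossible by arithmetic. What passing
tests show is that the chain recovers injected band-limited rate
modulation and its frequency at realistic spike counts and shot noise;
they do not show robustness to electrode dropout, nonstationary
baselines, waveform asymmetry, or inter-well heterogeneity, none of
which the generator emulates.

`simulate_psd` is the generative twin of the spectral model (its peak
width parameter is the Gaussian σ in Hz; fitted bandwidths are 2σ).
`simulate_occurrence` is a *conditional* binomial model with a shared
plate-level Normal(0, 0.5²) logit intercept inducing within-plate
correlation. A marginal estimator such as the GEE targets the
*population-averaged* coefficients, which are attenuated relative to
the conditional ones; `marginal_beta` computes the exact pseudo-true
marginal vector (Gauss–Hermite integration of each cell's marginal
probability, then cross-entropy projection onto the logistic model)
and is the correct recovery target in validation studies.

## GEE

Estimation is delegated to statsmodels' GEE (binomial logit,
exchangeable working correlation, observation-level weights = wells
per plate, scale fixed at 1 as standard for binomial data), with
robust sandwich standard errors; Wald χ²(1) statistics, odds ratios
and 95 % CIs (±1.96·SE, exponentiated) are derived from the returned
fit. With singleton clusters the estimates coincide with direct
weighted-logistic maximum likelihood to ~10⁻⁷. Design columns are
ordered (intercept, centered week, C80, C50, and the two
interactions), weeks centered at the mean of observed rows, reference
condition the pure glutamatergic culture. Known limitation: the plain
sandwich underestimates SEs by ~5 % at a few hundred clusters, so
2-SE coverage sits near 94–95 % and Wald tests at 30 clusters reject
at ~0.08–0.10 under the null; small-sample corrected covariances are
deliberately out of scope.

## Reproducibility

All generators are pure functions of their configs including seeds;
the pipeline spawns per-well seeds from a single master seed and two
runs with the same config are byte-identical. Simulation sizes in the
test suite (20 wells of 300 s for end-to-end recovery, 100 spectra,
100 GEE recovery replicates, 1000 null replicates at 30 plates) were
chosen as the smallest designs at which the targeted rates are stable
to a few percent.
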