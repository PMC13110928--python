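"""Band-limited nested-oscillation detection on the population signal.

Per band (delta 1–4 Hz, theta 4–8 Hz, alpha 8–13 Hz): zero-phase FIR
bandpass → Hilbert amplitude envelope → Gaussian smoothing with a sigma
that scales with the band's center frequency and bandwidth → dual
percentile thresholding (50th/75th of the whole recording's smoothed
envelope).  A candidate is a maximal run above the low threshold;
candidates separated by sub-threshold gaps shorter than the band's
cycle allowance are merged; a candidate becomes an event if it crosses
the high threshold at least once and spans at least the band's minimum
number of cycles (duration × band center frequency).

Because thresholds are percentiles of the same recording, detection is
invariant to any positive rescaling of the input signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps
from scipy.ndimage import gaussian_filter1d

from meaosc.population_signal import PopulationSignal


@dataclass(frozen=True)
class FrequencyBand:
    name: str
    f_low: float
    f_high: float
    min_cycles: float
    gap_allowance_cycles: float

    def __post_init__(self) -> None:
        if not 0 < self.f_low < self.f_high:
            raise ValueError("need 0 < f_low < f_high")

    @property
    def f_center(self) -> float:
        return 0.5 * (self.f_low + self.f_high)

    @property
    def bandwidth(self) -> float:
        return self.f_high - self.f_low


DEFAULT_BANDS: dict[str, FrequencyBand] = {
    "delta": FrequencyBand("delta", 1.0, 4.0, 8, 3),
    "theta": FrequencyBand("theta", 4.0, 8.0, 16, 4),
    "alpha": FrequencyBand("alpha", 8.0, 13.0, 24, 5),
}


@dataclass
class DetectionParams:
    """Dual-threshold settings; percentiles of the smoothed envelope."""

    low_percentile: float = 50.0
    high_percentile: float = 75.0
    c1: float = 0.25  # smoothing sigma term scaling with 1/f_center, seconds*Hz
    c2: float = 0.25  # smoothing sigma term scaling with 1/bandwidth
    min_spectral_duration: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.low_percentile < self.high_percentile <= 100:
            raise ValueError("need 0 <= low < high <= 100")


@dataclass
class OscillationEvent:
    """One detected nested-oscillation episode in one band.

    Spectral fields are filled by :func:`meaosc.spectral_param.event_spectra`
    for events lasting at least the spectral minimum duration; otherwise
    they stay ``None``.
    """

    well_id: str
    band: str
    start: float
    end: float
    duration: float
    n_cycles: float
    peak_envelope: float
    peak_freq: Optional[float] = None
    peak_power: Optional[float] = None
    offset: Optional[float] = None
    exponent: Optional[float] = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("event must have end > start")


def design_bandpass(band: FrequencyBand, fs: float) -> np.ndarray:
    """Windowed-sinc (Hamming) FIR taps; order spans 3 cycles of f_low."""
    if fs <= 2 * band.f_high:
        raise ValueError(f"sampling rate {fs} too low for band up to {band.f_high} Hz")
    numtaps = int(round(3 * fs / band.f_low))
    numtaps += 1 - numtaps % 2  # odd length -> exactly linear phase
    return sps.firwin(
        numtaps, [band.f_low, band.f_high], pass_zero=False, window="hamming", fs=fs
    )


def bandpass(signal: PopulationSignal | np.ndarray, band: FrequencyBand, fs: float | None = None) -> np.ndarray:
    """Zero-phase FIR bandpass; output has the input's length.

    The symmetric FIR is applied centered (group delay compensated) over
    a reflect-padded copy of the signal, so phase — hence event timing —
    is preserved.
    """
    if isinstance(signal, PopulationSignal):
        x, fs = signal.values, signal.fs
    else:
        x = np.asarray(signal, dtype=float)
        if fs is None:
            raise ValueError("fs required when passing a bare array")
    taps = design_bandpass(band, fs)
    half = taps.size // 2
    pad = min(half, x.size - 1)
    xp = np.pad(x, pad, mode="reflect")
    y = sps.fftconvolve(xp, taps, mode="same")
    return y[pad : pad + x.size]


def envelope(filtered: np.ndarray) -> np.ndarray:
    """Instantaneous amplitude: magnitude of the analytic (Hilbert) signal."""
    return np.abs(sps.hilbert(np.asarray(filtered, dtype=float)))


def smooth_envelope(
    env: np.ndarray,
    band: FrequencyBand,
    fs: float,
    params: DetectionParams = DetectionParams(),
) -> np.ndarray:
    """Gaussian smoothing with sigma = c1/f_center + c2/bandwidth seconds.

    The kernel is normalized and applied with reflect padding, so the
    series mean is preserved.
    """
    sigma_s = params.c1 / band.f_center + params.c2 / band.bandwidth
    if sigma_s <= 0:
        raise ValueError("computed smoothing sigma must be positive")
    return gaussian_filter1d(np.asarray(env, dtype=float), sigma_s * fs, mode="reflect")


def _runs_above(x: np.ndarray, threshold: float) -> list[tuple[int, int]]:
    """Maximal half-open index runs where x > threshold (strict)."""
    above = x > threshold
    if not above.any():
        return []
    d = np.diff(np.concatenate(([0], above.astype(np.int8), [0])))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), stops.tolist()))


def detect_events(
    smoothed: np.ndarray,
    band: FrequencyBand,
    fs: float,
    params: DetectionParams = DetectionParams(),
    well_id: str = "",
    thresholds: tuple[float, float] | None = None,
) -> list[OscillationEvent]:
    """Dual-threshold detection on a smoothed amplitude envelope.

    Thresholds are the configured percentiles of the *entire* envelope
    (linear-interpolation definition).  Candidates are maximal runs
    strictly above the low threshold; adjacent candidates separated by a
    gap of at most ``gap_allowance_cycles / f_center`` seconds are merged;
    surviving candidates must exceed the high threshold at least once and
    span at least ``min_cycles / f_center`` seconds.

    ``thresholds`` overrides the percentile rule with absolute (low,
    high) values — used for surrogate testing, where a null recording is
    screened against the thresholds calibrated on its matched original
    rather than against its own percentiles (which would by construction
    select that recording's top quartile).
    """
    x = np.asarray(smoothed, dtype=float)
    if x.size == 0:
        return []
    if thresholds is None:
        lo = np.percentile(x, params.low_percentile)
        hi = np.percentile(x, params.high_percentile)
    else:
        lo, hi = thresholds

    runs = _runs_above(x, lo)
    max_gap_s = band.gap_allowance_cycles / band.f_center
    merged: list[list[int]] = []
    for start, stop in runs:
        if merged and (start - merged[-1][1]) / fs <= max_gap_s:
            merged[-1][1] = stop
        else:
            merged.append([start, stop])

    events = []
    for start, stop in merged:
        seg = x[start:stop]
        if seg.max() <= hi:
            continue
        duration = (stop - start) / fs
        n_cycles = duration * band.f_center
        if n_cycles < band.min_cycles:
            continue
        events.append(
            OscillationEvent(
                well_id=well_id,
                band=band.name,
                start=start / fs,
                end=stop / fs,
                duration=duration,
                n_cycles=n_cycles,
                peak_envelope=float(seg.max()),
            )
        )
    return events


def smoothed_band_envelope(
    signal: PopulationSignal,
    band: FrequencyBand,
    params: DetectionParams = DetectionParams(),
) -> np.ndarray:
    """Bandpass → Hilbert envelope → Gaussian smoothing, as one array."""
    return smooth_envelope(envelope(bandpass(signal, band)), band, signal.fs, params)


def band_thresholds(
    signal: PopulationSignal,
    band: FrequencyBand,
    params: DetectionParams = DetectionParams(),
) -> tuple[float, float]:
    """The (low, high) percentile thresholds this recording calibrates."""
    env = smoothed_band_envelope(signal, band, params)
    return (
        float(np.percentile(env, params.low_percentile)),
        float(np.percentile(env, params.high_percentile)),
    )


def detect_band(
    signal: PopulationSignal,
    band: FrequencyBand,
    params: DetectionParams = DetectionParams(),
    thresholds: tuple[float, float] | None = None,
) -> list[OscillationEvent]:
    """Full single-band chain: bandpass → envelope → smooth → detect."""
    sm = smoothed_band_envelope(signal, band, params)
    return detect_events(
        sm, band, signal.fs, params, well_id=signal.well_id, thresholds=thresholds
    )


def detect_all_bands(
    signal: PopulationSignal,
    bands: Sequence[FrequencyBand] | dict[str, FrequencyBand] | None = None,
    params: DetectionParams = DetectionParams(),
) -> dict[str, list[OscillationEvent]]:
    """Run detection independently for each band; returns band → events."""
    if bands is None:
        bands = DEFAULT_BANDS
    if isinstance(bands, dict):
        bands = list(bands.values())
    return {band.name: detect_band(signal, band, params) for band in bands}
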