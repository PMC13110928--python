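"""Welch spectra of oscillation events and periodic/aperiodic decomposition.

Power spectra are estimated with Welch's method (4-s Hann segments, 2-s
overlap, 0.05–40 Hz).  Each spectrum is then decomposed, in log10 power,
into an aperiodic 1/f component ``L(f) = offset - exponent*log10(f)``
("fixed" mode, no knee) plus up to four Gaussian peaks fitted on the
flattened (aperiodic-subtracted) spectrum — the standard spectral
parameterization model.  Fitting proceeds as:

1. initial aperiodic fit by least squares on log-log axes;
2. robust refit using only the lower-residual half of frequency points,
   so narrowband peaks do not drag the 1/f estimate up;
3. iterative peak extraction on the flattened spectrum: take the
   maximum, accept it if it clears both the absolute minimum height and
   ``peak_threshold`` standard deviations of the flattened spectrum, fit
   a Gaussian (width bounded by the configured limits, bandwidth = 2σ),
   subtract, repeat up to ``max_n_peaks``;
4. joint refit of all Gaussians;
5. final aperiodic refit on the peak-subtracted spectrum.

Events shorter than one Welch segment use a shortened segment
(``min(segment_length, event duration)``) with 50% overlap; the rule is
exposed through :class:`WelchParams`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps
from scipy.optimize import curve_fit

from meaosc.oscillation_detection import FrequencyBand, OscillationEvent
from meaosc.population_signal import PopulationSignal


@dataclass
class WelchParams:
    segment_length: float = 4.0
    overlap: float = 2.0
    f_min: float = 0.05
    f_max: float = 40.0
    taper: str = "hann"

    def __post_init__(self) -> None:
        if not 0 <= self.overlap < self.segment_length:
            raise ValueError("need 0 <= overlap < segment_length")
        if not 0 < self.f_min < self.f_max:
            raise ValueError("need 0 < f_min < f_max")


@dataclass
class SpecFitSettings:
    peak_width_limits: tuple[float, float] = (1.0, 8.0)
    min_peak_height: float = 0.2  # log10-power units
    max_n_peaks: int = 4
    peak_threshold: float = 1.5  # multiples of the flattened spectrum's SD
    aperiodic_mode: str = "fixed"

    def __post_init__(self) -> None:
        lo, hi = self.peak_width_limits
        if not 0 < lo < hi:
            raise ValueError("peak_width_limits must be positive and ordered")
        if self.max_n_peaks < 0:
            raise ValueError("max_n_peaks must be >= 0")
        if self.aperiodic_mode != "fixed":
            raise ValueError("only the 'fixed' aperiodic mode is supported")


@dataclass
class SpectralFit:
    """Parameterized power spectrum.

    ``peaks`` holds (center_freq Hz, height in log10-power above the
    aperiodic fit, bandwidth Hz = 2σ).  ``flattened`` is
    ``log_psd - aperiodic``; adding them back reconstructs the data, and
    the model spectrum is ``aperiodic + sum of Gaussians``.
    """

    frequencies: np.ndarray
    log_psd: np.ndarray
    offset: float
    exponent: float
    peaks: list[tuple[float, float, float]]
    flattened: np.ndarray
    r_squared: float
    error: float

    @property
    def aperiodic(self) -> np.ndarray:
        return self.offset - self.exponent * np.log10(self.frequencies)

    def model(self) -> np.ndarray:
        m = self.aperiodic.copy()
        for cf, height, bw in self.peaks:
            sd = bw / 2.0
            m += height * np.exp(-((self.frequencies - cf) ** 2) / (2 * sd**2))
        return m


@dataclass
class BandPeak:
    band: str
    peak_freq: float
    peak_power: float


def welch_psd(
    x: np.ndarray,
    fs: float,
    params: WelchParams = WelchParams(),
) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD restricted to [f_min, f_max].

    Segments shorter than ``segment_length`` seconds of data use the full
    data length as one segment with 50% overlap (relevant for 1–4 s
    oscillation events); the paper-level default is 4-s segments with 2-s
    overlap.
    """
    x = np.asarray(x, dtype=float)
    duration = x.size / fs
    seg_s = min(params.segment_length, duration)
    if seg_s <= 0 or x.size < 8:
        raise ValueError("segment too short for spectral analysis")
    if seg_s < params.segment_length:
        overlap_s = seg_s / 2.0
    else:
        overlap_s = params.overlap
    nperseg = int(round(seg_s * fs))
    noverlap = min(int(round(overlap_s * fs)), nperseg - 1)
    freqs, psd = sps.welch(
        x,
        fs=fs,
        window=params.taper,
        nperseg=nperseg,
        noverlap=noverlap,
        detrend="constant",
    )
    keep = (freqs >= params.f_min) & (freqs <= params.f_max)
    return freqs[keep], psd[keep]


def _aperiodic_ls(logf: np.ndarray, log_psd: np.ndarray) -> tuple[float, float]:
    """Exact least squares for log_psd = offset - exponent*logf."""
    slope, intercept = np.polyfit(logf, log_psd, 1)
    return float(intercept), float(-slope)


def _gaussian(f: np.ndarray, center: float, height: float, sd: float) -> np.ndarray:
    return height * np.exp(-((f - center) ** 2) / (2 * sd**2))


def _multi_gaussian(f: np.ndarray, *params: float) -> np.ndarray:
    out = np.zeros_like(f)
    for i in range(0, len(params), 3):
        out += _gaussian(f, params[i], params[i + 1], params[i + 2])
    return out


def fit_spectrum(
    frequencies: np.ndarray,
    psd: np.ndarray,
    settings: SpecFitSettings = SpecFitSettings(),
) -> SpectralFit:
    """Decompose a linear-power spectrum into aperiodic + Gaussian peaks."""
    freqs = np.asarray(frequencies, dtype=float)
    psd = np.asarray(psd, dtype=float)
    if freqs.size < 8:
        raise ValueError("need at least 8 frequency points")
    if np.any(~np.isfinite(psd)) or np.any(psd <= 0) or np.any(freqs <= 0):
        raise ValueError("psd must be finite and strictly positive")
    logf = np.log10(freqs)
    log_psd = np.log10(psd)

    # (1) initial aperiodic, (2) robust refit on lower-residual half
    offset0, exponent0 = _aperiodic_ls(logf, log_psd)
    resid = log_psd - (offset0 - exponent0 * logf)
    keep = resid <= np.median(resid)
    offset, exponent = _aperiodic_ls(logf[keep], log_psd[keep])

    # (3) iterative peak search on the flattened spectrum
    sd_lo = settings.peak_width_limits[0] / 2.0
    sd_hi = settings.peak_width_limits[1] / 2.0
    flat = log_psd - (offset - exponent * logf)
    guesses: list[tuple[float, float, float]] = []
    work = flat.copy()
    for _ in range(settings.max_n_peaks):
        i = int(np.argmax(work))
        height = work[i]
        if height <= settings.min_peak_height:
            break
        if height <= settings.peak_threshold * np.std(work):
            break
        center = freqs[i]
        # half-height width estimate for the sigma guess
        half = height / 2.0
        right = i
        while right < work.size - 1 and work[right] > half:
            right += 1
        left = i
        while left > 0 and work[left] > half:
            left -= 1
        fwhm = max(freqs[right] - freqs[left], 2 * sd_lo * 2.355 / 2)
        sd_guess = np.clip(fwhm / 2.355, sd_lo, sd_hi)
        # center constrained near its guess so the Gaussian cannot drift
        # away to soak up residual baseline curvature
        c_lo = max(freqs.min(), center - 1.5 * sd_guess)
        c_hi = min(freqs.max(), center + 1.5 * sd_guess)
        try:
            popt, _ = curve_fit(
                _gaussian,
                freqs,
                work,
                p0=[center, height, sd_guess],
                bounds=([c_lo, 0.0, sd_lo], [c_hi, np.inf, sd_hi]),
                maxfev=5000,
            )
        except RuntimeError:
            break
        guesses.append((float(popt[0]), float(popt[1]), float(popt[2])))
        work = work - _gaussian(freqs, *popt)

    # (4) joint multi-Gaussian refit against the flattened spectrum
    peaks: list[tuple[float, float, float]] = []
    if guesses:
        p0 = np.ravel(guesses)
        lb = np.ravel(
            [[max(freqs.min(), c - 1.5 * sd), 0.0, sd_lo] for c, _, sd in guesses]
        )
        ub = np.ravel(
            [[min(freqs.max(), c + 1.5 * sd), np.inf, sd_hi] for c, _, sd in guesses]
        )
        try:
            popt, _ = curve_fit(
                _multi_gaussian, freqs, flat, p0=p0, bounds=(lb, ub), maxfev=5000
            )
            peaks = [
                (float(popt[i]), float(popt[i + 1]), float(popt[i + 2]))
                for i in range(0, popt.size, 3)
            ]
        except RuntimeError:
            peaks = guesses
        peaks.sort(key=lambda p: p[0])

    # (5) final aperiodic refit on the peak-subtracted spectrum; robust
    # again, so residual peak mis-fit cannot lift the background
    peak_model = np.zeros_like(freqs)
    for cf, h, sd in peaks:
        peak_model += _gaussian(freqs, cf, h, sd)
    residual_spectrum = log_psd - peak_model
    offset, exponent = _aperiodic_ls(logf, residual_spectrum)
    resid = residual_spectrum - (offset - exponent * logf)
    keep = resid <= np.median(resid)
    offset, exponent = _aperiodic_ls(logf[keep], residual_spectrum[keep])

    flattened = log_psd - (offset - exponent * logf)
    model = (offset - exponent * logf) + peak_model
    ss_res = float(np.sum((log_psd - model) ** 2))
    ss_tot = float(np.sum((log_psd - log_psd.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    mae = float(np.mean(np.abs(log_psd - model)))

    # report bandwidth = 2*sigma (the conventional specparam output)
    peaks_bw = [(cf, h, 2.0 * sd) for cf, h, sd in peaks]
    return SpectralFit(
        frequencies=freqs,
        log_psd=log_psd,
        offset=float(offset),
        exponent=float(exponent),
        peaks=peaks_bw,
        flattened=flattened,
        r_squared=r2,
        error=mae,
    )


def band_peak(fit: SpectralFit, band: FrequencyBand) -> Optional[BandPeak]:
    """Maximum of the flattened spectrum within the band's edges.

    Returns ``None`` when the in-band flattened maximum is not above
    zero (no periodic power above the aperiodic background).  Ties break
    toward the lower frequency.
    """
    mask = (fit.frequencies >= band.f_low) & (fit.frequencies <= band.f_high)
    if not mask.any():
        raise ValueError(f"band {band.name} outside the fitted frequency range")
    flat = fit.flattened[mask]
    freqs = fit.frequencies[mask]
    i = int(np.argmax(flat))
    if flat[i] <= 0:
        return None
    return BandPeak(band.name, float(freqs[i]), float(flat[i]))


def event_spectra(
    signal: PopulationSignal,
    events: Sequence[OscillationEvent],
    bands: dict[str, FrequencyBand],
    welch: WelchParams = WelchParams(),
    settings: SpecFitSettings = SpecFitSettings(),
    min_duration: float = 1.0,
) -> list[OscillationEvent]:
    """Annotate events with spectral summaries.

    Only events lasting at least ``min_duration`` seconds are analyzed;
    shorter events keep ``None`` spectral fields.  Each analyzed event
    gets the fitted aperiodic offset/exponent and, from its own band, the
    flattened-spectrum peak frequency and aperiodic-corrected power.
    """
    annotated = []
    for ev in events:
        if ev.duration < min_duration:
            annotated.append(ev)
            continue
        i0 = int(round(ev.start * signal.fs))
        i1 = int(round(ev.end * signal.fs))
        seg = signal.values[i0:i1]
        try:
            freqs, psd = welch_psd(seg, signal.fs, welch)
            fit = fit_spectrum(freqs, psd, settings)
        except ValueError:
            annotated.append(ev)
            continue
        bp = band_peak(fit, bands[ev.band]) if ev.band in bands else None
        annotated.append(
            OscillationEvent(
                well_id=ev.well_id,
                band=ev.band,
                start=ev.start,
                end=ev.end,
                duration=ev.duration,
                n_cycles=ev.n_cycles,
                peak_envelope=ev.peak_envelope,
                peak_freq=bp.peak_freq if bp else None,
                peak_power=bp.peak_power if bp else None,
                offset=fit.offset,
                exponent=fit.exponent,
            )
        )
    return annotated
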