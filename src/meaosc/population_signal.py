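"""Spike trains to a continuous 500 Hz population signal.

Spikes from all electrodes of a well are binned into 2 ms windows
(500 Hz histogram) and convolved with a double-exponential kernel shaped
like a glutamatergic postsynaptic response (rise 2 ms, decay 25 ms,
300 ms support).  The result is a nonnegative waveform tracking
population activity — the substrate for all oscillation and spectral
analysis.  The convolution is causal (the kernel follows the spike) and
the kernel is normalized to unit peak; all downstream thresholds are
percentile-based, so the overall scale is immaterial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from meaosc.spike_io import WellRecording


@dataclass
class KernelParams:
    tau_rise: float = 0.002
    tau_decay: float = 0.025
    window: float = 0.300

    def __post_init__(self) -> None:
        if not 0 < self.tau_rise < self.tau_decay:
            raise ValueError("need 0 < tau_rise < tau_decay")
        if self.window < 5 * self.tau_decay:
            raise ValueError("kernel window must cover >= 5 decay constants")

    @property
    def peak_time(self) -> float:
        """Closed-form argmax of exp(-t/tau_d) - exp(-t/tau_r)."""
        tr, td = self.tau_rise, self.tau_decay
        return tr * td / (td - tr) * np.log(td / tr)


@dataclass
class PopulationSignal:
    """Continuous population-activity waveform for one well."""

    values: np.ndarray
    fs: float = 500.0
    bin_width: float = 0.002
    t0: float = 0.0
    well_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if abs(self.fs * self.bin_width - 1.0) > 1e-9:
            raise ValueError("fs and bin_width must satisfy fs*bin_width == 1")

    @property
    def duration(self) -> float:
        return self.values.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.fs


def bin_spikes(recording: WellRecording, bin_width: float = 0.002) -> np.ndarray:
    """Histogram all electrodes' spikes into half-open bins [b*w, (b+1)*w).

    The bin count equals ``ceil(duration / bin_width)`` and the counts
    sum to the total number of spikes.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n_bins = int(np.ceil(recording.duration / bin_width))
    pooled = recording.all_spikes()
    # floor puts a spike exactly on an edge into the right-hand bin
    idx = np.floor(pooled / bin_width).astype(int)
    idx = idx[idx < n_bins]
    return np.bincount(idx, minlength=n_bins).astype(float)


def make_kernel(params: KernelParams = KernelParams(), fs: float = 500.0) -> np.ndarray:
    """Double-exponential kernel sampled at fs, rescaled to unit peak.

    ``k(t) = exp(-t/tau_decay) - exp(-t/tau_rise)`` for t = 0..window;
    k(0) = 0 and the single maximum sits at
    ``t* = tau_r*tau_d/(tau_d - tau_r) * ln(tau_d/tau_r)`` (~5.49 ms at
    the defaults).
    """
    t = np.arange(0, params.window + 0.5 / fs, 1.0 / fs)
    k = np.exp(-t / params.tau_decay) - np.exp(-t / params.tau_rise)
    return k / k.max()


def convolve_signal(
    histogram: np.ndarray,
    kernel: np.ndarray,
    fs: float = 500.0,
    well_id: str = "",
) -> PopulationSignal:
    """Causal convolution of the spike histogram with the kernel.

    Output has the histogram's length (the tail of the last kernel is
    dropped), so sample n maps to time n/fs throughout.  A single count
    reproduces the kernel shape exactly.
    """
    histogram = np.asarray(histogram, dtype=float)
    kernel = np.asarray(kernel, dtype=float)
    if histogram.size == 0 or kernel.size == 0:
        raise ValueError("histogram and kernel must be non-empty")
    if kernel.size > histogram.size:
        raise ValueError("kernel must be shorter than the histogram")
    values = np.convolve(histogram, kernel, mode="full")[: histogram.size]
    return PopulationSignal(values=values, fs=fs, bin_width=1.0 / fs, well_id=well_id)


def spike_density(
    recording: WellRecording,
    kernel_params: KernelParams = KernelParams(),
    fs: float = 500.0,
) -> PopulationSignal:
    """Convenience composition: bin at 1/fs, convolve with the kernel."""
    hist = bin_spikes(recording, bin_width=1.0 / fs)
    kernel = make_kernel(kernel_params, fs)
    return convolve_signal(hist, kernel, fs=fs, well_id=recording.well_id)
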