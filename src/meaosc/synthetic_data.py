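"""Synthetic MEA data with known ground truth.

Three generators mirror the statistical structure the analysis assumes:

* :func:`simulate_well` — spike trains on a 16-electrode well in which
  slow network bursts (NBs, sub-1 Hz; around 0.3–0.4 events/s before
  dead-time thinning) carry a sinusoidally rate-modulated nested
  oscillation over a Poisson background.
* :func:`simulate_psd` — power spectra with known aperiodic (offset,
  exponent) and periodic (Gaussian peak) parameters.
* :func:`simulate_occurrence` — plate-level correlated binomial
  "well oscillates" counts with known logistic coefficients, for
  exercising the GEE stage.

These are validation scaffolding: the distributional choices make every
downstream stage testable against ground truth, they are not claims
about the biology of real cultures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from meaosc.spike_io import WellRecording

CONDITIONS = ("iGluta-alone", "80:20", "50:50")


def _check_nonneg(name: str, value: float) -> None:
    if not np.isfinite(value) or value < 0:
        raise ValueError(f"{name} must be finite and >= 0, got {value}")


@dataclass
class SpikeSimConfig:
    """Parameters of the synthetic well generator.

    Network-burst onsets form a hard-core renewal process: Poisson
    candidates at ``nb_rate`` thinned so consecutive onsets are at least
    ``nb_min_ibi`` apart.  Each NB has a half-sine firing-rate envelope
    (duration drawn uniformly within ±15% of ``nb_duration_mean``,
    truncated at ``nb_min_ibi``) whose rate is modulated as
    ``1 + modulation_depth * sin(2*pi*nested_freq*(t - t_onset))``.
    Electrodes join a given NB independently with ``participation_prob``;
    outside NBs every electrode fires as homogeneous Poisson at
    ``baseline_rate``.  Spikes closer than ``refractory`` to the previous
    kept spike on the same electrode are deleted.
    """

    n_electrodes: int = 16
    duration: float = 300.0
    nb_rate: float = 0.35
    nb_duration_mean: float = 3.5
    nb_min_ibi: float = 4.2
    baseline_rate: float = 0.5
    burst_peak_rate: float = 25.0
    nested_freq: float = 5.0
    modulation_depth: float = 0.8
    participation_prob: float = 0.9
    refractory: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_electrodes < 1:
            raise ValueError("n_electrodes must be >= 1")
        for name in (
            "duration",
            "nb_rate",
            "nb_duration_mean",
            "nb_min_ibi",
            "baseline_rate",
            "burst_peak_rate",
            "nested_freq",
            "refractory",
        ):
            _check_nonneg(name, getattr(self, name))
        if not 0.0 <= self.modulation_depth <= 1.0:
            raise ValueError("modulation_depth must lie in [0, 1]")
        if not 0.0 <= self.participation_prob <= 1.0:
            raise ValueError("participation_prob must lie in [0, 1]")


@dataclass
class PsdSimConfig:
    """Generative model for a parameterized power spectrum.

    ``log10 psd(f) = offset - exponent*log10(f) + sum_k G_k(f) + eps``
    with ``G_k`` a Gaussian in linear frequency (center Hz, height in
    log10-power, standard deviation Hz) and ``eps ~ N(0, noise_sd)``.
    The returned spectrum is linear power, i.e. ``10**(...)``.
    """

    offset: float = 1.0
    exponent: float = 1.5
    peaks: list[tuple[float, float, float]] = field(default_factory=list)
    freq_range: tuple[float, float] = (0.5, 40.0)
    freq_resolution: float = 0.25
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.exponent < 0:
            raise ValueError("exponent must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        lo, hi = self.freq_range
        if lo <= 0 or hi <= lo:
            raise ValueError("freq_range must satisfy 0 < lo < hi")
        for cf, _, bw in self.peaks:
            if not lo <= cf <= hi:
                raise ValueError(f"peak center {cf} Hz outside freq_range")
            if bw <= 0:
                raise ValueError("peak bandwidths must be positive")


@dataclass
class OccurrenceSimConfig:
    """Generative twin of the oscillation-emergence GEE.

    For plate ``i`` in condition ``c`` at week ``j`` the number of
    oscillating wells is ``k_ij ~ Binomial(n_ij, p_ij)`` with
    ``logit(p_ij) = b0 + b1*t + b2*C80 + b3*C50 + b4*t*C80 + b5*t*C50 + u_i``
    where ``t`` is the centered week and ``u_i ~ N(0, plate_sd^2)`` is a
    shared plate effect inducing within-plate correlation.
    """

    beta: tuple[float, float, float, float, float, float] = (0.0, 0.8, 1.2, 0.4, 0.5, 0.0)
    n_plates_per_condition: int = 7
    wells_per_plate: tuple[int, int] = (6, 18)
    weeks: tuple[float, ...] = (3.0, 4.0, 5.0, 6.0)
    plate_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.beta) != 6:
            raise ValueError("beta must have 6 entries (b0..b5)")
        if self.plate_sd < 0:
            raise ValueError("plate_sd must be >= 0")
        if not self.weeks:
            raise ValueError("weeks must be non-empty")
        lo, hi = self.wells_per_plate
        if lo < 1 or hi < lo:
            raise ValueError("wells_per_plate must satisfy 1 <= lo <= hi")
        if self.n_plates_per_condition < 1:
            raise ValueError("n_plates_per_condition must be >= 1")


def nb_rate_function(
    t: np.ndarray,
    onset: float,
    nb_duration: float,
    config: SpikeSimConfig,
) -> np.ndarray:
    """Within-burst firing rate for a participating electrode (spikes/s)."""
    t = np.asarray(t, dtype=float)
    rel = t - onset
    env = np.where(
        (rel >= 0) & (rel <= nb_duration),
        np.sin(np.pi * np.clip(rel, 0, nb_duration) / nb_duration),
        0.0,
    )
    mod = 1.0 + config.modulation_depth * np.sin(2 * np.pi * config.nested_freq * rel)
    return config.burst_peak_rate * env * mod


def _draw_nb_onsets(config: SpikeSimConfig, rng: np.random.Generator) -> np.ndarray:
    """Hard-core renewal NB onsets: Poisson candidates thinned to min IBI.

    ``nb_rate`` is the rate of the Poisson candidate stream; the dead
    time makes the realized NB rate lower, with inter-onset intervals
    distributed as ``nb_min_ibi + Exp(1/nb_rate)``.
    """
    if config.nb_rate == 0:
        return np.empty(0)
    expected = config.nb_rate * config.duration
    n_cand = rng.poisson(expected)
    cand = np.sort(rng.uniform(0, config.duration, n_cand))
    kept: list[float] = []
    for t in cand:
        if not kept or t - kept[-1] >= config.nb_min_ibi:
            kept.append(t)
    return np.asarray(kept)


def _thin_refractory(times: np.ndarray, refractory: float) -> np.ndarray:
    """Delete spikes within ``refractory`` of the previous kept spike."""
    if refractory <= 0 or times.size < 2:
        return times
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= refractory:
            kept.append(t)
    return np.asarray(kept)


def _inhomogeneous_burst_spikes(
    onset: float,
    nb_duration: float,
    config: SpikeSimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Spikes of one participating electrode in one NB, by thinning."""
    r_max = config.burst_peak_rate * (1.0 + config.modulation_depth)
    if r_max == 0:
        return np.empty(0)
    n_cand = rng.poisson(r_max * nb_duration)
    cand = rng.uniform(onset, onset + nb_duration, n_cand)
    accept = rng.uniform(0, r_max, n_cand) < nb_rate_function(
        cand, onset, nb_duration, config
    )
    return np.sort(cand[accept])


def simulate_well(config: SpikeSimConfig, well_id: str = "SIM") -> WellRecording:
    """Simulate one well; ground truth is stored in the result's metadata.

    ``metadata['injected_nbs']`` holds the (onset, duration) pairs of the
    injected network bursts and ``metadata['participation']`` the boolean
    electrode × NB participation matrix.
    """
    rng = np.random.default_rng(config.seed)
    onsets = _draw_nb_onsets(config, rng)
    durations = np.minimum(
        config.nb_duration_mean * rng.uniform(0.85, 1.15, onsets.size),
        config.nb_min_ibi if config.nb_min_ibi > 0 else np.inf,
    )
    # clip the last NB so no spike lands at/after `duration`
    if onsets.size:
        durations = np.minimum(durations, config.duration - 1e-6 - onsets)
        keep = durations > 0
        onsets, durations = onsets[keep], durations[keep]

    electrode_ids = [f"E{i + 1:02d}" for i in range(config.n_electrodes)]
    participation = rng.uniform(size=(config.n_electrodes, onsets.size)) < (
        config.participation_prob
    )

    electrode_spikes: dict[str, np.ndarray] = {}
    for e, eid in enumerate(electrode_ids):
        n_base = rng.poisson(config.baseline_rate * config.duration)
        base = rng.uniform(0, config.duration, n_base)
        # baseline applies outside NBs the electrode participates in
        for k in range(onsets.size):
            if participation[e, k]:
                inside = (base >= onsets[k]) & (base < onsets[k] + durations[k])
                base = base[~inside]
        parts = [base]
        for k in range(onsets.size):
            if participation[e, k]:
                parts.append(
                    _inhomogeneous_burst_spikes(onsets[k], durations[k], config, rng)
                )
        times = np.sort(np.concatenate(parts)) if parts else np.empty(0)
        electrode_spikes[eid] = _thin_refractory(times, config.refractory)

    return WellRecording(
        well_id=well_id,
        electrode_spikes=electrode_spikes,
        duration=config.duration,
        metadata={
            "injected_nbs": [(float(o), float(d)) for o, d in zip(onsets, durations)],
            "participation": participation,
            "config": config,
        },
    )


def simulate_psd(config: PsdSimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Return (frequencies, linear-power psd) from the generative model."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.freq_range
    freqs = np.arange(lo, hi + 0.5 * config.freq_resolution, config.freq_resolution)
    if np.any(freqs <= 0):
        raise ValueError("all frequencies must be positive")
    log_psd = config.offset - config.exponent * np.log10(freqs)
    for cf, height, sd in config.peaks:
        log_psd = log_psd + height * np.exp(-((freqs - cf) ** 2) / (2 * sd**2))
    if config.noise_sd > 0:
        log_psd = log_psd + rng.normal(0, config.noise_sd, freqs.size)
    return freqs, 10.0**log_psd


def marginal_beta(config: OccurrenceSimConfig) -> np.ndarray:
    """Population-averaged coefficients implied by the conditional model.

    The generator is a conditional (plate random-intercept) logistic
    model; a marginal estimator such as a GEE targets the
    population-averaged coefficients, which are attenuated relative to
    the conditional ``beta`` when ``plate_sd > 0``.  This computes the
    exact pseudo-true marginal vector: the marginal success probability
    ``E_u[logistic(x'beta + u)]`` is integrated by Gauss–Hermite
    quadrature for every design cell, then projected back onto the
    logistic model by minimizing the cross-entropy over the balanced
    design.  With ``plate_sd = 0`` this returns ``beta`` unchanged.
    """
    from scipy.optimize import minimize

    b = np.asarray(config.beta, dtype=float)
    if config.plate_sd == 0:
        return b.copy()
    weeks = np.asarray(config.weeks, dtype=float)
    t = weeks - weeks.mean()
    X = []
    for cond in CONDITIONS:
        c80 = 1.0 if cond == "80:20" else 0.0
        c50 = 1.0 if cond == "50:50" else 0.0
        for tc in t:
            X.append([1.0, tc, c80, c50, tc * c80, tc * c50])
    X = np.asarray(X)
    nodes, weights = np.polynomial.hermite_e.hermegauss(80)
    w_norm = weights / weights.sum()
    eta = X @ b
    p_marg = np.array(
        [np.sum(w_norm / (1.0 + np.exp(-(e + config.plate_sd * nodes)))) for e in eta]
    )

    def cross_entropy(bm):
        p = 1.0 / (1.0 + np.exp(-(X @ bm)))
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return -np.sum(p_marg * np.log(p) + (1 - p_marg) * np.log(1 - p))

    res = minimize(cross_entropy, b, method="BFGS", options={"gtol": 1e-12})
    return res.x


def simulate_occurrence(config: OccurrenceSimConfig) -> pd.DataFrame:
    """Simulate a plate-level occurrence table with known GEE coefficients.

    Returns a DataFrame with columns plate_id, condition, week, n_wells,
    n_oscillating.  Weeks in the output are the raw (uncentered) weeks;
    the design-matrix builder re-centers them, matching the generative
    centering used here.
    """
    rng = np.random.default_rng(config.seed)
    b = np.asarray(config.beta, dtype=float)
    weeks = np.asarray(config.weeks, dtype=float)
    t_centered = weeks - weeks.mean()
    rows = []
    plate_counter = 0
    for ci, cond in enumerate(CONDITIONS):
        c80 = 1.0 if cond == "80:20" else 0.0
        c50 = 1.0 if cond == "50:50" else 0.0
        for _ in range(config.n_plates_per_condition):
            plate_counter += 1
            plate_id = f"P{plate_counter:03d}"
            u = rng.normal(0, config.plate_sd) if config.plate_sd > 0 else 0.0
            n_wells = int(rng.integers(config.wells_per_plate[0], config.wells_per_plate[1] + 1))
            for week, t in zip(weeks, t_centered):
                eta = (
                    b[0] + b[1] * t + b[2] * c80 + b[3] * c50
                    + b[4] * t * c80 + b[5] * t * c50 + u
                )
                p = 1.0 / (1.0 + np.exp(-eta))
                k = int(rng.binomial(n_wells, p))
                rows.append((plate_id, cond, float(week), n_wells, k))
    return pd.DataFrame(
        rows, columns=["plate_id", "condition", "week", "n_wells", "n_oscillating"]
    )
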