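"""Spike-train burst and network-burst detectors and pairwise synchrony.

Two parameter sets mirror common MEA practice: (1) Poisson-surprise
single-electrode bursts with envelope-based network bursts, and (2)
ISI-threshold bursts (min 5 spikes, max ISI 100 ms) with pooled-train
ISI network bursts (min 10 spikes, max pooled ISI 10 ms, ≥25% of active
electrodes).  An electrode is active at ≥5 spikes/min.

The vendor definitions of the envelope network-burst "burst inclusion"
rule and of the synchrony index are proprietary; the versions here are
explicit, documented approximations (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.stats import poisson

from meaosc.spike_io import WellRecording


@dataclass
class BurstEvent:
    electrode_id: str
    start: float
    end: float
    n_spikes: int
    surprise: Optional[float] = None

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("burst must have end >= start")


@dataclass
class NetworkBurstEvent:
    start: float
    end: float
    n_spikes: int
    participating_electrodes: frozenset
    method: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("network burst must have end > start")


def active_electrodes(recording: WellRecording, min_rate: float = 5.0) -> set[str]:
    """Electrodes firing at >= min_rate spikes per minute."""
    minutes = recording.duration / 60.0
    return {
        eid
        for eid, times in recording.electrode_spikes.items()
        if times.size / minutes >= min_rate
    }


def detect_bursts_isi(
    spike_times: np.ndarray,
    min_spikes: int = 5,
    max_isi: float = 0.100,
    electrode_id: str = "",
) -> list[BurstEvent]:
    """Maximal runs of spikes whose every ISI is <= max_isi, run >= min_spikes."""
    t = np.asarray(spike_times, dtype=float)
    if t.size < min_spikes:
        return []
    close = np.diff(t) <= max_isi
    bursts = []
    i = 0
    while i < close.size:
        if close[i]:
            j = i
            while j < close.size and close[j]:
                j += 1
            n = j - i + 1  # spikes i..j inclusive
            if n >= min_spikes:
                bursts.append(
                    BurstEvent(electrode_id, float(t[i]), float(t[j]), n)
                )
            i = j
        else:
            i += 1
    return bursts


def poisson_surprise(n: int, t_span: float, rate: float) -> float:
    """Poisson surprise S = -log10 P(>= n spikes in t_span | rate).

    Computed from the exact Poisson upper tail at high precision
    (``logsf``).  Base-10 logarithm: S = 5 then means P < 1e-5, the
    stringency a min-surprise-5 acceptance implies; the natural-log
    reading (P < 6.7e-3) would accept several spurious bursts in every
    few minutes of a homogeneous Poisson train.
    """
    if n <= 1 or t_span < 0 or rate <= 0:
        return 0.0
    return float(-poisson.logsf(n - 1, rate * t_span) / np.log(10))


def detect_bursts_surprise(
    spike_times: np.ndarray,
    duration: float,
    min_surprise: float = 5.0,
    electrode_id: str = "",
) -> list[BurstEvent]:
    """Poisson-surprise (Legéndy–Salcman style) burst detection.

    Candidate seeds are maximal runs of at least three consecutive ISIs
    below half the train's mean ISI.  Each seed is greedily extended
    forward while adding the next spike increases the surprise, then
    trimmed from the front while removal increases it (extension runs
    forward, so the stale end is the front), never below three spikes.  Bursts with surprise >= ``min_surprise`` are
    accepted; the search resumes after the last accepted spike, so
    output bursts never overlap.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    t = np.asarray(spike_times, dtype=float)
    if t.size < 2:
        return []
    rate = t.size / duration
    isi = np.diff(t)
    mean_isi = isi.mean()
    short = isi < mean_isi / 2.0

    bursts: list[BurstEvent] = []
    i = 0
    while i < short.size:
        if not short[i]:
            i += 1
            continue
        j = i
        while j < short.size and short[j]:
            j += 1
        # seed spans spikes i..j (j - i ISIs); require >= 3 short ISIs
        if j - i < 3:
            i = j
            continue
        a, b = i, j  # spike indices of current burst [a, b]
        s = poisson_surprise(b - a + 1, t[b] - t[a], rate)
        # extend forward while surprise increases
        while b + 1 < t.size:
            s_new = poisson_surprise(b + 2 - a, t[b + 1] - t[a], rate)
            if s_new > s:
                b += 1
                s = s_new
            else:
                break
        # trim from the front while surprise increases (keep >= 3 spikes)
        while b - a + 1 > 3:
            s_new = poisson_surprise(b - a, t[b] - t[a + 1], rate)
            if s_new > s:
                a += 1
                s = s_new
            else:
                break
        if s >= min_surprise:
            bursts.append(
                BurstEvent(electrode_id, float(t[a]), float(t[b]), b - a + 1, s)
            )
            i = b  # resume after the burst
        else:
            i = j
    return bursts


def _pooled_train(
    recording: WellRecording, active: set[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Merge active electrodes' spikes; ties in time break by electrode id."""
    eids = sorted(active)
    if not eids:
        return np.empty(0), np.empty(0, dtype=int)
    times = np.concatenate([recording.electrode_spikes[e] for e in eids])
    elec = np.concatenate(
        [np.full(recording.electrode_spikes[e].size, k) for k, e in enumerate(eids)]
    )
    order = np.lexsort((elec, times))
    return times[order], elec[order]


def detect_network_bursts_isi(
    recording: WellRecording,
    min_spikes: int = 10,
    max_isi: float = 0.010,
    min_electrode_frac: float = 0.25,
    min_rate: float = 5.0,
) -> list[NetworkBurstEvent]:
    """ISI-threshold network bursts on the pooled active-electrode train."""
    active = active_electrodes(recording, min_rate)
    if not active:
        return []
    eids = sorted(active)
    times, elec = _pooled_train(recording, active)
    raw = detect_bursts_isi(times, min_spikes, max_isi)
    nbs = []
    for b in raw:
        if b.end <= b.start:  # all spikes simultaneous — degenerate run
            continue
        mask = (times >= b.start) & (times <= b.end)
        members = frozenset(eids[k] for k in np.unique(elec[mask]))
        if len(members) / len(active) >= min_electrode_frac:
            nbs.append(
                NetworkBurstEvent(b.start, b.end, int(mask.sum()), members, "isi")
            )
    return nbs


def detect_network_bursts_envelope(
    recording: WellRecording,
    threshold_factor: float = 2.0,
    min_ibi: float = 1.0,
    min_electrode_frac: float = 0.25,
    burst_inclusion: float = 0.75,
    smoothing: float = 0.1,
    bin_width: float = 0.010,
    min_rate: float = 5.0,
) -> list[NetworkBurstEvent]:
    """Envelope-threshold network bursts.

    The pooled firing-rate histogram (10 ms bins) is Gaussian-smoothed
    (``smoothing`` seconds); candidates are regions above
    ``threshold_factor`` times the recording-mean rate; candidates closer
    than ``min_ibi`` are merged; each candidate's boundaries are expanded
    symmetrically within its territory (midway to the neighbouring
    candidates) until it contains at least ``burst_inclusion`` of the
    territory's spikes; finally the electrode-participation filter
    applies.
    """
    active = active_electrodes(recording, min_rate)
    if not active:
        return []
    eids = sorted(active)
    times, elec = _pooled_train(recording, active)
    if times.size == 0:
        return []
    n_bins = int(np.ceil(recording.duration / bin_width))
    hist = np.bincount(
        np.minimum(np.floor(times / bin_width).astype(int), n_bins - 1),
        minlength=n_bins,
    ).astype(float)
    smoothed = gaussian_filter1d(hist, smoothing / bin_width, mode="reflect")
    threshold = threshold_factor * smoothed.mean()

    above = smoothed > threshold
    if not above.any():
        return []
    d = np.diff(np.concatenate(([0], above.astype(np.int8), [0])))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    # merge candidates separated by less than min_ibi
    merged: list[list[int]] = []
    for s0, s1 in zip(starts, stops):
        if merged and (s0 - merged[-1][1]) * bin_width < min_ibi:
            merged[-1][1] = s1
        else:
            merged.append([s0, s1])

    # territory bounds: midway to neighbouring candidates (bin indices)
    bounds = []
    for k, (s0, s1) in enumerate(merged):
        left = 0 if k == 0 else (merged[k - 1][1] + s0) // 2
        right = n_bins if k == len(merged) - 1 else (s1 + merged[k + 1][0]) // 2
        bounds.append((left, right))

    nbs = []
    for (s0, s1), (left, right) in zip(merged, bounds):
        territory = (times >= left * bin_width) & (times < right * bin_width)
        n_territory = int(territory.sum())
        if n_territory == 0:
            continue
        lo, hi = s0, s1
        while True:
            inside = (times >= lo * bin_width) & (times < hi * bin_width)
            if inside.sum() >= burst_inclusion * n_territory:
                break
            grew = False
            if lo > left:
                lo -= 1
                grew = True
            if hi < right:
                hi += 1
                grew = True
            if not grew:
                break
        inside = (times >= lo * bin_width) & (times < hi * bin_width)
        members = frozenset(eids[k] for k in np.unique(elec[inside]))
        if len(members) / len(active) >= min_electrode_frac:
            nbs.append(
                NetworkBurstEvent(
                    lo * bin_width,
                    hi * bin_width,
                    int(inside.sum()),
                    members,
                    "envelope",
                )
            )
    return nbs


def synchrony_index(
    recording: WellRecording,
    window: float = 0.020,
    broad: float = 1.0,
    min_rate: float = 5.0,
) -> float:
    """Pairwise cross-correlation synchrony in [0, 1].

    For every pair of active electrodes, the fraction of cross-spike
    intervals with |Δt| <= ``window`` relative to those with
    |Δt| <= ``broad`` (±1 s correlogram area), averaged over pairs.
    Near 1 for identical sparse trains; about ``window/broad`` for
    independent stationary trains.
    """
    active = sorted(active_electrodes(recording, min_rate))
    if len(active) < 2:
        raise ValueError("synchrony index needs at least 2 active electrodes")

    def _count_within(a: np.ndarray, b: np.ndarray, w: float) -> int:
        hi = np.searchsorted(b, a + w, side="right")
        lo = np.searchsorted(b, a - w, side="left")
        return int(np.sum(hi - lo))

    vals = []
    for i in range(len(active)):
        for j in range(i + 1, len(active)):
            a = recording.electrode_spikes[active[i]]
            b = recording.electrode_spikes[active[j]]
            n_broad = _count_within(a, b, broad)
            if n_broad == 0:
                continue
            vals.append(_count_within(a, b, window) / n_broad)
    if not vals:
        return 0.0
    return float(np.mean(vals))
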