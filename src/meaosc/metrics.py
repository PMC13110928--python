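"""Per-well summary metrics and treatment comparisons.

Per band: event count, mean duration, occurrence rate (events/minute),
spectral means (peak frequency, aperiodic-corrected peak power, offset,
exponent) over events with fits, and the percentage of network bursts
that carry at least one oscillation event in the band.  Spike-train
metrics (spikes per burst/NB, durations, ISI coefficient of variation,
burst %, NB %, weighted mean firing rate) summarize overall activity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from meaosc.burst_detection import BurstEvent, NetworkBurstEvent, active_electrodes
from meaosc.oscillation_detection import OscillationEvent
from meaosc.spike_io import WellRecording


@dataclass
class WellBandMetrics:
    well_id: str
    band: str
    n_events: int
    mean_duration: Optional[float]
    occurrence_rate: float
    mean_peak_freq: Optional[float]
    mean_peak_power: Optional[float]
    mean_offset: Optional[float]
    mean_exponent: Optional[float]
    pct_oscillatory_nbs: Optional[float]


def _mean_or_none(values: list[float]) -> Optional[float]:
    return float(np.mean(values)) if values else None


def _overlaps(a0: float, a1: float, b0: float, b1: float) -> bool:
    """Any positive overlap between intervals [a0,a1] and [b0,b1]."""
    return min(a1, b1) > max(a0, b0)


def summarize_well(
    events_by_band: Mapping[str, Sequence[OscillationEvent]],
    network_bursts: Sequence[NetworkBurstEvent],
    recording: WellRecording,
) -> list[WellBandMetrics]:
    """One :class:`WellBandMetrics` per band, for one well."""
    minutes = recording.duration / 60.0
    out = []
    for band, events in events_by_band.items():
        durations = [ev.duration for ev in events]
        fitted = [ev for ev in events if ev.offset is not None]
        peaked = [ev for ev in events if ev.peak_freq is not None]
        if network_bursts:
            n_osc_nb = sum(
                1
                for nb in network_bursts
                if any(_overlaps(nb.start, nb.end, ev.start, ev.end) for ev in events)
            )
            pct = 100.0 * n_osc_nb / len(network_bursts)
        else:
            pct = None
        out.append(
            WellBandMetrics(
                well_id=recording.well_id,
                band=band,
                n_events=len(events),
                mean_duration=_mean_or_none(durations),
                occurrence_rate=len(events) / minutes,
                mean_peak_freq=_mean_or_none([ev.peak_freq for ev in peaked]),
                mean_peak_power=_mean_or_none([ev.peak_power for ev in peaked]),
                mean_offset=_mean_or_none([ev.offset for ev in fitted]),
                mean_exponent=_mean_or_none([ev.exponent for ev in fitted]),
                pct_oscillatory_nbs=pct,
            )
        )
    return out


def metrics_table(metrics: Iterable[WellBandMetrics]) -> pd.DataFrame:
    """Stack per-well metrics into one row per (well, band)."""
    return pd.DataFrame([vars(m) for m in metrics])


def percent_change(baseline: float, post: float) -> Optional[float]:
    """100 × (post − baseline)/baseline; None (with a warning) at baseline <= 0."""
    if baseline is None or post is None or not np.isfinite(baseline) or baseline <= 0:
        warnings.warn("percent_change undefined for non-positive baseline")
        return None
    return 100.0 * (post - baseline) / baseline


def nb_spike_metrics(
    recording: WellRecording,
    network_bursts: Sequence[NetworkBurstEvent],
    bursts: Sequence[BurstEvent],
    min_rate: float = 5.0,
) -> dict:
    """Spike-train summary metrics for one well.

    WMFR (weighted mean firing rate) is total spikes over duration times
    the number of active electrodes — a documented approximation of the
    vendor metric, whose exact formula is not public.
    """
    total = recording.n_spikes
    pooled = recording.all_spikes()
    active = active_electrodes(recording, min_rate)

    def _spikes_in(intervals: Sequence) -> int:
        n = 0
        for iv in intervals:
            n += int(
                np.searchsorted(pooled, iv.end, side="right")
                - np.searchsorted(pooled, iv.start, side="left")
            )
        return n

    spikes_in_nbs = _spikes_in(network_bursts)
    # electrode bursts: count each burst's spikes on its own electrode
    spikes_in_bursts = sum(b.n_spikes for b in bursts)

    isis = np.concatenate(
        [np.diff(t) for t in recording.electrode_spikes.values() if t.size >= 2]
    ) if any(t.size >= 2 for t in recording.electrode_spikes.values()) else np.empty(0)

    return {
        "well_id": recording.well_id,
        "spikes_per_nb": float(np.mean([nb.n_spikes for nb in network_bursts]))
        if network_bursts
        else None,
        "nb_duration_mean": float(np.mean([nb.end - nb.start for nb in network_bursts]))
        if network_bursts
        else None,
        "spikes_per_burst": float(np.mean([b.n_spikes for b in bursts]))
        if bursts
        else None,
        "burst_duration_mean": float(np.mean([b.end - b.start for b in bursts]))
        if bursts
        else None,
        "isi_cov": float(np.std(isis) / np.mean(isis)) if isis.size else None,
        "burst_pct": 100.0 * spikes_in_bursts / total if total else None,
        "nb_pct": 100.0 * spikes_in_nbs / total if total else None,
        "wmfr": total / (recording.duration * len(active)) if active else None,
    }


def oscillating_wells(
    events_by_well_week: Mapping[tuple[str, float], int],
    eligible_wells: Iterable[str],
    well_info: Mapping[str, tuple[str, str]],
    weeks: Sequence[float],
    min_events: int = 1,
) -> pd.DataFrame:
    """Plate-level oscillating-well fractions by week.

    ``events_by_well_week`` maps (well_id, week) to the well's event
    count (any band) that week.  Only wells in ``eligible_wells`` (those
    with network bursting at the final week) enter numerators and
    denominators.  ``well_info`` maps well_id to (plate_id, condition).
    A well oscillates at a week when its event count >= ``min_events``.
    """
    eligible = sorted(set(eligible_wells))
    rows = []
    plates: dict[tuple[str, str], list[str]] = {}
    for w in eligible:
        plate, cond = well_info[w]
        plates.setdefault((plate, cond), []).append(w)
    for (plate, cond), wells in sorted(plates.items()):
        for week in weeks:
            n_osc = sum(
                1
                for w in wells
                if events_by_well_week.get((w, week), 0) >= min_events
            )
            rows.append((plate, cond, float(week), len(wells), n_osc))
    return pd.DataFrame(
        rows, columns=["plate_id", "condition", "week", "n_wells", "n_oscillating"]
    )
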