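"""Readers and writers for spike lists, event tables and result tables.

The spike-list dialect is a plain UTF-8 CSV with columns ``well``,
``electrode``, ``time_s`` — the least-common-denominator of AxIS-style
spike exports.  Times are seconds from recording start, half-open
``[0, duration)``.  All writers produce deterministic column orders so
that round-trips and byte-level comparisons are meaningful.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

SPIKE_COLUMNS = ["well", "electrode", "time_s"]

EVENT_COLUMNS = [
    "well_id",
    "band",
    "start_s",
    "end_s",
    "duration_s",
    "n_cycles",
    "peak_envelope",
    "peak_freq_hz",
    "peak_power",
    "offset",
    "exponent",
]

OCCURRENCE_COLUMNS = ["plate_id", "condition", "week", "n_wells", "n_oscillating"]


@dataclass
class WellRecording:
    """All spike times for one well over one recording session.

    ``electrode_spikes`` maps electrode id to a sorted array of spike
    times in seconds.  ``metadata`` carries free-form context such as
    condition label, plate id, weeks post-plating, or — for simulated
    wells — the injected ground truth.
    """

    well_id: str
    electrode_spikes: dict[str, np.ndarray]
    duration: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"duration must be positive, got {self.duration}")
        if len(self.electrode_spikes) < 1:
            raise ValueError("a recording needs at least one electrode")
        clean: dict[str, np.ndarray] = {}
        for eid, times in self.electrode_spikes.items():
            t = np.asarray(times, dtype=float)
            if t.size and (t.min() < 0 or t.max() >= self.duration + 1e-9):
                raise ValueError(
                    f"electrode {eid}: spike times must lie in [0, {self.duration})"
                )
            if t.size and np.any(np.diff(t) < 0):
                raise ValueError(f"electrode {eid}: spike times must be sorted")
            clean[eid] = t
        self.electrode_spikes = clean

    @property
    def n_electrodes(self) -> int:
        return len(self.electrode_spikes)

    @property
    def n_spikes(self) -> int:
        return int(sum(t.size for t in self.electrode_spikes.values()))

    def all_spikes(self) -> np.ndarray:
        """Pooled, time-sorted spike times across all electrodes."""
        if self.n_spikes == 0:
            return np.empty(0)
        return np.sort(np.concatenate(list(self.electrode_spikes.values())))


def read_spike_list(
    path: str | Path,
    well_filter: Iterable[str] | None = None,
    duration: float | Mapping[str, float] | None = None,
) -> list[WellRecording]:
    """Read a spike-list CSV into one :class:`WellRecording` per well.

    Parameters
    ----------
    path:
        CSV with header columns ``well``, ``electrode``, ``time_s``.
        An optional ``duration_s`` column (constant per well) is honoured.
    well_filter:
        If given, only wells in this collection are returned.
    duration:
        Recording duration in seconds, either one number for all wells or
        a mapping well id → duration.  When absent, the duration defaults
        to the well's last spike time rounded up to a whole second.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"well": str, "electrode": str})
    missing = [c for c in SPIKE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    times = pd.to_numeric(df["time_s"], errors="coerce")
    bad = np.flatnonzero(~np.isfinite(times.to_numpy()))
    if bad.size:
        # +2: one for the header row, one for 1-based line numbering
        raise ValueError(f"{path}: unparseable time_s at line {bad[0] + 2}")
    neg = np.flatnonzero(times.to_numpy() < 0)
    if neg.size:
        raise ValueError(f"{path}: negative spike time at line {neg[0] + 2}")
    df["time_s"] = times

    if well_filter is not None:
        keep = set(well_filter)
        df = df[df["well"].isin(keep)]

    recordings = []
    for well_id, wdf in df.groupby("well", sort=True):
        if duration is None:
            if "duration_s" in wdf.columns and wdf["duration_s"].notna().any():
                dur = float(wdf["duration_s"].dropna().iloc[0])
            else:
                dur = float(np.ceil(wdf["time_s"].max()))
                if dur <= wdf["time_s"].max():
                    dur += 1.0
        elif isinstance(duration, Mapping):
            dur = float(duration[well_id])
        else:
            dur = float(duration)
        electrode_spikes = {
            str(eid): np.sort(edf["time_s"].to_numpy())
            for eid, edf in wdf.groupby("electrode", sort=True)
        }
        recordings.append(WellRecording(str(well_id), electrode_spikes, dur))
    return recordings


def write_spike_list(recordings: Sequence[WellRecording], path: str | Path) -> None:
    """Write recordings to the spike-list CSV dialect (lossless to 1e-6 s)."""
    rows = []
    for rec in recordings:
        for eid in sorted(rec.electrode_spikes):
            for t in rec.electrode_spikes[eid]:
                rows.append((rec.well_id, eid, t, rec.duration))
    df = pd.DataFrame(rows, columns=SPIKE_COLUMNS + ["duration_s"])
    df.to_csv(path, index=False, float_format="%.6f")


def write_events(events: Sequence, path: str | Path) -> None:
    """Write oscillation events as CSV; zero events yields a header-only file."""
    rows = []
    for ev in events:
        d = dataclasses.asdict(ev)
        rows.append(
            {
                "well_id": d["well_id"],
                "band": d["band"],
                "start_s": d["start"],
                "end_s": d["end"],
                "duration_s": d["duration"],
                "n_cycles": d["n_cycles"],
                "peak_envelope": d["peak_envelope"],
                "peak_freq_hz": d.get("peak_freq"),
                "peak_power": d.get("peak_power"),
                "offset": d.get("offset"),
                "exponent": d.get("exponent"),
            }
        )
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing event columns {missing}")
    return df


def write_metrics(table: pd.DataFrame, path: str | Path) -> None:
    """Write a metrics table with stable column order (as constructed)."""
    table.to_csv(path, index=False)


def write_occurrence_table(table: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in OCCURRENCE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"occurrence table missing columns {missing}")
    table[OCCURRENCE_COLUMNS].to_csv(path, index=False)


def read_occurrence_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"plate_id": str, "condition": str})
    missing = [c for c in OCCURRENCE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing occurrence columns {missing}")
    if ((df["n_oscillating"] < 0) | (df["n_oscillating"] > df["n_wells"])).any():
        raise ValueError(f"{path}: n_oscillating must lie in [0, n_wells]")
    return df
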