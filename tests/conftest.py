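"""Shared fixtures and independent brute-force oracles.

The oracle implementations here deliberately use plain-Python scans and
direct arithmetic, independent of the vectorized implementations they
check.
"""

from __future__ import annotations

import numpy as np
import pytest

from meaosc.spike_io import WellRecording


@pytest.fixture
def tiny_recording() -> WellRecording:
    """Three electrodes, hand-placed spikes, 10 s."""
    return WellRecording(
        well_id="T1",
        electrode_spikes={
            "E01": np.array([0.1, 0.2, 0.3, 5.0]),
            "E02": np.array([0.15, 2.0, 2.05, 2.1]),
            "E03": np.array([9.5]),
        },
        duration=10.0,
    )


def oracle_dual_threshold(
    env: np.ndarray,
    lo: float,
    hi: float,
    fs: float,
    max_gap_s: float,
    min_duration_s: float,
) -> list[tuple[int, int]]:
    """Exhaustive scan for the dual-threshold detector.

    Returns half-open sample-index intervals of accepted events:
    maximal runs strictly above ``lo``, merged when separated by at most
    ``max_gap_s``, kept when their maximum exceeds ``hi`` strictly and
    their length is at least ``min_duration_s``.
    """
    runs = []
    in_run = False
    for i, v in enumerate(env):
        if v > lo and not in_run:
            start = i
            in_run = True
        elif v <= lo and in_run:
            runs.append((start, i))
            in_run = False
    if in_run:
        runs.append((start, len(env)))

    merged: list[list[int]] = []
    for s, e in runs:
        if merged and (s - merged[-1][1]) / fs <= max_gap_s:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    events = []
    for s, e in merged:
        if max(env[s:e]) <= hi:
            continue
        if (e - s) / fs < min_duration_s:
            continue
        events.append((s, e))
    return events


def oracle_isi_bursts(
    times: np.ndarray, min_spikes: int, max_isi: float
) -> list[tuple[int, int]]:
    """Exhaustive scan for ISI-threshold bursts; (first, last) spike indices."""
    out = []
    n = len(times)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and times[j + 1] - times[j] <= max_isi:
            j += 1
        if j - i + 1 >= min_spikes:
            out.append((i, j))
        i = j + 1
    return out
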