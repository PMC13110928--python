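"""Per-well metrics and the plate-level oscillating-well occurrence table.

Computes the per-band summary metrics (event counts, durations,
occurrence rates, spectral means, percent oscillatory network bursts)
and the spike-train metrics, then assembles a plate-level occurrence
table from the simulated wells (wells grouped into plates of 5).

    python analysis/04_summarize_metrics.py --results results/
"""

import argparse
from pathlib import Path

import pandas as pd

from meaosc.burst_detection import detect_bursts_isi, detect_network_bursts_isi
from meaosc.metrics import (
    metrics_table,
    nb_spike_metrics,
    oscillating_wells,
    summarize_well,
)
from meaosc.oscillation_detection import DEFAULT_BANDS, detect_all_bands
from meaosc.population_signal import spike_density
from meaosc.spectral_param import event_spectra
from meaosc.spike_io import read_spike_list, write_metrics, write_occurrence_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    recordings = read_spike_list(args.results / "spikes_modulated.csv")
    all_metrics, nb_rows = [], []
    events_by_well = {}
    eligible = set()
    for rec in recordings:
        sig = spike_density(rec)
        by_band = {
            band: event_spectra(sig, evs, DEFAULT_BANDS)
            for band, evs in detect_all_bands(sig).items()
        }
        nbs = detect_network_bursts_isi(rec)
        bursts = [
            b
            for eid, t in rec.electrode_spikes.items()
            for b in detect_bursts_isi(t, electrode_id=eid)
        ]
        all_metrics.extend(summarize_well(by_band, nbs, rec))
        nb_rows.append(nb_spike_metrics(rec, nbs, bursts))
        events_by_well[(rec.well_id, 6.0)] = sum(len(v) for v in by_band.values())
        if nbs:
            eligible.add(rec.well_id)

    write_metrics(metrics_table(all_metrics), args.results / "well_band_metrics.csv")
    write_metrics(pd.DataFrame(nb_rows), args.results / "spike_metrics.csv")

    # group wells into plates of 5 for the occurrence table
    well_info = {
        rec.well_id: (f"P{(i // 5) + 1:02d}", "iGluta-alone")
        for i, rec in enumerate(recordings)
    }
    occurrence = oscillating_wells(events_by_well, eligible, well_info, weeks=[6.0])
    write_occurrence_table(occurrence, args.results / "occurrence_observed.csv")

    m = metrics_table(all_metrics)
    theta = m[m.band == "theta"]
    print(f"wells: {len(recordings)}; NB-eligible: {len(eligible)}")
    print(
        f"theta: {theta.n_events.sum()} events, "
        f"occurrence {theta.occurrence_rate.mean():.2f}/min, "
        f"mean duration {theta.mean_duration.mean():.2f} s, "
        f"oscillatory NBs {theta.pct_oscillatory_nbs.mean():.1f}%"
    )


if __name__ == "__main__":
    main()
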