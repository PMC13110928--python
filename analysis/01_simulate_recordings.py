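"""Simulate the synthetic MEA dataset the downstream analyses consume.

Generates 20 wells with 5 Hz theta-range rate modulation nested in slow
network bursts, plus matched unmodulated surrogate wells sharing the
same background seeds, and writes spike lists plus the injected ground
truth.

    python analysis/01_simulate_recordings.py --seed 1 --out results/
"""

import argparse
import json
from pathlib import Path

import numpy as np

from meaosc.spike_io import write_spike_list
from meaosc.synthetic_data import SpikeSimConfig, simulate_well


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--n-wells", type=int, default=20)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    seeds = [
        int(s % (2**31))
        for s in np.random.SeedSequence(args.seed).generate_state(args.n_wells)
    ]
    modulated, surrogate, truth = [], [], {}
    for w, s in enumerate(seeds):
        well_id = f"W{w + 1:02d}"
        rec = simulate_well(SpikeSimConfig(seed=s), well_id=well_id)
        sur = simulate_well(
            SpikeSimConfig(seed=s, modulation_depth=0.0), well_id=well_id
        )
        modulated.append(rec)
        surrogate.append(sur)
        truth[well_id] = {"seed": s, "injected_nbs": rec.metadata["injected_nbs"]}

    write_spike_list(modulated, args.out / "spikes_modulated.csv")
    write_spike_list(surrogate, args.out / "spikes_surrogate.csv")
    with open(args.out / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)

    n_spikes = sum(r.n_spikes for r in modulated)
    n_nbs = sum(len(v["injected_nbs"]) for v in truth.values())
    print(
        f"simulated {len(modulated)} wells ({n_spikes} spikes, "
        f"{n_nbs} injected network bursts) -> {args.out}"
    )


if __name__ == "__main__":
    main()
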