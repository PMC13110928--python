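import numpy as np
import pytest
from scipy.stats import poisson

from conftest import oracle_isi_bursts
from meaosc.burst_detection import (
    active_electrodes,
    detect_bursts_isi,
    detect_bursts_surprise,
    detect_network_bursts_envelope,
    detect_network_bursts_isi,
    poisson_surprise,
    synchrony_index,
)
from meaosc.spike_io import WellRecording
from meaosc.synthetic_data import SpikeSimConfig, simulate_well


def _rec(times_by_electrode, duration):
    return WellRecording(
        "W", {k: np.asarray(v, float) for k, v in times_by_electrode.items()}, duration
    )


class TestActiveElectrodes:
    def test_exactly_five_per_minute_is_active(self):
        # 25 spikes in 300 s = 5/min; the >= criterion passes
        rec = _rec(
            {"E01": np.linspace(1, 290, 25), "E02": np.linspace(1, 290, 24), "E03": []},
            300.0,
        )
        assert active_electrodes(rec) == {"E01"}


class TestIsiBursts:
    def test_six_spikes_at_50ms(self):
        t = np.arange(6) * 0.05
        bursts = detect_bursts_isi(t)
        assert len(bursts) == 1
        assert bursts[0].n_spikes == 6
        assert bursts[0].start == 0.0 and bursts[0].end == pytest.approx(0.25)

    def test_four_spikes_insufficient(self):
        assert detect_bursts_isi(np.arange(4) * 0.05) == []

    def test_oracle_equivalence_on_poisson_trains(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = int(rng.integers(0, 1000))
            t = np.sort(rng.uniform(0, 100, n))
            got = [(b.start, b.end, b.n_spikes) for b in detect_bursts_isi(t)]
            exp = [
                (t[i], t[j], j - i + 1) for i, j in oracle_isi_bursts(t, 5, 0.100)
            ]
            assert got == exp


class TestSurpriseBursts:
    def test_surprise_matches_direct_poisson_tail(self):
        """S agrees with an independent high-precision tail computation."""
        from mpmath import mp, mpf, e, exp as mpexp, power, factorial

        mp.dps = 50
        for n, T, rate in [(20, 0.1, 1.0), (10, 0.5, 2.0), (5, 0.2, 1.5)]:
            lam = mpf(rate) * mpf(T)
            p = 1 - sum(mpexp(-lam) * power(lam, k) / factorial(k) for k in range(n - 1 + 1))
            expected = -float(mp.log(p, 10))
            assert poisson_surprise(n, T, rate) == pytest.approx(expected, rel=1e-9)

    def test_planted_burst_always_found(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            bg = np.sort(rng.uniform(0, 300, rng.poisson(300)))
            planted = np.sort(rng.uniform(150.0, 150.1, 20))
            t = np.sort(np.concatenate([bg, planted]))
            bursts = [
                b
                for b in detect_bursts_surprise(t, 300.0)
                if b.start <= 150.1 and b.end >= 150.0
            ]
            assert bursts
            best = max(bursts, key=lambda b: b.surprise)
            inside = np.sum((planted >= best.start) & (planted <= best.end))
            assert inside >= 18
            assert best.surprise > 5

    def test_regular_train_has_no_bursts(self):
        assert detect_bursts_surprise(np.arange(0, 300, 1.0), 300.0) == []

    def test_outputs_sorted_nonoverlapping(self):
        rng = np.random.default_rng(9)
        parts = [np.sort(rng.uniform(k * 30, k * 30 + 0.5, 30)) for k in range(5)]
        t = np.sort(np.concatenate([np.sort(rng.uniform(0, 300, 100))] + parts))
        bursts = detect_bursts_surprise(t, 300.0)
        assert len(bursts) >= 4
        for a, b in zip(bursts, bursts[1:]):
            assert a.end < b.start


class TestNetworkBurstsIsi:
    def test_pooled_burst_across_electrodes(self):
        # 12 pooled spikes at 5 ms spacing over 8 of 16 electrodes
        pooled = np.arange(12) * 0.005 + 10.0
        spikes = {f"E{i:02d}": [] for i in range(1, 17)}
        for k, t in enumerate(pooled):
            spikes[f"E{(k % 8) + 1:02d}"].append(t)
        # keep every electrode active with sparse background activity
        rng = np.random.default_rng(1)
        for i in range(1, 17):
            spikes[f"E{i:02d}"] += list(rng.uniform(20, 290, 30))
        rec = _rec({k: np.sort(v) for k, v in spikes.items()}, 300.0)
        nbs = detect_network_bursts_isi(rec)
        assert len(nbs) == 1
        assert len(nbs[0].participating_electrodes) == 8

    def test_single_electrode_run_fails_participation(self):
        rng = np.random.default_rng(2)
        spikes = {
            f"E{i:02d}": sorted(rng.uniform(20, 290, 30)) for i in range(1, 17)
        }
        spikes["E01"] = sorted(spikes["E01"] + list(np.arange(12) * 0.005 + 10.0))
        rec = _rec(spikes, 300.0)
        nbs = detect_network_bursts_isi(rec)
        assert all(not (nb.start >= 9.9 and nb.end <= 10.2) for nb in nbs)

    def test_oracle_equivalence_on_random_trains(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            n_elec = int(rng.integers(4, 9))
            spikes = {
                f"E{i:02d}": np.sort(rng.uniform(0, 60, int(rng.integers(50, 150))))
                for i in range(1, n_elec + 1)
            }
            rec = _rec(spikes, 60.0)
            active = sorted(active_electrodes(rec))
            pooled = np.sort(np.concatenate([spikes[e] for e in active]))
            expected = []
            for i, j in oracle_isi_bursts(pooled, 10, 0.010):
                members = {
                    e
                    for e in active
                    if np.any((spikes[e] >= pooled[i]) & (spikes[e] <= pooled[j]))
                }
                if len(members) / len(active) >= 0.25:
                    expected.append((pooled[i], pooled[j]))
            got = [(nb.start, nb.end) for nb in detect_network_bursts_isi(rec)]
            assert got == expected


class TestNetworkBurstsEnvelope:
    def test_recovers_injected_nb_count(self):
        """Detected NB count within +-10% of injected, over seeds."""
        inj = det = 0
        for seed in range(5):
            rec = simulate_well(SpikeSimConfig(seed=seed))
            inj += len(rec.metadata["injected_nbs"])
            det += len(detect_network_bursts_envelope(rec))
        assert abs(det - inj) / inj <= 0.10

    def test_stationary_background_yields_no_nbs(self):
        none = 0
        for seed in range(10):
            rec = simulate_well(
                SpikeSimConfig(seed=seed, nb_rate=0.0, baseline_rate=5.0, duration=300)
            )
            none += len(detect_network_bursts_envelope(rec)) == 0
        assert none >= 9

    def test_close_bursts_merge(self):
        """Two rate bumps 0.5 s apart (< 1 s min IBI) report as one NB."""
        rng = np.random.default_rng(0)
        spikes = {}
        for i in range(1, 17):
            bg = rng.uniform(0, 60, 30)
            b1 = rng.uniform(20.0, 21.0, 40)
            b2 = rng.uniform(21.5, 22.5, 40)
            spikes[f"E{i:02d}"] = np.sort(np.concatenate([bg, b1, b2]))
        rec = _rec(spikes, 60.0)
        nbs = detect_network_bursts_envelope(rec)
        overlapping = [nb for nb in nbs if nb.end > 19.5 and nb.start < 23.0]
        assert len(overlapping) == 1


class TestSynchrony:
    def test_identical_single_spike_trains(self):
        spikes = {"E01": [10.0], "E02": [10.0]}
        rec = _rec(spikes, 60.0)
        assert synchrony_index(rec, min_rate=1.0) == pytest.approx(1.0)

    def test_independent_poisson_expectation(self):
        """Flat correlogram: index ~ window/broad = 0.02."""
        rng = np.random.default_rng(3)
        vals = []
        for _ in range(20):
            rec = _rec(
                {
                    "E01": np.sort(rng.uniform(0, 600, 600)),
                    "E02": np.sort(rng.uniform(0, 600, 600)),
                },
                600.0,
            )
            vals.append(synchrony_index(rec))
        assert np.mean(vals) == pytest.approx(0.02, abs=0.005)

    def test_jitter_monotonicity(self):
        """Increasing jitter never increases the index (in expectation)."""
        rng = np.random.default_rng(6)
        base = np.sort(rng.uniform(5, 595, 200))
        means = []
        for sd in (0.001, 0.05, 0.3):
            vals = []
            for _ in range(10):
                jit = np.sort(np.clip(base + rng.normal(0, sd, base.size), 0, 599.9))
                rec = _rec({"E01": base, "E02": jit}, 600.0)
                vals.append(synchrony_index(rec))
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]

    def test_needs_two_active(self):
        rec = _rec({"E01": np.linspace(1, 290, 50), "E02": []}, 300.0)
        with pytest.raises(ValueError):
            synchrony_index(rec)
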