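import numpy as np
import pytest

from hhspike.metrics import burst_index, classify_rate, mean_firing_rate
from hhspike.synth import (
    PopulationConfig,
    SyncPairParams,
    bursty_params_for,
    generate_bursty_train,
    generate_poisson_train,
    generate_population,
    generate_synchronous_pair,
    inject_discharge,
    render_trace,
)


class TestPoisson:
    def test_zero_rate_is_empty(self):
        assert generate_poisson_train(0.0, 300.0, 0).n_spikes == 0

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            generate_poisson_train(-1.0, 300.0, 0)

    def test_seed_determinism(self):
        a = generate_poisson_train(10.0, 300.0, 42)
        b = generate_poisson_train(10.0, 300.0, 42)
        assert np.array_equal(a.spike_times, b.spike_times)

    def test_mean_count_matches_rate(self):
        # law of large numbers: mean count over 500 trains within 3 SE of 3000
        counts = [
            generate_poisson_train(10.0, 300.0, s).n_spikes for s in range(500)
        ]
        se = np.sqrt(3000.0 / 500.0)
        assert abs(np.mean(counts) - 3000.0) < 3 * se


class TestBursty:
    def test_single_spike_bursts_reduce_to_poisson(self):
        # with one spike per burst the process is Poisson at the combined rate
        counts = [
            generate_bursty_train(5.0, 5.0, 1, 4.0, 300.0, s).n_spikes
            for s in range(100)
        ]
        assert abs(np.mean(counts) - 3000.0) < 3 * np.sqrt(3000.0 / 100.0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            generate_bursty_train(5.0, 1.0, 3, 12.0, 300.0, 0)  # intra ISI >= 10 ms
        with pytest.raises(ValueError):
            generate_bursty_train(-1.0, 1.0, 3, 4.0, 300.0, 0)

    def test_calibration_hits_target_bisi(self):
        bp = bursty_params_for(15.0, 0.39)
        vals = []
        for s in range(100):
            tr = generate_bursty_train(
                bp["baseline_rate"], bp["burst_rate"], bp["mean_spikes_per_burst"],
                bp["intra_burst_isi_ms"], 300.0, s,
            )
            vals.append(burst_index(tr))
        assert abs(np.median(vals) - 0.39) <= 0.1

    def test_class_target_medians_ordered(self):
        meds = []
        for target in (0.015, 0.18, 0.39):
            bp = bursty_params_for(5.0, target)
            vals = [
                burst_index(
                    generate_bursty_train(
                        bp["baseline_rate"], bp["burst_rate"],
                        bp["mean_spikes_per_burst"], bp["intra_burst_isi_ms"],
                        300.0, s,
                    )
                )
                for s in range(30)
            ]
            meds.append(np.median(vals))
        assert meds[0] < meds[1] < meds[2]


class TestSyncPair:
    def test_zero_copy_probs_independent(self):
        p = SyncPairParams(10.0, 0.0, 0.0, 1.0, 8.0, 8.0)
        a, b = generate_synchronous_pair(p, 300.0, 0)
        # no master copies: counts reflect the independent backgrounds only
        assert abs(a.n_spikes - 2400) < 5 * np.sqrt(2400)
        assert abs(b.n_spikes - 2400) < 5 * np.sqrt(2400)

    def test_full_copy_no_jitter_shares_master(self):
        p = SyncPairParams(10.0, 1.0, 1.0, 0.0, 0.0, 0.0)
        a, b = generate_synchronous_pair(p, 300.0, 1)
        assert np.array_equal(a.spike_times, b.spike_times)
        assert a.n_spikes > 0

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            SyncPairParams(10.0, 1.5, 0.5)

    def test_coincidence_surplus_matches_thinning_expectation(self):
        # copy probs (0.5, 0.5) of a 10 sp/s master: surplus 2.5 coincidences/s
        p = SyncPairParams(10.0, 0.5, 0.5, 1.0, 5.0, 5.0)
        surplus = []
        for s in range(25):
            a, b = generate_synchronous_pair(p, 300.0, s)
            # brute-force near-coincidence count within +/-4 ms (jitter sd 1 ms
            # per train catches ~99.5% of shared-spike offsets)
            idx = np.searchsorted(b.spike_times, a.spike_times)
            near = 0
            for t, i in zip(a.spike_times, idx):
                for j in (i - 1, i, i + 1):
                    if 0 <= j < b.n_spikes and abs(b.spike_times[j] - t) < 0.004:
                        near += 1
            ra, rb = a.n_spikes / 300.0, b.n_spikes / 300.0
            baseline = ra * rb * 0.008 * 300.0  # chance pairs in the window
            surplus.append((near - baseline) / 300.0)
        assert abs(np.mean(surplus) - 2.5) < 0.25


class TestDischarge:
    def test_zero_duration_identity(self):
        tr = generate_poisson_train(5.0, 300.0, 0)
        assert inject_discharge(tr, 100.0, 0.0, 30.0, 1) is tr

    def test_peak_at_baseline_unchanged(self):
        tr = generate_poisson_train(5.0, 300.0, 0)
        out = inject_discharge(tr, 100.0, 10.0, 5.0, 1, epoch_duration_s=300.0,
                               baseline_rate=5.0)
        assert out.n_spikes == tr.n_spikes

    def test_window_outside_epoch_rejected(self):
        tr = generate_poisson_train(5.0, 300.0, 0)
        with pytest.raises(ValueError):
            inject_discharge(tr, 295.0, 10.0, 30.0, 1, epoch_duration_s=300.0)

    def test_injected_window_dominates_counts(self):
        hits = 0
        n = 50
        for s in range(n):
            tr = generate_poisson_train(1.0, 300.0, 1000 + s)
            out = inject_discharge(tr, 140.0, 10.0, 30.0, s, epoch_duration_s=300.0,
                                   baseline_rate=1.0)
            t = out.spike_times
            win_count = np.sum((t >= 140.0) & (t < 150.0))
            others = [
                np.sum((t >= s0) & (t < s0 + 10.0))
                for s0 in range(0, 291, 10)
                if abs(s0 - 140.0) >= 10.0
            ]
            hits += win_count > max(others)
        assert hits >= int(0.95 * n)


class TestTrace:
    def test_pure_noise_sd(self):
        tr = render_trace([], 2.0, 1.0, 0)
        assert abs(tr.samples.std() - 1.0) < 0.02
        assert tr.samples.size == int(round(2.0 * 29412))

    def test_single_large_spike_one_excursion(self):
        from conftest import make_train

        spike = make_train([1.0])
        tr = render_trace([spike], 2.0, 1.0, 0, amplitude=10.0)
        above = np.abs(tr.samples) > 5.0
        # one contiguous excursion only
        runs = np.flatnonzero(np.diff(above.astype(int)) == 1).size + int(above[0])
        assert runs == 1

    def test_invalid_sampling_rate(self):
        with pytest.raises(ValueError):
            render_trace([], 1.0, 1.0, 0, sampling_hz=0.0)


class TestPopulation:
    def test_default_shape_matches_cohort(self):
        res = generate_population(PopulationConfig(seed=3))
        assert res.session.n_units == 222
        assert res.session.n_epochs == 37
        assert len(res.session.patients) == 14
        assert len(res.pairs) == 840  # sum of C(n,2) over epochs

    def test_seed_determinism(self):
        r1 = generate_population(PopulationConfig(seed=5))
        r2 = generate_population(PopulationConfig(seed=5))
        t1 = [tr.spike_times for _, tr in r1.session.iter_trains()]
        t2 = [tr.spike_times for _, tr in r2.session.iter_trains()]
        assert all(np.array_equal(a, b) for a, b in zip(t1, t2))

    def test_realized_class_medians(self):
        res = generate_population(PopulationConfig(seed=11))
        rates = np.array(
            [mean_firing_rate(tr, ep.duration_s) for ep, tr in res.session.iter_trains()]
        )
        cls = np.array([classify_rate(r) for r in rates])
        slow_med = np.median(rates[cls == "slow"])
        fast_med = np.median(rates[cls == "fast"])
        assert abs(slow_med - 0.6) <= 0.3 * 0.6
        assert abs(fast_med - 15.0) <= 0.3 * 15.0

    def test_rate_burst_correlation_near_target(self):
        res = generate_population(PopulationConfig(seed=2))
        rates, bis = [], []
        for ep, tr in res.session.iter_trains():
            rates.append(mean_firing_rate(tr, ep.duration_s))
            bis.append(burst_index(tr))
        rates, bis = np.array(rates), np.array(bis)
        ok = np.isfinite(bis)
        rho = np.corrcoef(rates[ok], bis[ok])[0, 1]
        assert abs(rho - 0.66) <= 0.15

    def test_discharge_unit_count(self):
        res = generate_population(PopulationConfig(seed=3))
        assert res.units["discharge"].sum() == round(0.036 * 222)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            PopulationConfig(rate_class_mix=(0.5, 0.6))
        with pytest.raises(ValueError):
            PopulationConfig(sync_pair_fraction=1.5)
        with pytest.raises(ValueError):
            PopulationConfig(epoch_duration_s=0.0)

    def test_ground_truth_aligns_with_session(self):
        res = generate_population(PopulationConfig(seed=1))
        ids_session = {tr.unit_id for _, tr in res.session.iter_trains()}
        assert ids_session == set(res.units["unit_id"])
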