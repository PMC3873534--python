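import numpy as np
import pytest

from hhspike.model import Epoch
from hhspike.synchrony import (
    CCGParams,
    analyze_all_pairs,
    averaged_ccg,
    bin_counts,
    peak_statistic,
    permutation_test,
    segment_counts,
)
from hhspike.synth import SyncPairParams, generate_poisson_train, generate_synchronous_pair

from conftest import make_train

PARAMS = CCGParams(seed=0)


def brute_force_ccg(a, b, duration, params):
    """O(n^2) circular lagged pair counting, the oracle for the FFT path."""
    ca = segment_counts(a, duration, params)
    cb = segment_counts(b, duration, params)
    n_seg, n_bins = ca.shape
    L = params.max_lag_bins
    out = np.zeros(2 * L + 1)
    for d_i, d in enumerate(range(-L, L + 1)):
        tot = sum(np.sum(ca[s] * np.roll(cb[s], -d)) for s in range(n_seg))
        out[d_i] = tot / n_seg / params.segment_s
    return out


class TestBinning:
    def test_one_spike_per_bin_center(self):
        bin_s = 0.25
        times = np.arange(8) * bin_s + bin_s / 2
        counts = bin_counts(make_train(times), 0.0, 2.0, bin_s)
        assert np.array_equal(counts, np.ones(8, dtype=int))

    def test_boundary_spike_goes_to_later_bin(self):
        counts = bin_counts(make_train([0.25]), 0.0, 2.0, 0.25)
        assert counts[1] == 1 and counts.sum() == 1

    def test_default_segment_has_2048_bins(self):
        counts = bin_counts(make_train([0.5]), 0.0, 2.0, 1.0 / 1024.0)
        assert counts.size == 2048

    def test_counts_conserve_spikes(self):
        rng = np.random.default_rng(0)
        tr = make_train(np.sort(rng.uniform(0, 10, 500)))
        total = segment_counts(tr, 10.0, PARAMS).sum()
        assert total == 500  # no spike at exactly t=10 here


class TestAveragedCCG:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_fft_equals_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        a = generate_poisson_train(30.0, 6.0, rng)
        b = generate_poisson_train(25.0, 6.0, rng)
        res = averaged_ccg(a, b, 6.0, PARAMS)
        np.testing.assert_allclose(res.values, brute_force_ccg(a, b, 6.0, PARAMS),
                                   atol=1e-9)

    def test_identical_trains_zero_lag_value(self):
        a = generate_poisson_train(20.0, 4.0, 1)
        res = averaged_ccg(a, a, 4.0, PARAMS)
        ca = segment_counts(a, 4.0, PARAMS).astype(float)
        expect = (ca**2).sum(axis=1).mean() / PARAMS.segment_s
        assert res.values[res.delays == 0][0] == pytest.approx(expect)
        assert expect >= a.n_spikes / 4.0  # at least the mean firing rate

    def test_independent_pairs_flat_at_product_rate(self):
        a = generate_poisson_train(20.0, 300.0, 1)
        b = generate_poisson_train(20.0, 300.0, 2)
        res = averaged_ccg(a, b, 300.0, PARAMS)
        assert res.values.mean() == pytest.approx(20 * 20 / 1024, rel=0.1)

    def test_empty_train_gives_zero_ccg(self):
        a = generate_poisson_train(20.0, 4.0, 1)
        res = averaged_ccg(a, make_train([]), 4.0, PARAMS)
        assert np.all(res.values == 0)

    def test_epoch_shorter_than_segment_rejected(self):
        a = make_train([0.5])
        with pytest.raises(ValueError):
            averaged_ccg(a, a, 1.0, PARAMS)


class TestPeakStatistic:
    def test_flat_ccg_undefined_normalization(self):
        circ = np.ones(2048)
        zero, norm = peak_statistic(circ, PARAMS)
        assert zero == 0.0
        assert np.isnan(norm)

    def test_constructed_three_sd_peak(self):
        rng = np.random.default_rng(0)
        circ = rng.normal(10.0, 1.0, 2048)
        win = PARAMS.window_bins()
        base = circ[win % 2048]
        circ[0] = base.mean() + 3.0 * base.std(ddof=1)
        zero, norm = peak_statistic(circ, PARAMS)
        assert norm == pytest.approx(3.0)

    def test_negative_peak_sign(self):
        circ = np.full(2048, 5.0)
        win = PARAMS.window_bins()
        circ[win % 2048] += np.linspace(-0.1, 0.1, win.size)  # non-flat window
        circ[0] = 1.0
        zero, _ = peak_statistic(circ, PARAMS)
        assert zero < 0


class TestPermutation:
    def test_perfect_copy_pair_minimal_p(self):
        p = SyncPairParams(10.0, 1.0, 1.0, 0.0, 0.0, 0.0)
        a, b = generate_synchronous_pair(p, 300.0, 0)
        res = permutation_test(a, b, 300.0, PARAMS)
        assert res.p_value == pytest.approx(1.0 / 201.0)
        assert res.sign == "positive"
        assert res.significant

    def test_p_value_bounds(self):
        a = generate_poisson_train(5.0, 60.0, 1)
        b = generate_poisson_train(5.0, 60.0, 2)
        res = permutation_test(a, b, 60.0, PARAMS)
        assert 1.0 / 201.0 <= res.p_value <= 1.0
        assert res.sign in ("positive", "negative", "none")
        assert (res.sign == "none") == (not res.significant)

    def test_rates_unaffected_by_shuffling(self):
        # shuffling permutes segment order: total counts (hence rates) conserved
        a = generate_poisson_train(8.0, 60.0, 3)
        counts = segment_counts(a, 60.0, PARAMS)
        rng = np.random.default_rng(0)
        assert counts[rng.permutation(counts.shape[0])].sum() == counts.sum()

    def test_shuffling_both_identically_preserves_ccg(self):
        from hhspike.synchrony import _circular_ccg

        a = generate_poisson_train(15.0, 60.0, 4)
        b = generate_poisson_train(15.0, 60.0, 5)
        ca = segment_counts(a, 60.0, PARAMS)
        cb = segment_counts(b, 60.0, PARAMS)
        perm = np.random.default_rng(1).permutation(ca.shape[0])
        np.testing.assert_allclose(
            _circular_ccg(ca, cb), _circular_ccg(ca[perm], cb[perm]), atol=1e-9
        )

    def test_fewer_than_two_segments_rejected(self):
        a = generate_poisson_train(10.0, 3.0, 1)
        with pytest.raises(ValueError):
            permutation_test(a, a, 3.0, PARAMS)


class TestAllPairs:
    def _epoch(self, n_units, duration=20.0):
        rng = np.random.default_rng(0)
        trains = [
            make_train(np.sort(rng.uniform(0, duration, 40)), f"u{k}", (k % 8) + 1, "e")
            for k in range(n_units)
        ]
        return Epoch("e", "p", duration, trains)

    def test_pair_count_is_n_choose_2(self):
        fast = CCGParams(seed=0, n_permutations=20)
        records = analyze_all_pairs(self._epoch(5), fast)
        assert len(records) == 10

    def test_single_unit_yields_empty(self):
        assert analyze_all_pairs(self._epoch(1), PARAMS) == []

    def test_cohort_pair_counts(self, cohort_session):
        from math import comb

        total = sum(
            comb(ep.n_units, 2) for ep in cohort_session.iter_epochs()
        )
        assert total == 840
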