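import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vasoburst import (SpikeTrain, binned_rate, burst_profile, burst_summary,
                       detect_bursts, fit_isi_tail, hazard_curve,
                       isi_histogram)

from conftest import poisson_train


def brute_force_bursts(times, min_spikes=25, max_isi_ms=1500.0):
    """Oracle: explicit enumeration of maximal runs of close spikes."""
    runs = []
    i = 0
    while i < len(times):
        j = i
        while j + 1 < len(times) and times[j + 1] - times[j] <= max_isi_ms:
            j += 1
        runs.append((i, j))
        i = j + 1
    return [(times[a], times[b], b - a + 1) for a, b in runs
            if b - a + 1 > min_spikes]


class TestDetectBursts:
    def test_single_run_above_threshold(self):
        t = np.arange(30) * 100.0
        bs = detect_bursts(SpikeTrain(t, 3000.0))
        assert bs.n_bursts == 1
        b = bs.bursts.iloc[0]
        assert b["n_spikes"] == 30
        assert b["duration_s"] == pytest.approx(2.9)

    def test_run_at_threshold_not_a_burst(self):
        # "more than 25 spikes": 20 (and exactly 25) do not qualify
        for n in (20, 25):
            t = np.arange(n) * 100.0
            assert detect_bursts(SpikeTrain(t, 10_000.0)).n_bursts == 0

    def test_two_bursts_and_one_silence(self):
        a = np.arange(30) * 100.0
        b = a[-1] + 2000.0 + np.arange(30) * 100.0
        bs = detect_bursts(SpikeTrain(np.concatenate([a, b]), 10_000.0))
        assert bs.n_bursts == 2
        assert bs.silences_s == pytest.approx([2.0])

    def test_empty_train(self):
        bs = detect_bursts(SpikeTrain(np.empty(0), 1000.0))
        assert bs.n_bursts == 0
        assert burst_summary(bs)["empty"]

    def test_long_isi_splits_runs(self):
        t = np.concatenate([np.arange(26) * 100.0,
                            [2500.0 + 1501.0 + 26 * 100.0]])
        bs = detect_bursts(SpikeTrain(t, 10_000.0))
        assert bs.n_bursts == 1  # the lone trailing spike is not a burst

    def test_matches_brute_force_oracle_on_random_trains(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            n = rng.integers(0, 120)
            isis = rng.exponential(rng.uniform(50, 2000), n)
            times = np.cumsum(isis) + 1.0
            dur = float(times[-1] + 1) if n else 1000.0
            train = SpikeTrain(times, dur)
            got = detect_bursts(train)
            want = brute_force_bursts(times)
            assert got.n_bursts == len(want)
            for (_, row), (s, e, c) in zip(got.bursts.iterrows(), want):
                assert row["start_ms"] == pytest.approx(s)
                assert row["end_ms"] == pytest.approx(e)
                assert row["n_spikes"] == c

    @given(st.lists(st.floats(1.0, 3000.0), min_size=0, max_size=80),
           st.integers(2, 30))
    @settings(max_examples=200, deadline=None)
    def test_invariants_on_arbitrary_trains(self, isis, min_spikes):
        times = np.cumsum(np.asarray(isis))
        train = SpikeTrain(times, float(times[-1]) if len(isis) else 0.0)
        bs = detect_bursts(train, min_spikes=min_spikes)
        b = bs.bursts
        # bursts ordered, non-overlapping, all above the spike-count floor
        assert (b["n_spikes"] > min_spikes).all()
        assert (b["start_ms"].to_numpy()[1:]
                >= b["end_ms"].to_numpy()[:-1]).all()
        # every silence separates two detected bursts
        assert len(bs.silences_s) == max(0, bs.n_bursts - 1)
        # conservation: spikes inside bursts never exceed the total
        assert bs.spikes_in_bursts <= train.n_spikes


class TestBurstSummary:
    def test_known_durations(self):
        a = np.arange(0, 10_001, 100.0)            # 101 spikes, 10 s
        b = 15_000.0 + np.arange(0, 20_001, 100.0)  # 201 spikes, 20 s
        bs = detect_bursts(SpikeTrain(np.concatenate([a, b]), 40_000.0))
        s = burst_summary(bs)
        assert s["burst_mean_s"] == pytest.approx(15.0)
        assert s["intra_rate_hz"] == pytest.approx(10.0)
        assert s["silence_mean_s"] == pytest.approx(5.0)

    def test_single_burst_sd_zero(self):
        t = np.arange(30) * 100.0
        s = burst_summary(detect_bursts(SpikeTrain(t, 4000.0)))
        assert s["burst_sd_s"] == 0.0
        assert np.isnan(s["silence_mean_s"])  # censored: no complete silence


class TestISIHistogram:
    def test_constant_isi_single_bin(self):
        t = np.arange(50) * 100.0
        edges, counts = isi_histogram(SpikeTrain(t, 5000.0), bin_ms=10.0,
                                      max_ms=500.0)
        assert counts.sum() == 49
        assert (counts > 0).sum() == 1
        assert counts[10] == 49  # the [100, 110) bin

    def test_poisson_train_is_exponential(self):
        rng = np.random.default_rng(11)
        train = poisson_train(20.0, 2_000_000, rng)
        edges, counts = isi_histogram(train, bin_ms=10.0, max_ms=300.0)
        amp, decay, r2 = fit_isi_tail(edges, counts, t_min_ms=0.0)
        assert decay == pytest.approx(0.020, rel=0.05)  # rate/1000 per ms
        assert r2 > 0.97

    def test_needs_two_spikes(self):
        with pytest.raises(ValueError):
            isi_histogram(SpikeTrain(np.array([5.0]), 10.0))


class TestHazard:
    def test_flat_for_poisson(self):
        rng = np.random.default_rng(13)
        train = poisson_train(10.0, 3_000_000, rng)
        hz = hazard_curve(train, bin_ms=10.0, max_ms=300.0)
        expected = 1.0 - np.exp(-10.0 * 0.010)
        early = hz.hazard[:15]
        assert np.nanmean(early) == pytest.approx(expected, rel=0.05)
        assert np.nanstd(early) < 0.02

    def test_refractory_bins_zero(self, m1_train_long):
        hz = hazard_curve(m1_train_long, bin_ms=1.0, max_ms=100.0)
        assert (hz.hazard[:3] == 0.0).all()

    def test_reconstructs_histogram(self, m1_train_long):
        edges, counts = isi_histogram(m1_train_long, 10.0, 500.0)
        hz = hazard_curve(m1_train_long, 10.0, 500.0)
        reconstructed = hz.hazard * hz.at_risk
        np.testing.assert_allclose(reconstructed, counts)

    def test_phasic_cell_shape(self, m1_train_long):
        # relative-refractory deficit, then a post-spike excitability peak
        # at ~50-150 ms standing above the random-firing plateau
        hz = hazard_curve(m1_train_long, 10.0, 500.0)
        early = np.nanmean(hz.hazard[:3])        # 0-30 ms
        peak = np.nanmean(hz.hazard[4:16])       # 40-160 ms
        plateau = np.nanmean(hz.hazard[24:48])   # 240-480 ms
        assert early < 0.5 * peak
        assert peak > plateau


class TestTailFit:
    def test_exact_exponential_recovered(self):
        edges = np.arange(0.0, 501.0, 10.0)
        centres = 0.5 * (edges[:-1] + edges[1:])
        counts = 5000.0 * np.exp(-0.0114 * centres)
        amp, decay, r2 = fit_isi_tail(edges, counts, t_min_ms=150.0)
        assert decay == pytest.approx(0.0114, abs=1e-6)
        assert amp == pytest.approx(5000.0, rel=1e-6)
        assert r2 == pytest.approx(1.0)

    def test_too_few_bins_rejected(self):
        edges = np.arange(0.0, 501.0, 10.0)
        counts = np.zeros(50)
        counts[:5] = 10
        with pytest.raises(ValueError):
            fit_isi_tail(edges, counts, t_min_ms=150.0)

    def test_phasic_tail_is_exponential(self, m1_train_long):
        edges, counts = isi_histogram(m1_train_long, 10.0, 500.0)
        _, decay, r2 = fit_isi_tail(edges, counts, t_min_ms=150.0)
        assert r2 > 0.95
        assert decay > 0


class TestProfilesAndRates:
    def test_constant_rate_profiles_flat(self):
        t = np.arange(0, 60_000, 100.0)  # one 60-s burst at 10 Hz
        bs = detect_bursts(SpikeTrain(t, 60_000.0))
        head, tail = burst_profile(SpikeTrain(t, 60_000.0), bs, window_s=50)
        assert head.shape == (50,) and tail.shape == (50,)
        assert head == pytest.approx(np.full(50, 10.0))
        assert tail == pytest.approx(np.full(50, 10.0))

    def test_no_qualifying_burst(self):
        t = np.arange(30) * 100.0  # 2.9-s burst, window 50 s
        bs = detect_bursts(SpikeTrain(t, 3000.0))
        head, tail = burst_profile(SpikeTrain(t, 3000.0), bs)
        assert head.size == 0 and tail.size == 0

    def test_binned_rate_conservation(self, m1_train_long):
        r = binned_rate(m1_train_long, bin_s=1.0)
        assert r.sum() == m1_train_long.n_spikes
        assert r.size == 2000

    def test_binned_rate_empty(self):
        assert binned_rate(SpikeTrain(np.empty(0), 0.0)).size == 0
        r = binned_rate(SpikeTrain(np.array([500.0]), 1000.0))
        assert r == pytest.approx([1.0])
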