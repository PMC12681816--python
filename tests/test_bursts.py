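"""Burst detection: fixed and adaptive thresholds, histogram, metrics."""

import numpy as np
import pytest

from meaburst.bursts import (
    BurstParams,
    InsufficientDataError,
    burst_metrics,
    detect_bursts_adaptive,
    detect_bursts_fixed,
    detect_bursts_hybrid,
    find_isi_threshold,
    log_isi_histogram,
)
from meaburst.core import ISIHistogram, SpikeTrain
from meaburst.synthetic import gen_bursty_train, gen_poisson_train


def _train(times, duration=None, uid=0):
    times = np.asarray(times, dtype=float)
    if duration is None:
        duration = float(times[-1]) + 1.0 if times.size else 1.0
    return SpikeTrain(uid, times, duration)


def brute_force_bursts(times, max_isi, min_spikes):
    """Independent enumeration of maximal qualifying runs."""
    bursts = []
    run = [0] if len(times) else []
    for i in range(1, len(times)):
        if times[i] - times[i - 1] <= max_isi:
            run.append(i)
        else:
            if len(run) >= min_spikes:
                bursts.append((times[run[0]], times[run[-1]], len(run)))
            run = [i]
    if len(run) >= min_spikes:
        bursts.append((times[run[0]], times[run[-1]], len(run)))
    return bursts


class TestFixedDetection:
    def test_grouping_rule(self):
        train = _train([0, 0.05, 0.1, 0.15, 0.2, 1.0, 1.05], 2.0)
        bursts = detect_bursts_fixed(train, 0.1, 5)
        assert len(bursts) == 1
        assert (bursts[0].start, bursts[0].end, bursts[0].n_spikes) == (0.0, 0.2, 5)

    def test_interval_equal_to_threshold_joins(self):
        # 0.25 is exactly representable, so every ISI equals max_isi exactly
        train = _train([0, 0.25, 0.5, 0.75, 1.0], 2.0)
        bursts = detect_bursts_fixed(train, 0.25, 5)
        assert len(bursts) == 1
        assert bursts[0].n_spikes == 5
        assert brute_force_bursts(train.times, 0.25, 5) == [(0.0, 1.0, 5)]

    def test_sparse_poisson_rarely_bursts(self):
        # mean ISI is 10x the threshold: 4 consecutive short ISIs are ~1e-4
        hits = 0
        for seed in range(30):
            train = gen_poisson_train(1.0, 200.0, seed)
            hits += len(detect_bursts_fixed(train, 0.1, 5))
        assert hits <= 1

    def test_matches_brute_force_on_random_trains(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 60))
            times = np.sort(rng.uniform(0, 5.0, n))
            train = _train(times, 5.0)
            max_isi = float(rng.uniform(0.01, 0.5))
            min_spikes = int(rng.integers(2, 6))
            got = [
                (b.start, b.end, b.n_spikes)
                for b in detect_bursts_fixed(train, max_isi, min_spikes)
            ]
            assert got == brute_force_bursts(times, max_isi, min_spikes)

    def test_bursts_disjoint_and_ordered(self, rng):
        for seed in range(20):
            train, _ = gen_bursty_train(event_rate=1.0, duration=30.0, seed=seed,
                                        background_rate=0.5)
            bursts = detect_bursts_fixed(train, 0.1, 3)
            for prev, nxt in zip(bursts, bursts[1:]):
                assert prev.end < nxt.start

    def test_min_spikes_monotonicity(self, rng):
        train, _ = gen_bursty_train(event_rate=1.0, duration=30.0, seed=7)
        counts = [len(detect_bursts_fixed(train, 0.1, m)) for m in range(2, 12)]
        assert counts == sorted(counts, reverse=True)


class TestLogIsiHistogram:
    def test_identical_isis_single_occupied_bin(self):
        train = _train(np.arange(20) * 0.010, 1.0)  # all ISIs 10 ms
        hist = log_isi_histogram(train)
        occupied = np.flatnonzero(hist.counts)
        assert occupied.size == 1
        left, right = hist.bin_edges[occupied[0]], hist.bin_edges[occupied[0] + 1]
        assert left <= 1.0 < right  # log10(10 ms) = 1

    def test_counts_sum_to_interval_count(self, rng):
        for seed in range(10):
            train = gen_poisson_train(5.0, 30.0, seed)
            if train.n_spikes < 3:
                continue
            hist = log_isi_histogram(train)
            assert hist.counts.sum() == train.n_spikes - 1

    def test_bimodal_isis_two_separated_regions(self):
        rng = np.random.default_rng(0)
        isis = np.concatenate([
            rng.uniform(0.004, 0.006, 200),   # 5 ms mode
            rng.uniform(0.4, 0.6, 200),       # 500 ms mode
        ])
        rng.shuffle(isis)
        times = np.concatenate([[0.0], np.cumsum(isis)])
        train = _train(times, times[-1] + 1)
        hist = log_isi_histogram(train)
        occupied = np.flatnonzero(hist.counts)
        gaps = np.diff(occupied)
        # two occupied regions separated by >= 1.5 decades of empty bins
        assert gaps.max() * 0.1 >= 1.5

    def test_too_few_intervals_signals(self):
        with pytest.raises(InsufficientDataError):
            log_isi_histogram(_train([0.1, 0.2], 1.0))


class TestFindIsiThreshold:
    def _hist(self, smoothed, bin_size=0.1, lo=0.0):
        smoothed = np.asarray(smoothed, dtype=float)
        edges = lo + np.arange(len(smoothed) + 1) * bin_size
        return ISIHistogram(edges, smoothed.astype(int), smoothed)

    def test_void_arithmetic(self):
        # peaks 100 and 50 with valley 10: v = 1 - 10/sqrt(5000) ~ 0.8586
        hist = self._hist([0, 100, 10, 10, 10, 50, 0])
        threshold = find_isi_threshold(hist, max_intra_peak=0.1, min_void=0.7)
        assert hist.voids[(1, 5)] == pytest.approx(1 - 10 / np.sqrt(5000), abs=1e-4)
        # valley plateau spans bins 2-4; its centre is bin 3
        assert threshold == pytest.approx(10 ** hist.bin_centers[3] / 1000.0)

    def test_unimodal_histogram_gives_none(self):
        hist = self._hist([0, 5, 20, 5, 0])
        assert find_isi_threshold(hist) is None

    def test_shallow_valley_gives_none(self):
        hist = self._hist([0, 100, 90, 95, 0])  # void ~ 0.077 < 0.7
        assert find_isi_threshold(hist, min_void=0.7) is None

    def test_threshold_beyond_cap_gives_none(self):
        smoothed = np.zeros(45)
        smoothed[5] = 100.0   # ~3 ms: intra-burst peak
        smoothed[40] = 50.0   # ~10 s peak
        smoothed[6:40] = 10.0
        smoothed[35] = 1.0    # unique valley minimum at ~10^3.55 ms ~ 3.5 s
        hist = self._hist(smoothed, lo=0.0)
        assert find_isi_threshold(hist, max_threshold=1.0) is None
        assert find_isi_threshold(hist, max_threshold=None) is not None


class TestAdaptiveDetection:
    def test_recovers_generated_bursts_and_threshold(self):
        train, truth = gen_bursty_train(
            event_rate=0.1, spikes_per_burst=8, intra_isi=0.005, duration=500.0, seed=3
        )
        bursts, hist = detect_bursts_adaptive(train)
        assert len(bursts) == len(truth)
        assert 0.010 <= hist.threshold <= 0.400

    def test_fallback_equals_fixed_defaults(self):
        # jittered periodic train: unimodal ISI histogram, no valley
        rng = np.random.default_rng(5)
        times = np.cumsum(rng.uniform(0.09, 0.11, 200))
        train = _train(times, times[-1] + 1)
        bursts, hist = detect_bursts_adaptive(train)
        assert hist is None or hist.threshold is None
        fixed = detect_bursts_fixed(train, 0.1, 5)
        assert [(b.start, b.end) for b in bursts] == [(b.start, b.end) for b in fixed]

    def test_core_extension_excludes_distant_spikes(self):
        # core of 5 tight spikes, one boundary spike within T, one beyond
        core = np.array([1.0, 1.01, 1.02, 1.03, 1.04])
        times = np.sort(np.concatenate([core, [1.24, 3.0, 10.0, 20.0, 30.0]]))
        train = _train(times, 40.0)
        cores = detect_bursts_fixed(train, 0.1, 2)
        assert len(cores) == 1
        from meaburst.bursts import _extend_and_merge_cores, _runs_within

        runs = _runs_within(train.times, 0.1)
        extended = _extend_and_merge_cores(train.times, runs, 0.3)
        i, j = extended[0]
        assert train.times[j] == 1.24  # 0.2 s gap <= T extends
        assert 3.0 not in train.times[i : j + 1]  # 1.76 s gap > T does not


class TestHybridDetection:
    def test_fallback_identical_to_fixed(self):
        train = gen_poisson_train(1.0, 120.0, seed=5)
        assert detect_bursts_hybrid(train) == detect_bursts_fixed(train, 0.1, 5)

    def test_small_threshold_equals_adaptive(self):
        train, _ = gen_bursty_train(event_rate=0.5, intra_isi=0.004, duration=100.0, seed=2)
        adaptive, hist = detect_bursts_adaptive(train)
        assert hist.threshold is not None and hist.threshold <= 0.1
        assert detect_bursts_hybrid(train) == adaptive

    def test_recovers_most_generated_bursts(self):
        recovered = total = 0
        for seed in range(10):
            train, truth = gen_bursty_train(
                event_rate=0.1, spikes_per_burst=8, intra_isi=0.005,
                duration=300.0, seed=seed,
            )
            bursts = detect_bursts_hybrid(train)
            total += len(truth)
            recovered += sum(
                1
                for s, e in truth
                if any(b.start <= s and b.end >= e - 1e-9 for b in bursts)
            )
        assert recovered / total >= 0.95


class TestBurstMetrics:
    def test_duration_and_density(self):
        from meaburst.core import Burst

        per_burst, summary = burst_metrics([Burst(0, 0.0, 0.45, 10)])
        assert per_burst[0]["duration"] == pytest.approx(0.45)
        assert per_burst[0]["density"] == pytest.approx(22.22, abs=0.01)
        assert summary["n_bursts"] == 1

    def test_empty_list(self):
        per_burst, summary = burst_metrics([])
        assert per_burst == [] and summary is None

    def test_mean_density(self):
        from meaburst.core import Burst

        bursts = [Burst(0, 0.0, 0.5, 10), Burst(0, 1.0, 1.5, 14)]  # 20 and 28 Hz
        _, summary = burst_metrics(bursts)
        assert summary["mean_density"] == pytest.approx(24.0)

    def test_zero_duration_burst_excluded_from_summary(self):
        from meaburst.core import Burst

        bursts = [Burst(0, 1.0, 1.0, 5), Burst(0, 2.0, 2.5, 10)]
        per_burst, summary = burst_metrics(bursts, duration=10.0)
        assert np.isnan(per_burst[0]["density"])
        assert summary["mean_density"] == pytest.approx(20.0)
        assert summary["burst_rate"] == pytest.approx(0.2)
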