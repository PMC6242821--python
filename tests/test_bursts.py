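import numpy as np
import pytest

from spikeglm.bursts import (BurstConfig, BurstTable, ElectrodeLayout,
                             RankMatrix, burst_statistics, detect_bursts,
                             ibi_amplitude_correlation, kernel_distance_profile,
                             nearest_burst_comparison, rank_shuffle, time_ranks)
from spikeglm.data import SpikeCountMatrix
from spikeglm.params import ModelParams
from spikeglm.basis import build_basis


def planted_boxcars(rng, n_neurons=6, n_bins=6000, n_bursts=6,
                    burst_rate=50.0, base_rate=0.5, width=30):
    """Poisson background with box-car population bursts at known bins."""
    onsets = np.linspace(500, n_bins - 800, n_bursts).astype(int)
    lam = np.full(n_bins, base_rate / n_neurons)
    for s in onsets:
        lam[s:s + width] = burst_rate / n_neurons
    counts = rng.poisson(lam[None, :].repeat(n_neurons, axis=0))
    return SpikeCountMatrix(counts, 0.01), onsets, width


class TestDetection:
    def test_all_zero_counts_yield_empty_table(self):
        table = detect_bursts(SpikeCountMatrix(np.zeros((4, 100), int), 0.01))
        assert table.n_bursts == 0
        assert table.ibis.size == 0

    def test_planted_boxcars_recovered_within_one_bin(self, rng):
        counts, onsets, width = planted_boxcars(rng)
        table = detect_bursts(counts)
        assert table.n_bursts == len(onsets)
        assert np.all(np.abs(table.onsets - onsets) <= 1)
        assert np.all(np.abs(table.offsets - (onsets + width)) <= 1)

    def test_amplitude_is_total_count_in_interval(self, rng):
        counts, _, _ = planted_boxcars(rng)
        table = detect_bursts(counts)
        pop = counts.population_rate()
        for s, e, a in zip(table.onsets, table.offsets, table.amplitudes):
            assert a == pop[s:e].sum()

    def test_partition_tiles_record_without_overlap(self, rng):
        counts, _, _ = planted_boxcars(rng)
        table = detect_bursts(counts)
        assert np.all(table.onsets[1:] > table.offsets[:-1])
        np.testing.assert_allclose(
            table.ibis, (table.onsets[1:] - table.offsets[:-1]) * counts.dt)

    def test_close_bursts_merge_and_short_ones_drop(self, rng):
        n = 2000
        lam = np.full(n, 0.1)
        lam[500:530] = 30.0
        lam[535:560] = 30.0   # 50 ms gap -> merged
        lam[1500:1502] = 30.0  # 20 ms -> dropped
        counts = SpikeCountMatrix(rng.poisson(lam[None].repeat(4, 0)), 0.01)
        table = detect_bursts(counts)
        assert table.n_bursts == 1
        assert table.onsets[0] == pytest.approx(500, abs=2)
        assert table.offsets[0] == pytest.approx(560, abs=2)


class TestStatistics:
    def test_two_duration_arithmetic(self):
        table = BurstTable([100, 300], [110, 330], [50.0, 60.0], 0.01)
        stats = burst_statistics(table)
        assert stats["duration"]["mean"] == pytest.approx(0.2)
        assert stats["duration"]["std"] == pytest.approx(0.1 * np.sqrt(2))

    def test_single_burst_flags_undefined_std(self):
        table = BurstTable([100], [120], [40.0], 0.01)
        stats = burst_statistics(table)
        assert stats["duration"]["std"] is None
        assert any("std undefined" in f for f in stats["flags"])

    def test_exponential_ibi_cv_approaches_one(self, rng):
        ibis_bins = np.maximum(rng.exponential(300.0, 10_000).astype(int), 5)
        onsets = np.cumsum(ibis_bins + 10)
        table = BurstTable(onsets, onsets + 10, np.full(len(onsets), 9.0), 0.01)
        stats = burst_statistics(table)
        assert stats["ibi"]["cv"] == pytest.approx(1.0, rel=0.03)


class TestIbiAmplitudeCorrelation:
    def _table(self, ibis_s, amps, dt=0.01):
        gaps = (np.asarray(ibis_s) / dt).astype(int)
        onsets = [100]
        for g in gaps:
            onsets.append(onsets[-1] + 10 + g)
        onsets = np.array(onsets)
        return BurstTable(onsets, onsets + 10, np.r_[50.0, amps], dt)

    def test_perfect_linearity(self, rng):
        ibis = rng.uniform(1.0, 5.0, 30)
        table = self._table(ibis, 40.0 * ibis)
        table.amplitudes[1:] = 40.0 * table.ibis  # exact linear relation
        out = ibi_amplitude_correlation(table)
        assert out["c"] == pytest.approx(1.0, abs=1e-9)

    def test_independent_pairs_near_zero(self, rng):
        ibis = rng.uniform(1.0, 5.0, 400)
        amps = rng.uniform(10, 100, 400)
        out = ibi_amplitude_correlation(self._table(ibis, amps),
                                        rng=np.random.default_rng(1))
        lo, hi = out["ci"]
        assert lo < 0.0 < hi

    def test_shuffling_destroys_planted_correlation(self, rng):
        ibis = rng.uniform(1.0, 5.0, 300)
        amps = 40 * ibis + rng.normal(0, 5, 300)
        out = ibi_amplitude_correlation(self._table(ibis, amps))
        shuffled = ibi_amplitude_correlation(
            self._table(ibis, rng.permutation(amps)))
        assert out["c"] > 0.8
        assert abs(shuffled["c"]) < 0.2

    def test_needs_three_bursts(self):
        with pytest.raises(ValueError):
            ibi_amplitude_correlation(BurstTable([1, 50], [10, 60],
                                                 [5.0, 6.0], 0.01))


class TestTimeRanks:
    def test_definition_against_direct_scan(self, rng):
        counts = SpikeCountMatrix(rng.poisson(0.4, (5, 400)), 0.01)
        table = BurstTable([50, 200], [90, 260], [1.0, 1.0], 0.01)
        rm = time_ranks(counts, table)
        for b, (s, e) in enumerate(zip(table.onsets, table.offsets)):
            for i in range(5):
                hits = [u for u in range(s, e) if counts.counts[i, u] > 0]
                if hits:
                    assert rm.ranks[b, i] == hits[0] - s
                else:
                    assert np.isnan(rm.ranks[b, i])

    def test_onset_spike_has_rank_zero_and_silent_is_nan(self):
        counts = np.zeros((2, 100), int)
        counts[0, 20] = 1   # spikes exactly at onset
        table = BurstTable([20], [40], [1.0], 0.01)
        rm = time_ranks(SpikeCountMatrix(counts, 0.01), table)
        assert rm.ranks[0, 0] == 0.0
        assert np.isnan(rm.ranks[0, 1])

    def test_sentinel_fill_uses_burst_duration(self):
        ranks = RankMatrix(np.array([[1.0, np.nan], [np.nan, 3.0]]),
                           np.array([10, 20]))
        filled = ranks.filled()
        assert filled[0, 1] == 10
        assert filled[1, 0] == 20


class TestRankShuffle:
    def test_per_neuron_multisets_preserved_exactly(self, rng):
        ranks = RankMatrix(rng.integers(0, 20, (30, 8)).astype(float),
                           np.full(30, 25))
        ranks.ranks[rng.random(ranks.ranks.shape) < 0.2] = np.nan
        surr = rank_shuffle(ranks, np.random.default_rng(2))
        for j in range(8):
            np.testing.assert_array_equal(np.sort(ranks.ranks[:, j]),
                                          np.sort(surr.ranks[:, j]))
        np.testing.assert_allclose(ranks.mean_ranks(), surr.mean_ranks())

    def test_different_seeds_give_different_surrogates(self, rng):
        ranks = RankMatrix(rng.integers(0, 50, (40, 6)).astype(float),
                           np.full(40, 60))
        s1 = rank_shuffle(ranks, np.random.default_rng(1))
        s2 = rank_shuffle(ranks, np.random.default_rng(2))
        assert not np.array_equal(s1.ranks, s2.ranks)


class TestNearestBurst:
    def test_identical_sets_have_zero_distance(self, rng):
        ranks = RankMatrix(rng.integers(0, 20, (10, 5)).astype(float),
                           np.full(10, 25))
        surr = rank_shuffle(ranks, rng)
        out = nearest_burst_comparison(ranks, ranks, surr)
        np.testing.assert_allclose(out["d_sim_min"], 0.0)
        assert np.all(out["diff"] >= 0.0)

    def test_matches_brute_force_oracle(self, rng):
        a = RankMatrix(rng.integers(0, 15, (8, 4)).astype(float), np.full(8, 20))
        b = RankMatrix(rng.integers(0, 15, (10, 4)).astype(float), np.full(10, 20))
        surr = rank_shuffle(b, rng)
        out = nearest_burst_comparison(a, b, surr)
        for i in range(8):
            d = [np.sqrt(((a.ranks[i] - b.ranks[j]) ** 2).sum())
                 for j in range(10)]
            assert out["d_sim_min"][i] == pytest.approx(min(d))

    def test_surrogate_null_centered_at_zero(self, rng):
        ranks = RankMatrix(rng.integers(0, 30, (60, 10)).astype(float),
                           np.full(60, 40))
        sim = RankMatrix(rng.integers(0, 30, (60, 10)).astype(float),
                         np.full(60, 40))
        surr = rank_shuffle(sim, np.random.default_rng(1))
        ref = (rank_shuffle(sim, np.random.default_rng(2)),
               rank_shuffle(sim, np.random.default_rng(3)))
        out = nearest_burst_comparison(ranks, sim, surr,
                                       reference_surrogates=ref)
        null = out["null_diff"]
        assert abs(null.mean()) < 3 * null.std(ddof=1) / np.sqrt(len(null))


class TestKernelDistanceProfile:
    def _params_with_areas(self, areas, dt=0.01):
        n = areas.shape[0]
        basis = build_basis("off_diagonal", dt)
        w = np.zeros((n, n, 4))
        w[:, :, 3] = areas / (basis.values[3].sum() * dt)
        return ModelParams("sig_negbin", w, np.zeros(n), np.zeros(5),
                           np.geomspace(0.05, 5, 5), dt=dt)

    def test_planted_exponential_decay_recovered(self, rng):
        layout = ElectrodeLayout.mea_grid(6, drop_corners=False)
        n = 36
        d = layout.distances()
        xi_true = 2.0
        areas = np.exp(-d / xi_true) * (1 + rng.normal(0, 0.01, (n, n)))
        params = self._params_with_areas(areas)
        out = kernel_distance_profile(params, layout, n_bins=10)
        assert out["xi_exc"] == pytest.approx(xi_true, rel=0.05)

    def test_exc_inh_length_constant_ordering(self, rng):
        layout = ElectrodeLayout.mea_grid(6, drop_corners=False)
        n = 36
        d = layout.distances()
        inh = np.zeros(n, bool)
        inh[rng.permutation(n)[:12]] = True
        xi = np.where(inh, 4.0, 1.5)[None, :]
        sign = np.where(inh, -1.0, 1.0)[None, :]
        areas = sign * np.exp(-d / xi) * (1 + rng.normal(0, 0.02, (n, n)))
        out = kernel_distance_profile(self._params_with_areas(areas), layout)
        assert out["xi_exc"] < out["xi_inh"]

    def test_flat_profile_flagged(self):
        layout = ElectrodeLayout.mea_grid(4, drop_corners=False)
        areas = np.ones((16, 16))
        out = kernel_distance_profile(self._params_with_areas(areas), layout)
        assert not np.isfinite(out["xi_exc"]) or "flag_exc" in out

    def test_layout_must_cover_neurons(self, rng):
        layout = ElectrodeLayout(np.array([[0.0, 0], [1, 0]]))
        with pytest.raises(ValueError):
            kernel_distance_profile(self._params_with_areas(np.ones((4, 4))),
                                    layout)

    def test_duplicate_positions_rejected(self):
        with pytest.raises(ValueError):
            ElectrodeLayout(np.array([[0.0, 0], [0.0, 0]]))
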