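"""Sliding-window variance partitioning: geometry, variances, summaries."""

import numpy as np
import pandas as pd
import pytest

from bayeswin import sim, windows
from bayeswin.windows import (Window, WindowResult, build_windows,
                              compute_h2_snp, significant_windows,
                              window_gebv, window_variance_pct,
                              windows_for_variance_fraction)

MB = 1_000_000


def _map(positions, chrom=1):
    positions = np.asarray(positions)
    return pd.DataFrame({"chrom": chrom, "snp_id":
                         [f"s{i}" for i in range(len(positions))],
                         "pos": positions, "a1": "A", "a2": "B"})


def _result(pct, chrom=1, start=0):
    w = Window(chrom, start, start + MB, np.array([0]))
    return WindowResult(w, 0.0, pct)


class TestBuildWindows:
    def test_snps_within_first_mb_give_ten_overlapping_windows(self):
        # SNPs spread over [0, 0.95 Mb]: starts 0, 0.1, ..., 0.9 Mb
        smap = _map(np.arange(50_000, 950_001, 50_000))
        wins = build_windows(smap)
        starts = sorted(w.start for w in wins)
        assert starts == [k * 100_000 for k in range(10)]

    def test_single_early_snp_yields_single_window(self):
        wins = build_windows(_map([50_000]))
        assert len(wins) == 1
        assert wins[0].start == 0

    def test_empty_windows_are_dropped(self):
        # two clusters 5 Mb apart: no window between them
        smap = _map([100_000, 5_900_000])
        wins = build_windows(smap)
        assert all(len(w.snp_indices) > 0 for w in wins)
        covered = {s for w in wins for s in w.snp_indices}
        assert covered == {0, 1}

    def test_window_extent_is_one_mb_half_open(self):
        smap = _map([100_000, 1_100_000])
        for w in build_windows(smap):
            assert w.end - w.start == MB
            pos = smap["pos"].to_numpy()[w.snp_indices]
            assert ((pos >= w.start) & (pos < w.end)).all()

    def test_unsorted_map_rejected(self):
        smap = _map([200_000, 100_000])
        with pytest.raises(ValueError):
            build_windows(smap)

    def test_brute_force_membership_on_random_map(self, rng):
        pos = np.sort(rng.choice(np.arange(1, 4 * MB), size=60, replace=False))
        smap = _map(pos)
        wins = build_windows(smap, size=MB, step=100_000)
        for w in wins:
            expected = {int(j) for j, p in enumerate(pos)
                        if w.start <= p < w.end}
            assert set(w.snp_indices) == expected


class TestWindowGebv:
    def test_zero_effects_give_zero_gebv(self, rng):
        G = rng.integers(0, 3, size=(10, 4))
        assert not window_gebv(G, np.zeros(4)).any()

    def test_single_snp_identity(self, rng):
        G = rng.integers(0, 3, size=(10, 1))
        assert np.array_equal(window_gebv(G, np.ones(1)), G[:, 0].astype(float))

    def test_matches_hand_computed_dot_products(self):
        G = np.array([[0, 2], [1, 1], [2, 0]])
        alpha = np.array([0.5, -1.0])
        assert np.allclose(window_gebv(G, alpha), [-2.0, -0.5, 1.0])


class TestWindowVariance:
    def test_single_window_with_all_snps_explains_everything(self, rng):
        G = rng.integers(0, 3, size=(200, 8)).astype(float)
        alpha = rng.normal(size=8)
        w = [Window(1, 0, MB, np.arange(8))]
        res = window_variance_pct(w, G, alpha, h2=0.44, h2_snp=0.44)
        assert res[0].pct_var == pytest.approx(100.0)

    def test_single_snp_window_equals_2pq_alpha_sq_at_exact_hwe(self):
        # n=1000 at p=0.3: counts 490/420/90, population variance 2pq exactly
        col = np.repeat([0, 1, 2], [490, 420, 90])
        alpha = np.array([0.7])
        w = [Window(1, 0, MB, np.array([0]))]
        res = window_variance_pct(w, col[:, None], alpha, 0.44, 0.44)
        expected = 2 * 0.3 * 0.7 * 0.7**2
        assert abs(res[0].sigma2_j - expected) / expected < 0.02

    def test_brute_force_variance_oracle(self):
        col = np.repeat([0, 1, 2], [100, 200, 100])  # n=400, p=0.5
        w = [Window(1, 0, MB, np.array([0]))]
        res = window_variance_pct(w, col[:, None], np.ones(1), 0.44, 0.44)
        gebv = col.astype(float)
        oracle = np.mean((gebv - gebv.mean()) ** 2)
        assert res[0].sigma2_j == pytest.approx(oracle, abs=1e-12)
        assert res[0].sigma2_j == pytest.approx(0.5, abs=1e-12)

    def test_constant_total_gebv_rejected(self):
        G = np.ones((10, 2))
        w = [Window(1, 0, MB, np.arange(2))]
        with pytest.raises(ValueError):
            window_variance_pct(w, G, np.zeros(2), 0.44, 0.44)

    def test_partition_sums_to_total_for_independent_blocks(self):
        # non-overlapping windows over independent LD blocks: the window
        # variances must add up to the whole-genome GEBV variance
        cfg = sim.SimConfig(n_animals=2000, chrom_lengths_bp=(4 * MB,),
                            snps_per_chrom=(200,), ld_block_bp=MB,
                            n_qtl=20, seed=17)
        G, smap = sim.simulate_genotypes(cfg)
        alpha = sim.simulate_qtl_effects(G, cfg)
        wins = build_windows(smap, size=MB, step=MB)  # exact partition
        res = window_variance_pct(wins, G, alpha, 0.44, 0.44)
        total = np.var(window_gebv(G, alpha))
        assert abs(sum(r.sigma2_j for r in res) - total) / total < 0.05

    def test_invariant_to_allele_orientation_flip(self, rng):
        G = rng.integers(0, 3, size=(300, 6)).astype(float)
        alpha = rng.normal(size=6)
        wins = [Window(1, 0, MB, np.arange(3)), Window(1, 0, MB, np.arange(3, 6))]
        res = window_variance_pct(wins, G, alpha, 0.44, 0.3)
        G2, alpha2 = G.copy(), alpha.copy()
        G2[:, 2] = 2 - G2[:, 2]   # flip allele orientation of one SNP
        alpha2[2] = -alpha2[2]
        res2 = window_variance_pct(wins, G2, alpha2, 0.44, 0.3)
        for a, b in zip(res, res2):
            assert a.pct_var == pytest.approx(b.pct_var, rel=1e-12)


class TestH2Snp:
    # printed variance-component pairs and the summaries derived from them
    @pytest.mark.parametrize("s2snp,s2e,dependent,h2,h2_snp,extra", [
        (0.503, 1.00, "phenotype", 0.44, 0.335, None),
        (1.031, 0.619, "debv", 0.44, 0.275, 0.625),
        (0.416, 1.00, "phenotype", 0.42, 0.294, None),
    ])
    def test_reported_ratios(self, s2snp, s2e, dependent, h2, h2_snp, extra):
        got = compute_h2_snp(s2snp, s2e, dependent, h2)
        assert round(got.h2_snp, 3) == h2_snp
        if extra is None:
            assert got.additive_proportion is None
        else:
            assert round(got.additive_proportion, 3) == extra

    def test_zero_residual_gives_ratio_one(self):
        assert compute_h2_snp(0.5, 0.0, "phenotype").h2_snp == 1.0


class TestWindowSummaries:
    def test_single_dominant_window(self):
        assert windows_for_variance_fraction([_result(100.0)]).count == 1

    def test_exact_cumulative_boundary(self):
        res = [_result(1.0, start=i * MB) for i in range(10)]
        assert windows_for_variance_fraction(res, 0.10).count == 10

    def test_cumulative_ordering(self):
        res = [_result(p, start=i * MB)
               for i, p in enumerate([6.0, 3.0, 2.0, 1.0])]
        out = windows_for_variance_fraction(res, 0.10)
        assert out.count == 3 and out.reached

    def test_shortfall_flags_not_reached(self):
        res = [_result(1.0), _result(2.0, start=MB)]
        out = windows_for_variance_fraction(res, 0.10)
        assert out.count == 2 and not out.reached

    def test_significance_threshold_is_strict(self):
        res = [_result(0.41), _result(0.25, start=MB), _result(0.10, start=2 * MB)]
        hits = significant_windows(res, threshold=0.25)
        assert [r.pct_var for r in hits] == [0.41]

    def test_all_below_threshold_gives_empty(self):
        assert significant_windows([_result(0.1)]) == []
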