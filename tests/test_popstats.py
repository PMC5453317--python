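"""Diversity/divergence statistics against brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

import hybridswarm as hs
from hybridswarm import popstats as ps


class TestPi:
    def test_single_difference_in_ten_kb(self):
        freqs = np.array([0.5])
        pos = np.array([100])
        assert np.isclose(ps.pi_window(freqs, 2, pos, (0, 10_000)), 1e-4)

    def test_monomorphic_window_is_zero(self):
        freqs = np.zeros(5)
        pos = np.arange(5) * 10
        assert ps.pi_window(freqs, 10, pos, (0, 100)) == 0.0

    def test_matches_all_pairs_oracle(self):
        """pi from frequencies equals the average over all 45 haplotype
        pairs' per-bp differences on a 10-haplotype fixture."""
        rng = np.random.default_rng(0)
        hap = rng.integers(0, 2, size=(10, 200))
        pos = np.sort(rng.choice(50_000, size=200, replace=False))
        span = (0, 50_000)
        freqs = ps.freqs_from_haplotypes(hap)
        got = ps.pi_window(freqs, 10, pos, span)
        diffs = [np.sum(hap[i] != hap[j])
                 for i, j in itertools.combinations(range(10), 2)]
        oracle = np.mean(diffs) / (span[1] - span[0])
        assert np.isclose(got, oracle, rtol=1e-12)

    def test_rejects_single_haplotype(self):
        with pytest.raises(ValueError):
            ps.pi_window(np.array([0.5]), 1, np.array([1]), (0, 10))


class TestTajimasD:
    def test_constants_match_independent_definitions(self):
        """Constants recomputed from their textbook definitions."""
        for n in (4, 10, 25, 60):
            c = ps._tajima_constants(n)
            a1 = sum(1.0 / i for i in range(1, n))
            a2 = sum(1.0 / i ** 2 for i in range(1, n))
            b1 = (n + 1) / (3 * (n - 1))
            b2 = 2 * (n ** 2 + n + 3) / (9 * n * (n - 1))
            c1 = b1 - 1 / a1
            c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
            assert np.isclose(c["e1"], c1 / a1, rtol=1e-12)
            assert np.isclose(c["e2"], c2 / (a1 ** 2 + a2), rtol=1e-12)

    def test_zero_when_pi_equals_watterson(self):
        c = ps._tajima_constants(10)
        S = 12
        assert np.isclose(ps.tajimas_d(S, 10, S / c["a1"]), 0.0, atol=1e-12)

    def test_reference_case_n10_s16(self):
        c = ps._tajima_constants(10)
        expected = (3.888 - 16 / c["a1"]) / np.sqrt(
            c["e1"] * 16 + c["e2"] * 16 * 15)
        assert np.isclose(ps.tajimas_d(16, 10, 3.888), expected, rtol=1e-6)

    def test_undefined_for_no_segregating_sites(self):
        assert np.isnan(ps.tajimas_d(0, 10, 0.0))

    def test_sweep_pushes_d_negative(self):
        """Post-sweep windows show negative D in nearly all replicates."""
        neg = 0
        reps = 8
        for s in range(reps):
            cfg = hs.ScenarioConfig(
                n_wild=10, n_dom_per_group={"indica": 12}, L=200_000,
                seed=700 + s, sweep_loci=((100_000, 1500),),
                sweep_names=("sh4",), sweep_width=80_000, pulses=[])
            sw = hs.simulate_swarm(cfg)
            dom = sw.haplotypes[sw.hap_indices(~sw.is_wild)]
            f = ps.freqs_from_haplotypes(dom)
            w = (95_000, 105_000)
            S = ps.segregating_sites(f, sw.positions, w)
            pi_tot = ps.pi_window(f, dom.shape[0], sw.positions, w) * 10_000
            d = ps.tajimas_d(S, dom.shape[0], pi_tot)
            neg += (np.isnan(d) or d < 0)
        assert neg >= 0.9 * reps


class TestDxy:
    @pytest.mark.parametrize("px,py,expected", [
        (1.0, 0.0, 1.0), (1.0, 1.0, 0.0), (0.5, 0.5, 0.5),
    ])
    def test_single_site_formula(self, px, py, expected):
        assert np.isclose(ps.dxy_site(px, py), expected)

    def test_fixed_difference_window(self):
        got = ps.dxy_window(np.array([1.0]), np.array([0.0]), np.array([5]),
                            (0, 10))
        assert np.isclose(got, 1.0)

    def test_undefined_without_polymorphic_sites(self):
        got = ps.dxy_window(np.zeros(3), np.zeros(3), np.arange(3), (0, 10))
        assert np.isnan(got)

    def test_self_dxy_equals_expected_heterozygosity(self):
        rng = np.random.default_rng(1)
        f = rng.random(50)
        pos = np.arange(50)
        got = ps.dxy_window(f, f, pos, (0, 50))
        poly = (f > 0) & (f < 1)
        oracle = np.mean(2 * f[poly] * (1 - f[poly]))
        assert np.isclose(got, oracle)

    def test_polymorphic_rule_switch(self):
        fx = np.array([1.0, 0.5])
        fy = np.array([0.0, 0.5])
        pos = np.array([1, 2])
        pooled = ps.dxy_window(fx, fy, pos, (0, 10), polymorphic="pooled")
        both = ps.dxy_window(fx, fy, pos, (0, 10), polymorphic="both")
        assert np.isclose(pooled, (1.0 + 0.5) / 2)   # fixed difference counts
        assert np.isclose(both, 0.5)                 # only the shared SNP


class TestFst:
    def test_fixed_difference_approaches_one(self):
        f = ps.hudson_fst(np.array([1.0]), np.array([0.0]), 1000, 1000,
                          np.array([5]), (0, 10))
        assert f > 0.99

    def test_identical_frequencies_near_zero(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.2, 0.8, 50)
        f = ps.hudson_fst(p, p, 10_000, 10_000, np.arange(50), (0, 50))
        assert abs(f) < 1e-3

    def test_two_deme_equilibrium_expectation(self):
        """Island-model replicates bracket F_ST ~ 1/(1 + 4Nm)."""
        import msprime

        n_per, Ne, mig = 20, 2_000, 2.5e-4     # 4Nm = 2 -> FST ~ 1/3
        vals = []
        for seed in range(1, 26):
            dem = msprime.Demography.island_model([Ne, Ne], migration_rate=mig)
            ts = msprime.sim_ancestry(
                samples={0: n_per, 1: n_per}, demography=dem, ploidy=1,
                sequence_length=200_000, recombination_rate=1e-8,
                random_seed=seed)
            mts = msprime.sim_mutations(ts, rate=1e-8, random_seed=seed)
            G = mts.genotype_matrix()
            fx = G[:, :n_per].mean(axis=1)
            fy = G[:, n_per:].mean(axis=1)
            pos = np.array([s.position for s in mts.sites()])
            vals.append(ps.hudson_fst(fx, fy, n_per, n_per, pos,
                                      (0, 200_000)))
        expected = 1.0 / (1.0 + 4 * Ne * mig)
        assert abs(np.mean(vals) - expected) / expected < 0.2


class TestRatioScan:
    def _frame(self, n):
        return ps.windows(n * 10_000, 10_000)

    def test_identical_populations_all_ones(self):
        pi = np.full(10, 1e-3)
        scan = ps.diversity_ratio_scan(pi, pi, self._frame(10))
        assert np.allclose(scan.ratios["ratio"], 1.0)

    def test_percentile_rank_arithmetic(self):
        pi_ref = np.ones(100)
        pi_pop = np.ones(100)
        pi_pop[42] = 0.25
        scan = ps.diversity_ratio_scan(pi_pop, pi_ref, self._frame(100))
        top = scan.ranking.iloc[0]
        assert top["ratio"] == 0.25
        assert top["percentile"] == 1.0

    def test_zero_reference_window_excluded(self):
        pi_ref = np.array([1.0, 0.0, 1.0])
        pi_pop = np.array([0.5, 0.5, 0.5])
        scan = ps.diversity_ratio_scan(pi_pop, pi_ref, self._frame(3))
        assert np.isnan(scan.ratios["ratio"].iloc[1])
        assert len(scan.ranking) == 2

    def test_sweep_localized_by_minimum_ratio(self):
        """The minimum dom/wild ratio falls in the swept window."""
        hits, reps = 0, 6
        for s in range(reps):
            cfg = hs.ScenarioConfig(
                n_wild=12, n_dom_per_group={"indica": 12}, L=400_000,
                seed=800 + s, sweep_loci=((200_000, 1500),),
                sweep_names=("sh4",), sweep_width=150_000, pulses=[])
            sw = hs.simulate_swarm(cfg)
            hw = sw.haplotypes[sw.hap_indices(sw.is_wild)]
            hd = sw.haplotypes[sw.hap_indices(~sw.is_wild)]
            fw, fd = ps.freqs_from_haplotypes(hw), ps.freqs_from_haplotypes(hd)
            win = ps.windows(cfg.L, 10_000)
            pi_d = [ps.pi_window(fd, hd.shape[0], sw.positions, (a, b))
                    for a, b, _ in win.itertuples(index=False)]
            pi_w = [ps.pi_window(fw, hw.shape[0], sw.positions, (a, b))
                    for a, b, _ in win.itertuples(index=False)]
            scan = ps.diversity_ratio_scan(np.array(pi_d), np.array(pi_w), win)
            best = scan.ranking.iloc[0]
            hits += (best["start"] >= 125_000) and (best["end"] <= 275_000)
        assert hits >= 0.9 * reps


class TestTopSnp:
    def test_single_polymorphic_site_returned(self):
        out = ps.top_differentiated_snp(np.array([0.0, 0.5]),
                                        np.array([0.0, 0.1]),
                                        np.array([10, 20]))
        assert out["pos"] == 20

    def test_leftmost_tie_rule(self):
        fa = np.array([0.2, 0.9, 0.9])
        fb = np.array([0.0, 0.0, 0.0])
        out = ps.top_differentiated_snp(fa, fb, np.array([5, 10, 15]))
        assert out["pos"] == 10

    def test_no_polymorphism_raises(self):
        with pytest.raises(ValueError):
            ps.top_differentiated_snp(np.zeros(3), np.zeros(3), np.arange(3))


class TestCertainDataIdentity:
    def test_window_stats_match_haplotype_bruteforce(self, two_pop_swarm):
        """pi and d_XY from exact frequencies equal brute-force pairwise
        computation on the true haplotypes."""
        sw = two_pop_swarm
        hx = sw.haplotypes[sw.hap_indices(~sw.is_wild)]
        hy = sw.haplotypes[sw.hap_indices(sw.is_wild)]
        fx, fy = ps.freqs_from_haplotypes(hx), ps.freqs_from_haplotypes(hy)
        w = (0, 100_000)
        i0, i1 = np.searchsorted(sw.positions, w)
        # pi oracle: mean pairwise differences
        diffs = [np.sum(hx[i, i0:i1] != hx[j, i0:i1])
                 for i, j in itertools.combinations(range(hx.shape[0]), 2)]
        assert np.isclose(ps.pi_window(fx, hx.shape[0], sw.positions, w),
                          np.mean(diffs) / (w[1] - w[0]), rtol=1e-10)
        # dxy oracle: mean cross-population differences over pooled-polymorphic sites
        pooled = np.concatenate([hx, hy])[:, i0:i1]
        poly = (pooled.mean(axis=0) > 0) & (pooled.mean(axis=0) < 1)
        cross = np.array([[np.mean(hx[i, i0:i1][poly] != hy[j, i0:i1][poly])
                           for j in range(hy.shape[0])]
                          for i in range(hx.shape[0])])
        got = ps.dxy_window(fx, fy, sw.positions, w,
                            n_x=hx.shape[0], n_y=hy.shape[0])
        assert np.isclose(got, cross.mean(), rtol=1e-10)
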