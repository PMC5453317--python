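"""Admixture EM, label alignment, GL-PCA, window ancestry, carriers, panels."""

import itertools

import numpy as np
import pandas as pd
import pytest

import hybridswarm as hs
from hybridswarm.ancestry import AdmixtureModel, PANEL_REFERENCE_CUTOFF
from tests.conftest import gl_from_genotypes


@pytest.fixture(scope="module")
def two_pop_gl(two_pop_swarm):
    """Near-certain GLs (deep coverage) for two diverged populations."""
    sw = two_pop_swarm
    counts = hs.emit_reads(sw.haplotypes, 25.0, 0.005, seed=4)
    gl = hs.GLMatrix.from_read_counts(counts, 0.005, sw.individuals, sw.sites())
    keep = hs.call_variable_sites(gl)
    return gl.subset_sites(keep), sw


class TestAdmixtureEM:
    def test_k1_collapses_to_site_frequencies(self, two_pop_gl):
        gl, _ = two_pop_gl
        fit = hs.fit_admixture(gl, 1, seed=0)
        assert np.allclose(fit.Q, 1.0)
        freqs = hs.estimate_allele_freqs(gl)["freq"].to_numpy()
        assert np.abs(fit.F[0] - freqs).mean() < 1e-3

    def test_two_populations_separate_cleanly(self, two_pop_gl):
        gl, sw = two_pop_gl
        fit = hs.best_of_replicates(gl, 2, 3, base_seed=0)
        own = fit.Q.max(axis=1)
        assert own.min() >= 0.95
        assert np.median(own) >= 0.99
        # the two groups sit in different clusters
        k_wild = fit.Q[sw.is_wild].mean(axis=0).argmax()
        k_dom = fit.Q[~sw.is_wild].mean(axis=0).argmax()
        assert k_wild != k_dom

    def test_loglik_monotone_every_iteration(self, two_pop_gl):
        gl, _ = two_pop_gl
        fit = hs.fit_admixture(gl, 2, seed=1)
        assert np.all(np.diff(fit.loglik_path) >= -1e-6)

    def test_constraints_hold_after_fit(self, two_pop_gl):
        gl, _ = two_pop_gl
        fit = hs.fit_admixture(gl, 3, seed=2)
        assert np.allclose(fit.Q.sum(axis=1), 1.0, atol=1e-6)
        assert np.all((fit.F >= 0) & (fit.F <= 1))
        assert np.isfinite(fit.loglik)

    def test_objective_matches_direct_evaluation(self, two_pop_gl):
        """Returned loglik equals the admixture objective evaluated
        independently at the returned (Q, F)."""
        gl, _ = two_pop_gl
        fit = hs.fit_admixture(gl, 2, seed=3)
        lin = gl.linear()
        h = fit.Q @ fit.F
        prior = np.stack([(1 - h) ** 2, 2 * h * (1 - h), h ** 2], axis=-1)
        direct = float(np.log((lin * prior).sum(axis=2)).sum())
        assert abs(direct - fit.loglik) <= 1e-6 * abs(direct)

    def test_invalid_inputs_rejected(self, two_pop_gl):
        gl, _ = two_pop_gl
        with pytest.raises(ValueError):
            AdmixtureModel(gl, gl.n_individuals + 1)
        with pytest.raises(ValueError):
            AdmixtureModel(gl.subset_sites(np.array([], dtype=int)), 2)

    def test_grid_search_confirms_fixed_difference_optimum(self):
        """Brute-force likelihood over a coarse Q grid agrees with EM on a
        two-population fixed-difference toy."""
        g = np.zeros((8, 40), dtype=int)
        g[4:] = 2
        gl = gl_from_genotypes(g)
        fit = hs.best_of_replicates(gl, 2, 5, base_seed=0)
        lin = gl.linear()

        def objective(qrows):
            F = np.vstack([np.full(40, 1e-6), np.full(40, 1 - 1e-6)])
            h = np.clip(qrows @ F, 1e-9, 1 - 1e-9)
            prior = np.stack([(1 - h) ** 2, 2 * h * (1 - h), h ** 2], axis=-1)
            return float(np.log((lin * prior).sum(axis=2)).sum())

        grid_best = -np.inf
        for q in np.linspace(0, 1, 21):
            qrows = np.tile([q, 1 - q], (8, 1))
            qrows[4:] = [1 - q, q]
            grid_best = max(grid_best, objective(qrows))
        assert fit.loglik >= grid_best - 1e-6
        assert np.all(fit.Q.max(axis=1) >= 0.99)


class TestReplicates:
    def test_single_replicate_identical_to_fit(self, two_pop_gl):
        gl, _ = two_pop_gl
        a = hs.fit_admixture(gl, 2, seed=11)
        b = hs.best_of_replicates(gl, 2, 1, base_seed=11)
        assert a.loglik == b.loglik
        assert np.array_equal(a.Q, b.Q)

    def test_best_dominates_every_replicate(self, two_pop_gl):
        gl, _ = two_pop_gl
        model = AdmixtureModel(gl, 3)
        best = model.fit_replicates(5, base_seed=0)
        singles = [model.fit(seed=s).loglik for s in range(5)]
        assert all(best.loglik >= s for s in singles)


class TestLabelAlignment:
    def _random_fit(self, rng, n=12, k=3):
        q = rng.dirichlet(np.ones(k), size=n)
        return hs.AdmixtureFit(k, q, np.full((k, 5), 0.5), 0.0, 0, 1, True,
                               np.zeros(1), [f"i{j}" for j in range(n)])

    def test_identical_fits_identity_permutation(self):
        rng = np.random.default_rng(0)
        fit = self._random_fit(rng)
        assert list(hs.align_cluster_labels(fit, fit)) == [0, 1, 2]

    def test_column_swap_recovered(self):
        rng = np.random.default_rng(1)
        fit = self._random_fit(rng)
        swapped = hs.AdmixtureFit(fit.K, fit.Q[:, [2, 0, 1]], fit.F, 0.0, 0,
                                  1, True, np.zeros(1), fit.individuals)
        perm = hs.align_cluster_labels(fit, swapped)
        assert np.array_equal(fit.Q, swapped.Q[:, perm])

    def test_matches_exhaustive_best(self):
        """Assignment equals the best over all K! permutations."""
        rng = np.random.default_rng(2)
        for _ in range(5):
            a, b = self._random_fit(rng), self._random_fit(rng)
            perm = hs.align_cluster_labels(a, b)

            def score(p):
                tot = 0.0
                for i, j in enumerate(p):
                    qa = a.Q[:, i] - a.Q[:, i].mean()
                    qb = b.Q[:, j] - b.Q[:, j].mean()
                    tot += (qa @ qb) / np.sqrt((qa @ qa) * (qb @ qb))
                return tot

            best = max(itertools.permutations(range(3)), key=score)
            assert np.isclose(score(tuple(perm)), score(best), atol=1e-9)


class TestGLPCA:
    def test_certain_data_matches_true_standardized_covariance(self):
        rng = np.random.default_rng(3)
        g = rng.binomial(2, 0.4, size=(10, 300))
        gl = gl_from_genotypes(g)
        res = hs.gl_pca(gl)
        freqs = hs.estimate_allele_freqs(gl)
        p = freqs["freq"].to_numpy()
        keep = (p > 0) & (p < 1)
        x = (g[:, keep] - 2 * p[keep]) / np.sqrt(2 * p[keep] * (1 - p[keep]))
        oracle = x @ x.T / keep.sum()
        assert np.allclose(res.cov, oracle, atol=1e-4)

    def test_two_populations_separate_on_pc1(self, two_pop_gl):
        gl, sw = two_pop_gl
        res = hs.gl_pca(gl)
        pc1 = res.components[:, 0]
        a, b = pc1[sw.is_wild], pc1[~sw.is_wild]
        assert max(a.min(), b.min()) > min(a.max(), b.max()) \
            or max(b.min(), a.min()) > min(b.max(), a.max())
        assert a.max() < b.min() or b.max() < a.min()

    def test_rejects_single_individual(self, two_pop_gl):
        gl, _ = two_pop_gl
        with pytest.raises(ValueError):
            hs.gl_pca(gl.subset_individuals([0]))


class TestCarrierCalls:
    @pytest.mark.parametrize("fraction,expected", [
        (0.96, True), (0.95, True), (0.94, False), (0.0, False), (1.0, True),
    ])
    def test_cutoff_boundary_inclusive(self, fraction, expected):
        calls = hs.classify_carriers({"x": fraction}, "sh4")
        assert calls[0].carrier is expected

    def test_rejects_fraction_outside_unit_interval(self):
        with pytest.raises(ValueError):
            hs.classify_carriers({"x": 1.2}, "sh4")


@pytest.fixture(scope="module")
def locus_fractions(introgressed_swarm, introgressed_gl):
    sw, gl = introgressed_swarm, introgressed_gl
    locus = 200_000
    region = ((gl.sites["pos"] >= locus - 5000)
              & (gl.sites["pos"] < locus + 5000)).to_numpy()
    panel = {ind: ("dom" if not w else "wild")
             for ind, w in zip(sw.individuals, sw.is_wild)}
    frac = hs.window_ancestry(gl.subset_sites(region), 5, panel, seed=13)
    i0, i1 = np.searchsorted(sw.positions, [locus - 5000, locus + 5000])
    dosage = sw.truth.dosage[:, i0:i1].mean(axis=1)
    return sw, frac, dosage


class TestWindowAncestry:
    def test_introgressed_individuals_scored_as_carriers(self, locus_fractions):
        sw, frac, dosage = locus_fractions
        carriers = [i for i in range(sw.n_individuals)
                    if sw.is_wild[i] and dosage[i] >= 0.95]
        assert carriers
        assert all(frac.iloc[i] >= 0.95 for i in carriers)

    def test_unadmixed_individuals_score_low(self, locus_fractions):
        sw, frac, dosage = locus_fractions
        clean = [i for i in range(sw.n_individuals)
                 if sw.is_wild[i] and dosage[i] <= 0.05]
        assert clean
        scores = np.array([frac.iloc[i] for i in clean])
        assert (scores <= 0.05).mean() >= 0.9   # bulk scores near zero
        assert scores.max() < 0.5               # none approach the carrier cutoff

    def test_domesticated_share_one_component(self, introgressed_swarm,
                                              introgressed_gl):
        """All-domesticated haplotypes at the swept locus load on a single
        shared component for K up to 5."""
        sw, gl = introgressed_swarm, introgressed_gl
        region = ((gl.sites["pos"] >= 195_000)
                  & (gl.sites["pos"] < 205_000)).to_numpy()
        panel = {ind: ("dom" if not w else "wild")
                 for ind, w in zip(sw.individuals, sw.is_wild)}
        for k in (2, 5):
            frac = hs.window_ancestry(gl.subset_sites(region), k, panel,
                                      seed=21)
            dom_frac = frac[~sw.is_wild].to_numpy()
            assert np.all(dom_frac >= 0.9)
            assert dom_frac.mean() >= 0.98

    def test_too_few_sites_rejected(self, introgressed_gl, introgressed_swarm):
        sw = introgressed_swarm
        gl = introgressed_gl.subset_sites(np.arange(3))
        panel = {ind: ("dom" if not w else "wild")
                 for ind, w in zip(sw.individuals, sw.is_wild)}
        with pytest.raises(ValueError):
            hs.window_ancestry(gl, 2, panel)


class TestReferencePanels:
    def _fit(self, q_rows, individuals):
        q = np.array(q_rows, dtype=float)
        return hs.AdmixtureFit(q.shape[1], q, np.full((q.shape[1], 4), 0.5),
                               0.0, 0, 1, True, np.zeros(1), individuals)

    def test_rules_applied_exactly(self):
        inds = ["w_ref", "w_carrier", "w_admixed", "w_none", "d_ref",
                "d_aus", "d_mix"]
        # clusters: 0-1 wild-specific, 2 indica, 3 aus
        fit = self._fit([
            [0.85, 0.05, 0.05, 0.05],    # wild reference candidate
            [0.85, 0.05, 0.05, 0.05],    # same profile but sh4 carrier
            [0.40, 0.10, 0.25, 0.25],    # admixed target (50% donor)
            [0.45, 0.37, 0.10, 0.08],    # high wild but split: unassigned
            [0.05, 0.05, 0.85, 0.05],    # indica reference
            [0.05, 0.05, 0.05, 0.85],    # aus reference
            [0.10, 0.10, 0.40, 0.40],    # domesticated but mixed: unassigned
        ], inds)
        calls = hs.classify_carriers(
            {"w_carrier": 0.99, "w_ref": 0.0, "w_admixed": 0.0,
             "w_none": 0.0}, "sh4")
        is_wild = {i: i.startswith("w") for i in inds}
        out = hs.build_reference_panels(fit, calls, is_wild,
                                        wild_clusters=[0, 1],
                                        donor_clusters={"indica": 2, "aus": 3})
        roles = dict(zip(out["individual"], out["role"]))
        assert roles["w_ref"] == "reference_wild"
        assert roles["w_carrier"] != "reference_wild"   # carrier exclusion rule
        assert roles["w_admixed"] == "admixed"
        assert roles["w_none"] == "unassigned"
        assert roles["d_ref"] == "reference_indica"
        assert roles["d_aus"] == "reference_aus"
        assert roles["d_mix"] == "unassigned"

    def test_boundary_at_twenty_percent_inclusive(self):
        inds = ["w1", "d1", "w2"]
        fit = self._fit([[0.80, 0.20], [0.05, 0.95], [0.90, 0.10]], inds)
        out = hs.build_reference_panels(
            fit, [], {"w1": True, "w2": True, "d1": False},
            wild_clusters=[0], donor_clusters={"indica": 1})
        roles = dict(zip(out["individual"], out["role"]))
        assert roles["w1"] == "reference_wild"     # 0.80 wild >= 0.80 wins first
        assert roles["w2"] == "reference_wild"

    def test_empty_required_panel_raises(self):
        inds = ["w1", "d1"]
        fit = self._fit([[0.5, 0.5], [0.5, 0.5]], inds)
        with pytest.raises(ValueError, match="empty reference panel"):
            hs.build_reference_panels(fit, [], {"w1": True, "d1": False},
                                      wild_clusters=[0],
                                      donor_clusters={"indica": 1})


class TestRecovery:
    def test_admixed_dosage_recovered_within_tolerance(self):
        """Simulated 50/50 admixture at 5x depth: mean |Q - truth| < 0.05."""
        cfg = hs.ScenarioConfig(
            n_wild=20, n_dom_per_group={"indica": 14}, L=2_000_000, seed=31,
            sweep_loci=(), sweep_names=(), selfing_rate_wild=0.0,
            selfing_rate_dom=0.0,
            pulses=[hs.Pulse("indica", "wild", alpha=0.5, g=10)])
        sw = hs.simulate_swarm(cfg)
        counts = hs.emit_reads(sw.haplotypes, 5.0, 0.01, seed=8)
        gl = hs.GLMatrix.from_read_counts(counts, 0.01, sw.individuals,
                                          sw.sites())
        gl = gl.subset_sites(hs.call_variable_sites(gl))
        gl = gl.subset_sites(hs.thin_markers(gl.sites, 2000, seed=0))
        fit = hs.best_of_replicates(gl, 2, 3, base_seed=0)
        dom_k = fit.Q[~sw.is_wild].mean(axis=0).argmax()
        truth = sw.truth.dosage.mean(axis=1)
        truth[~sw.is_wild] = 1.0
        assert np.abs(fit.Q[:, dom_k] - truth).mean() < 0.05
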