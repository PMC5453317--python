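"""Shared fixtures: small simulated swarms reused across test modules."""

import numpy as np
import pandas as pd
import pytest

import hybridswarm as hs


def gl_from_genotypes(genotypes: np.ndarray, individuals=None,
                      positions=None) -> hs.GLMatrix:
    """Certain (error-free) GLMatrix from a diploid dosage matrix."""
    g = np.asarray(genotypes, dtype=int)
    n, m = g.shape
    ll = np.full((n, m, 3), -1e9)
    for a in range(3):
        ll[:, :, a] = np.where(g == a, 0.0, -1e9)
    individuals = individuals or [f"ind{i}" for i in range(n)]
    positions = positions if positions is not None else np.arange(m) * 100
    sites = pd.DataFrame({"chrom": "1", "pos": positions, "ref": "A", "alt": "C"})
    return hs.GLMatrix(individuals, sites, ll)


@pytest.fixture(scope="session")
def introgressed_swarm():
    """One pulse (indica -> wild, alpha=0.3, g=10, seed-mediated) plus a
    hard sweep at a single domestication locus; the workhorse dataset."""
    cfg = hs.ScenarioConfig(
        n_wild=24, n_dom_per_group={"indica": 10, "japonica": 10},
        L=400_000, seed=202,
        sweep_loci=((200_000, 1_500),), sweep_names=("sh4",),
        sweep_width=120_000,
        pulses=[hs.Pulse("indica", "wild", alpha=0.3, g=10, seed_mediated=True)],
    )
    return hs.simulate_swarm(cfg)


@pytest.fixture(scope="session")
def introgressed_gl(introgressed_swarm):
    sw = introgressed_swarm
    counts = hs.emit_reads(sw.haplotypes, 5.0, 0.01, seed=77)
    return hs.GLMatrix.from_read_counts(counts, 0.01, sw.individuals, sw.sites())


@pytest.fixture(scope="session")
def two_pop_swarm():
    """Two diverged source populations, no admixture, no sweeps."""
    cfg = hs.ScenarioConfig(
        n_wild=12, n_dom_per_group={"indica": 12}, L=300_000, seed=5,
        sweep_loci=(), sweep_names=(), pulses=[],
    )
    return hs.simulate_swarm(cfg)
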