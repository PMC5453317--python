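"""Chloroplast haplotype networks and domesticated-haplotype sharing.

The chloroplast is maternally inherited and does not recombine, so every
sample carries one haplotype string over a set of common SNPs.  Identical
strings are collapsed into haplotypes, a minimum spanning tree over
pairwise Hamming distances summarizes their relationships, the network is
rooted at the haplotype closest to an outgroup string, and wild samples
sharing a haplotype with domesticated samples quantify seed-mediated gene
flow (pollen does not move the chloroplast).

MST rather than median-joining: the sharing counts that matter here depend
only on haplotype membership, not network topology; tie-breaking is
deterministic (edge distance, then lexicographic haplotype ids).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

MIN_ALLELE_FREQ = 0.05
MIN_HAP_COUNT = 2


@dataclass
class HaplotypeNetwork:
    haplotypes: dict                   # id -> allele string over kept sites
    membership: dict                   # id -> list of sample names
    edges: list = field(default_factory=list)   # (id_i, id_j, hamming)
    root: list = field(default_factory=list)    # rooting candidates
    root_tied: bool = False
    dropped: dict = field(default_factory=dict)  # rare haplotypes, reported not networked
    kept_sites: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return sum(len(m) for m in self.membership.values())


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def define_haplotypes(genotypes: np.ndarray, samples, *,
                      min_allele_freq: float = MIN_ALLELE_FREQ,
                      min_hap_count: int = MIN_HAP_COUNT) -> HaplotypeNetwork:
    """Collapse haploid genotypes into common haplotypes.

    ``genotypes``: (n_samples, n_sites) 0/1 haploid calls; any other value
    (a heterozygous chloroplast call) is a biological impossibility and
    raises.  Sites are filtered to minor-allele frequency >=
    ``min_allele_freq``; haplotypes carried by fewer than ``min_hap_count``
    samples are dropped from the network but reported in ``dropped``.
    Haplotype ids H01, H02, ... are assigned by descending carrier count,
    ties by lexicographic allele string.
    """
    g = np.asarray(genotypes)
    if g.ndim != 2:
        raise ValueError("expected a (n_samples, n_sites) matrix")
    if not np.isin(g, (0, 1)).all():
        raise ValueError("heterozygous or non-binary chloroplast call: "
                         "chloroplast genotypes must be haploid 0/1")
    freq = g.mean(axis=0)
    maf = np.minimum(freq, 1.0 - freq)
    keep = maf >= min_allele_freq
    strings = ["".join(map(str, row)) for row in g[:, keep].astype(int)]
    groups: dict = {}
    for s, string in zip(samples, strings):
        groups.setdefault(string, []).append(s)
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    haplotypes, membership, dropped = {}, {}, {}
    hid = 0
    for string, members in ordered:
        if len(members) >= min_hap_count:
            hid += 1
            name = f"H{hid:02d}"
            haplotypes[name] = string
            membership[name] = members
        else:
            dropped[string] = members
    return HaplotypeNetwork(haplotypes=haplotypes, membership=membership,
                            dropped=dropped, kept_sites=np.flatnonzero(keep))


def build_network(network: HaplotypeNetwork) -> HaplotypeNetwork:
    """Minimum spanning tree over pairwise Hamming distances (Kruskal).

    Edges are considered in (distance, id_i, id_j) order, making the tree
    deterministic under ties.  Mutates and returns ``network``.
    """
    ids = sorted(network.haplotypes)
    if not ids:
        raise ValueError("no haplotypes to network")
    cand = sorted(
        (_hamming(network.haplotypes[a], network.haplotypes[b]), a, b)
        for i, a in enumerate(ids) for b in ids[i + 1:]
    )
    parent = {h: h for h in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edges = []
    for d, a, b in cand:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
            edges.append((a, b, int(d)))
        if len(edges) == len(ids) - 1:
            break
    network.edges = edges
    return network


def root_network(network: HaplotypeNetwork, outgroup: str) -> HaplotypeNetwork:
    """Root at the in-network haplotype nearest the outgroup string.

    Equidistant candidates are all reported with ``root_tied`` set.  The
    outgroup string must cover the same kept sites.
    """
    some = next(iter(network.haplotypes.values()))
    if len(outgroup) != len(some):
        raise ValueError("outgroup string does not cover the network's sites")
    dists = {h: _hamming(s, outgroup) for h, s in network.haplotypes.items()}
    dmin = min(dists.values())
    roots = sorted(h for h, d in dists.items() if d == dmin)
    network.root = roots
    network.root_tied = len(roots) > 1
    return network


def count_domesticated_sharing(network: HaplotypeNetwork,
                               sample_class: dict,
                               subgroup: dict | None = None) -> dict:
    """Wild samples whose haplotype also contains a domesticated sample.

    ``sample_class`` maps sample -> 'wild' | 'domesticated'; ``subgroup``
    optionally maps wild samples to subgroup names for per-subgroup excess
    tests (chi-square goodness of fit against the overall wild sharing
    rate, plus Fisher's exact on the subgroup-vs-rest 2x2 table).
    """
    shared_haps = {h for h, members in network.membership.items()
                   if any(sample_class[s] == "domesticated" for s in members)}
    wild_total, wild_shared = 0, 0
    shared_wild_samples = []
    for h, members in network.membership.items():
        for s in members:
            if sample_class[s] != "wild":
                continue
            wild_total += 1
            if h in shared_haps:
                wild_shared += 1
                shared_wild_samples.append(s)
    out = {
        "n_wild": wild_total,
        "n_shared": wild_shared,
        "fraction": wild_shared / wild_total if wild_total else float("nan"),
        "shared_samples": shared_wild_samples,
        "subgroups": {},
    }
    if subgroup and wild_total:
        rate = wild_shared / wild_total
        shared_set = set(shared_wild_samples)
        wild_samples = [s for h, members in network.membership.items()
                        for s in members if sample_class[s] == "wild"]
        for grp in sorted({subgroup[s] for s in wild_samples if s in subgroup}):
            members = [s for s in wild_samples if subgroup.get(s) == grp]
            k = sum(s in shared_set for s in members)
            n = len(members)
            exp = np.array([rate * n, (1 - rate) * n])
            if exp.min() > 0:
                chi2 = stats.chisquare([k, n - k], exp)
                chi2_stat, chi2_p = float(chi2.statistic), float(chi2.pvalue)
            else:
                chi2_stat, chi2_p = float("nan"), float("nan")
            table = [[k, n - k],
                     [wild_shared - k, (wild_total - wild_shared) - (n - k)]]
            fisher = stats.fisher_exact(table)
            out["subgroups"][grp] = {
                "n": n, "shared": k, "chi2": chi2_stat, "chi2_pvalue": chi2_p,
                "fisher_pvalue": float(fisher.pvalue),
            }
    return out


def network_tables(network: HaplotypeNetwork) -> tuple:
    """(haplotype table, edge table) as DataFrames for TSV export."""
    haps = pd.DataFrame(
        [(h, s, len(network.membership[h]), ",".join(network.membership[h]))
         for h, s in network.haplotypes.items()],
        columns=["haplotype", "alleles", "n_samples", "samples"])
    edges = pd.DataFrame(network.edges, columns=["hap_i", "hap_j", "distance"])
    return haps, edges
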