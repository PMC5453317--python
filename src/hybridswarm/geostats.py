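"""Geographic and categorical statistics for gene-flow patterns.

Distance-vs-genetic-distance correlation with permutation inference,
chi-square tests of geographically uniform gene flow, domestication-allele
co-occurrence, a generic label-enrichment engine (Fisher's exact with
Bonferroni), and the carrier-count summary arithmetic.

Crop-wild sample pairs share members, so the printed parametric p-value of
a rank correlation is not valid; significance here comes from permuting one
distance vector (seeded).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

EARTH_RADIUS_KM = 6371.0088


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km between decimal-degree coordinates."""
    lat1, lon1, lat2, lon2 = map(np.radians, map(np.asarray, (lat1, lon1, lat2, lon2)))
    dlat, dlon = lat2 - lat1, lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def ibs_distance_matrix(genotypes: np.ndarray) -> np.ndarray:
    """1 - identity-by-state proportion between all individual pairs.

    ``genotypes``: (n, m) diploid dosage in {0, 1, 2}; IBS proportion per
    pair is 1 - |g_i - g_j| / 2 averaged over sites.
    """
    g = np.asarray(genotypes, dtype=float)
    n = g.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        d[i] = np.abs(g - g[i]).mean(axis=1) / 2.0
    return d


def distance_correlation(lat1, lon1, lat2, lon2, genetic_dist, *,
                         method: str = "spearman", n_perm: int = 999,
                         seed: int = 0, alternative: str = "greater") -> dict:
    """Correlation between pair geographic and genetic distance.

    One row per crop-wild pair.  rho is Spearman by default (Pearson via
    ``method``); the p-value permutes the genetic-distance vector
    ``n_perm`` times under ``seed``, because pairs sharing members are not
    independent.
    """
    geo = haversine_km(lat1, lon1, lat2, lon2)
    gen = np.asarray(genetic_dist, dtype=float)
    if geo.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.allclose(geo, geo[0]):
        return {"rho": float("nan"), "pvalue": float("nan"),
                "degenerate": True, "n_pairs": int(geo.size)}

    def corr(y):
        if method == "spearman":
            return stats.spearmanr(geo, y).statistic
        if method == "pearson":
            return stats.pearsonr(geo, y).statistic
        raise ValueError(f"unknown method {method!r}")

    rho = float(corr(gen))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        r = corr(rng.permutation(gen))
        if alternative == "greater":
            hits += r >= rho
        elif alternative == "less":
            hits += r <= rho
        else:
            hits += abs(r) >= abs(rho)
    p = (hits + 1.0) / (n_perm + 1.0)
    return {"rho": rho, "pvalue": float(p), "degenerate": False,
            "n_pairs": int(geo.size)}


def region_summary(regions, n, carriers_sh4, carriers_prog1,
                   carriers_both) -> pd.DataFrame:
    """Per-region four-way carrier breakdown (sh4 only / prog1 only / both / neither)."""
    df = pd.DataFrame({
        "region": regions, "n": n, "both": carriers_both,
        "sh4_only": np.asarray(carriers_sh4) - np.asarray(carriers_both),
        "prog1_only": np.asarray(carriers_prog1) - np.asarray(carriers_both),
    })
    df["neither"] = df["n"] - df["sh4_only"] - df["prog1_only"] - df["both"]
    if (df[["sh4_only", "prog1_only", "both", "neither"]] < 0).any().any():
        raise ValueError("inconsistent carrier counts")
    df["either"] = df["n"] - df["neither"]
    return df


def uniform_geography_test(summary: pd.DataFrame, *, count_col: str = "either",
                           min_region_n: int = 10) -> dict:
    """Homogeneity chi-square of carrier rates across regions.

    Regions with fewer than ``min_region_n`` samples are excluded (mirrors
    the map-display rule).  The test is the 2xR contingency chi-square of
    (carriers, non-carriers) against region, i.e. expectations proportional
    to region sizes.  Any expected cell < 1 flags the result and, for two
    regions, switches to Fisher's exact test.
    """
    use = summary[summary["n"] >= min_region_n]
    if len(use) < 2:
        raise ValueError("need >= 2 regions at the minimum sample size")
    table = np.array([use[count_col].to_numpy(),
                      (use["n"] - use[count_col]).to_numpy()])
    chi2, p, dof, expected = stats.chi2_contingency(table, correction=False)
    flagged = bool((expected < 1).any())
    result = {"chi2": float(chi2), "pvalue": float(p), "dof": int(dof),
              "n_regions": int(len(use)), "low_expected": flagged}
    if flagged and table.shape[1] == 2:
        result["fisher_pvalue"] = float(stats.fisher_exact(table.T).pvalue)
    return result


def cooccurrence_test(n_a: int, n_b: int, n_both: int, n_total: int) -> dict:
    """2x2 independence test for carriers of two loci.

    Table cells: both / A only / B only / neither, by subtraction from the
    margins.  Returns the table with chi-square (no continuity correction)
    and Fisher's exact p-values.
    """
    a_only = n_a - n_both
    b_only = n_b - n_both
    neither = n_total - n_a - n_b + n_both
    table = np.array([[n_both, a_only], [b_only, neither]])
    if (table < 0).any():
        raise ValueError(f"inconsistent counts give negative cell: {table.tolist()}")
    chi2, chi2_p, _, _ = stats.chi2_contingency(table, correction=False)
    fisher = stats.fisher_exact(table)
    return {"table": table, "chi2": float(chi2), "chi2_pvalue": float(chi2_p),
            "fisher_pvalue": float(fisher.pvalue),
            "odds_ratio": float(fisher.statistic)}


def label_enrichment(ranked_genes, top_fraction: float,
                     gene_labels: dict) -> pd.DataFrame:
    """One-sided Fisher enrichment of labels in the top of a ranked gene list.

    ``ranked_genes``: best-first ordering (e.g. by descending F_ST);
    ``gene_labels``: gene -> iterable of labels.  For each label the
    hypergeometric upper tail of (in-top, labelled) is computed and
    Bonferroni-adjusted by the number of tested labels.  Labels with no
    gene in the universe are skipped with a note.
    """
    if not 0.0 < top_fraction < 1.0:
        raise ValueError("top fraction must be in (0, 1)")
    genes = list(ranked_genes)
    universe = set(genes)
    n_univ = len(genes)
    n_top = max(1, int(round(n_univ * top_fraction)))
    top = set(genes[:n_top])
    label_to_genes: dict = {}
    skipped = []
    for gene, labels in gene_labels.items():
        if gene not in universe:
            continue
        for lab in labels:
            label_to_genes.setdefault(lab, set()).add(gene)
    for lab in {l for labels in gene_labels.values() for l in labels}:
        if lab not in label_to_genes:
            skipped.append(lab)
    n_labels = len(label_to_genes)
    rows = []
    for lab, members in sorted(label_to_genes.items()):
        k = len(members & top)
        K = len(members)
        p = float(stats.hypergeom.sf(k - 1, n_univ, K, n_top))
        rows.append({"label": lab, "in_top": k, "labelled": K,
                     "top_size": n_top, "universe": n_univ, "pvalue": p,
                     "bonferroni": min(1.0, p * n_labels)})
    out = pd.DataFrame(rows)
    out.attrs["skipped_labels"] = sorted(skipped)
    return out


def carrier_summary(n_sh4: int, n_prog1: int, n_both: int,
                    n_wild: int) -> dict:
    """Carrier-count arithmetic with inclusion-exclusion, percentages to 1 dp.

    either = |A u B| = |A| + |B| - |A n B|; total allele occurrences =
    |A| + |B| (each carried domestication allele counted once per locus).
    """
    if not (0 <= n_both <= min(n_sh4, n_prog1) and max(n_sh4, n_prog1) <= n_wild):
        raise ValueError("inconsistent carrier counts")
    either = n_sh4 + n_prog1 - n_both
    pct = lambda k: round(100.0 * k / n_wild, 1)
    return {
        "n_wild": n_wild,
        "sh4": n_sh4, "prog1": n_prog1, "both": n_both, "either": either,
        "sh4_pct": pct(n_sh4), "prog1_pct": pct(n_prog1),
        "either_pct": pct(either), "both_pct": pct(n_both),
        "total_alleles": n_sh4 + n_prog1,
    }


def sharing_fraction(n_shared: int, n_total: int) -> float:
    """Percentage of samples sharing a haplotype class, to 1 decimal place."""
    if not 0 <= n_shared <= n_total:
        raise ValueError("inconsistent sharing counts")
    return round(100.0 * n_shared / n_total, 1)
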