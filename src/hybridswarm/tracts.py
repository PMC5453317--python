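"""Local-ancestry classification of admixed genomes and tract-length analysis.

Each admixed individual's chromosome is cut into windows (50 kb by
default), every window is assigned to the reference panel (wild or one of
the domesticated donor groups) that maximizes the composite GL likelihood

    score(panel) = sum_sites log sum_g GL(g) * Binom(g; 2, p_panel),

labels are optionally majority-smoothed, and maximal runs of one label are
merged into ancestry tracts whose lengths are measured in centimorgans via
the genetic map.  Because recombination shortens introgressed tracts every
generation, the per-donor tract-length distribution orders admixture events
in time: older pulses leave shorter tracts (mean ~ 1/((1-alpha)*g) Morgans
for a single pulse).

This is an unphased window classifier, not a phased-haplotype CRF: it
labels the diploid majority ancestry of each window, which is sufficient
for per-donor tract-length distributions at desk scale.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from hybridswarm.gl_core import GLMatrix
from hybridswarm.simswarm import GeneticMap

DEFAULT_TRACT_WINDOW = 50_000
UNASSIGNED = "unassigned"


def classify_windows(gl: GLMatrix, individual: str, panel_freqs: dict,
                     window_frame: pd.DataFrame, *,
                     min_sites: int = 10) -> pd.DataFrame:
    """Assign each window of one individual to its best-scoring panel.

    ``panel_freqs`` maps label -> per-site allele-frequency array aligned to
    ``gl.sites``.  Windows with fewer than ``min_sites`` informative sites
    are labelled 'unassigned'.  Ties keep the first panel in insertion
    order and are flagged.  Returns a frame with columns start, end, label,
    margin, n_sites, tie.
    """
    try:
        i = gl.individuals.index(individual)
    except ValueError:
        raise KeyError(f"unknown individual {individual!r}") from None
    labels = list(panel_freqs)
    lin = gl.linear()[i]                      # (n_sites, 3)
    pos = gl.sites["pos"].to_numpy()
    inform = gl.informative()[i]
    scores = np.empty((len(labels), gl.n_sites))
    for j, lab in enumerate(labels):
        p = np.clip(np.asarray(panel_freqs[lab], dtype=float), 1e-6, 1 - 1e-6)
        prior = np.stack([(1 - p) ** 2, 2 * p * (1 - p), p ** 2], axis=-1)
        scores[j] = np.log(np.maximum((lin * prior).sum(axis=1), 1e-300))
    rows = []
    for start, end in window_frame[["start", "end"]].itertuples(index=False):
        i0, i1 = np.searchsorted(pos, [start, end])
        n_inf = int(inform[i0:i1].sum())
        if n_inf < min_sites:
            rows.append((start, end, UNASSIGNED, 0.0, n_inf, False))
            continue
        tot = scores[:, i0:i1].sum(axis=1)
        order = np.argsort(-tot, kind="stable")
        best, second = order[0], (order[1] if len(order) > 1 else order[0])
        margin = float(tot[best] - tot[second])
        tie = bool(np.isclose(margin, 0.0) and len(order) > 1)
        if tie:   # documented tie rule: first panel in insertion order
            best = min(k for k in range(len(labels))
                       if np.isclose(tot[k], tot[order[0]]))
        rows.append((start, end, labels[best], margin, n_inf, tie))
    return pd.DataFrame(rows, columns=["start", "end", "label", "margin",
                                       "n_sites", "tie"])


def smooth_labels(labels, radius: int = 1) -> list:
    """Majority filter over 2*radius+1 windows; ties keep the original label.

    Suppresses isolated single-window misassignments before tract merging;
    a run longer than ``radius`` can never be erased.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    labels = list(labels)
    if radius == 0:
        return labels
    n = len(labels)
    out = []
    for i in range(n):
        lo, hi = max(0, i - radius), min(n, i + radius + 1)
        counts = Counter(labels[lo:hi])
        top = counts.most_common()
        if len(top) > 1 and top[0][1] == top[1][1]:
            winners = {lab for lab, c in top if c == top[0][1]}
            out.append(labels[i] if labels[i] in winners else top[0][0])
        else:
            out.append(top[0][0])
    return out


def extract_tracts(labels, window_frame: pd.DataFrame, genetic_map: GeneticMap,
                   *, chrom: str = "1",
                   individual: str | None = None) -> pd.DataFrame:
    """Merge maximal runs of identical window labels into cM-measured tracts.

    Tract boundaries are window edges; cM lengths come from map
    interpolation at those edges.  Unassigned windows form their own tracts
    (so tracts tile the chromosome) but should be excluded from donor
    summaries.
    """
    labels = list(labels)
    if len(labels) != len(window_frame):
        raise ValueError("one label per window required")
    starts = window_frame["start"].to_numpy()
    ends = window_frame["end"].to_numpy()
    rows = []
    run_start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[run_start]:
            s, e = int(starts[run_start]), int(ends[i - 1])
            cs, ce = float(genetic_map.bp_to_cm(s)), float(genetic_map.bp_to_cm(e))
            rows.append({"chrom": chrom, "individual": individual,
                         "start": s, "end": e, "start_cm": cs, "end_cm": ce,
                         "length_cm": ce - cs, "label": labels[run_start]})
            run_start = i
    return pd.DataFrame(rows)


def infer_tracts(gl: GLMatrix, panel_freqs: dict, genetic_map: GeneticMap, *,
                 individuals=None, window_size: int = DEFAULT_TRACT_WINDOW,
                 min_sites: int = 10, smooth_radius: int = 1) -> pd.DataFrame:
    """classify -> smooth -> extract for a set of admixed individuals."""
    from hybridswarm.popstats import windows as make_windows

    win = make_windows(int(genetic_map.length_bp), window_size)
    individuals = list(individuals) if individuals is not None else list(gl.individuals)
    frames = []
    for ind in individuals:
        cls = classify_windows(gl, ind, panel_freqs, win, min_sites=min_sites)
        labs = smooth_labels(cls["label"], smooth_radius)
        frames.append(extract_tracts(labs, win, genetic_map, individual=ind))
    return pd.concat(frames, ignore_index=True)


@dataclass
class TractSummary:
    table: pd.DataFrame         # per donor: mean_cm, n_tracts
    cdfs: dict                  # donor -> (sorted lengths, ecdf values)
    excluded: list              # donors requested but absent


def tract_length_summary(tracts: pd.DataFrame, donor_groups) -> TractSummary:
    """Per-donor mean tract length (cM), counts and empirical CDFs."""
    rows, cdfs, excluded = [], {}, []
    for donor in donor_groups:
        lens = tracts.loc[tracts["label"] == donor, "length_cm"].to_numpy()
        if lens.size == 0:
            excluded.append(donor)
            continue
        x = np.sort(lens)
        cdfs[donor] = (x, np.arange(1, len(x) + 1) / len(x))
        rows.append({"donor": donor, "mean_cm": float(lens.mean()),
                     "median_cm": float(np.median(lens)),
                     "n_tracts": int(lens.size)})
    return TractSummary(pd.DataFrame(rows), cdfs, excluded)


def compare_tract_distributions(lengths_a, lengths_b) -> dict:
    """Welch t-test plus a KS companion on two tract-length samples.

    With degenerate variance (all lengths equal in both samples) only the
    KS result is meaningful and the output is flagged.
    """
    a = np.asarray(lengths_a, dtype=float)
    b = np.asarray(lengths_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 tracts in each sample")
    ks = stats.ks_2samp(a, b)
    degenerate = a.std() == 0 and b.std() == 0
    if degenerate and np.allclose(a.mean(), b.mean()):
        t_stat, t_p = 0.0, 1.0
    else:
        t = stats.ttest_ind(a, b, equal_var=False)
        t_stat, t_p = float(t.statistic), float(t.pvalue)
        if np.isnan(t_stat):
            degenerate, t_stat, t_p = True, 0.0, 1.0
    return {"t": t_stat, "t_pvalue": t_p, "ks": float(ks.statistic),
            "ks_pvalue": float(ks.pvalue), "degenerate_variance": degenerate}
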