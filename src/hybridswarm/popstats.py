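"""Window and gene-level diversity and divergence statistics.

pi (pairwise nucleotide diversity), Watterson's theta, Tajima's D, absolute
divergence d_XY, Hudson's F_ST, diversity-reduction ratio scans and the
most-differentiated-SNP lookup.  Everything operates on per-site allele
frequencies (from the GL EM or from true haplotypes) plus sample sizes, in
non-overlapping windows (10 kb by default); the last partial window is kept
and flagged.

Per site, pi contributes 2*p*q*n/(n-1) (the unbiased pairwise estimator);
d_XY contributes p_X*q_Y + p_Y*q_X, averaged over polymorphic sites in the
window; Hudson's F_ST is a ratio of window-summed numerators and
denominators ("ratio of averages").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_WINDOW = 10_000


def windows(length: int, size: int = DEFAULT_WINDOW) -> pd.DataFrame:
    """Non-overlapping half-open windows covering [0, length)."""
    starts = np.arange(0, length, size)
    ends = np.minimum(starts + size, length)
    return pd.DataFrame({"start": starts, "end": ends,
                         "partial": ends - starts < size})


def freqs_from_haplotypes(haplotypes: np.ndarray) -> np.ndarray:
    """Alt-allele frequencies from a (n_haplotypes, n_sites) 0/1 matrix."""
    return np.asarray(haplotypes, dtype=float).mean(axis=0)


def pi_window(freqs: np.ndarray, n: int, positions: np.ndarray,
              window: tuple) -> float:
    """Pairwise nucleotide diversity per bp in a half-open window.

    n is the number of sampled allele copies (haplotypes).
    """
    if n < 2:
        raise ValueError("pi requires n >= 2 sampled haplotypes")
    start, end = window
    if end <= start:
        raise ValueError("empty window")
    i0, i1 = np.searchsorted(positions, [start, end])
    p = np.asarray(freqs, dtype=float)[i0:i1]
    tot = float(np.sum(2.0 * p * (1.0 - p)) * n / (n - 1.0))
    return tot / float(end - start)


def _tajima_constants(n: int) -> dict:
    """Tajima's normalization constants a1, a2, b1, b2, c1, c2, e1, e2."""
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i ** 2))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n * n + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(S: int, n: int, pi_total: float) -> float:
    """Tajima's D from segregating sites S, sample size n and summed pi.

    D = (pi_total - S/a1) / sqrt(e1*S + e2*S*(S-1)).  Negative values
    indicate an excess of rare alleles (e.g. after a selective sweep).
    Returns NaN for S = 0 (undefined, flagged rather than zero).
    """
    if n < 4:
        raise ValueError("Tajima's D requires n >= 4")
    if S < 1:
        return float("nan")
    c = _tajima_constants(n)
    var = c["e1"] * S + c["e2"] * S * (S - 1.0)
    return float((pi_total - S / c["a1"]) / np.sqrt(var))


def dxy_site(p_x: float, p_y: float) -> float:
    """Per-site absolute divergence d_XY = pX*qY + pY*qX."""
    return p_x * (1.0 - p_y) + p_y * (1.0 - p_x)


def dxy_window(freq_x: np.ndarray, freq_y: np.ndarray, positions: np.ndarray,
               window: tuple, *, polymorphic: str = "pooled",
               n_x: int | None = None, n_y: int | None = None) -> float:
    """Mean per-site absolute divergence d_XY = pX*qY + pY*qX in a window.

    Averaged over sites polymorphic in the ``polymorphic`` sense:
    'pooled' (default; variable in the combined sample, so fixed
    differences count), 'either', or 'both'.  Returns NaN when no site
    qualifies.
    """
    start, end = window
    i0, i1 = np.searchsorted(positions, [start, end])
    px = np.asarray(freq_x, dtype=float)[i0:i1]
    py = np.asarray(freq_y, dtype=float)[i0:i1]
    var_x = (px > 0) & (px < 1)
    var_y = (py > 0) & (py < 1)
    if polymorphic == "pooled":
        wx = n_x if n_x is not None else 1
        wy = n_y if n_y is not None else 1
        pbar = (wx * px + wy * py) / (wx + wy)
        mask = (pbar > 0) & (pbar < 1)
    elif polymorphic == "either":
        mask = var_x | var_y
    elif polymorphic == "both":
        mask = var_x & var_y
    else:
        raise ValueError(f"unknown polymorphic rule {polymorphic!r}")
    if not mask.any():
        return float("nan")
    d = px[mask] * (1 - py[mask]) + py[mask] * (1 - px[mask])
    return float(d.mean())


def hudson_fst(freq_x: np.ndarray, freq_y: np.ndarray, n_x: int, n_y: int,
               positions: np.ndarray, window: tuple) -> float:
    """Hudson's F_ST over a window, ratio-of-averages form.

    Per site: num = (pX - pY)^2 - pX*qX/(nX-1) - pY*qY/(nY-1);
    den = pX*qY + pY*qX.  F_ST = sum(num)/sum(den) over window sites that
    are polymorphic in the pooled sample; NaN when none are.
    """
    if n_x < 2 or n_y < 2:
        raise ValueError("Hudson F_ST requires n >= 2 in both populations")
    start, end = window
    i0, i1 = np.searchsorted(positions, [start, end])
    px = np.asarray(freq_x, dtype=float)[i0:i1]
    py = np.asarray(freq_y, dtype=float)[i0:i1]
    pbar = (n_x * px + n_y * py) / (n_x + n_y)
    mask = (pbar > 0) & (pbar < 1)
    if not mask.any():
        return float("nan")
    px, py = px[mask], py[mask]
    num = ((px - py) ** 2
           - px * (1 - px) / (n_x - 1.0)
           - py * (1 - py) / (n_y - 1.0))
    den = px * (1 - py) + py * (1 - px)
    return float(num.sum() / den.sum())


def wc_fst(freq_x: np.ndarray, freq_y: np.ndarray, n_x: int, n_y: int,
           positions: np.ndarray, window: tuple) -> float:
    """Weir-Cockerham two-population F_ST (configurable alternative)."""
    start, end = window
    i0, i1 = np.searchsorted(positions, [start, end])
    px = np.asarray(freq_x, dtype=float)[i0:i1]
    py = np.asarray(freq_y, dtype=float)[i0:i1]
    nbar = (n_x + n_y) / 2.0
    nc = (n_x + n_y - (n_x ** 2 + n_y ** 2) / (n_x + n_y))
    pbar = (n_x * px + n_y * py) / (n_x + n_y)
    s2 = (n_x * (px - pbar) ** 2 + n_y * (py - pbar) ** 2) / nbar
    hbar = (n_x * 2 * px * (1 - px) + n_y * 2 * py * (1 - py)) / (n_x + n_y)
    a = nbar / nc * (s2 - (pbar * (1 - pbar) - s2 / 2.0 - hbar / 4.0) / (nbar - 1.0))
    b = nbar / (nbar - 1.0) * (pbar * (1 - pbar) - s2 / 2.0
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2.0
    mask = (pbar > 0) & (pbar < 1)
    if not mask.any():
        return float("nan")
    return float(a[mask].sum() / (a + b + c)[mask].sum())


def segregating_sites(freqs: np.ndarray, positions: np.ndarray,
                      window: tuple) -> int:
    start, end = window
    i0, i1 = np.searchsorted(positions, [start, end])
    p = np.asarray(freqs, dtype=float)[i0:i1]
    return int(np.sum((p > 0) & (p < 1)))


def compute_window_stats(freq_x: np.ndarray, n_x: int, freq_y: np.ndarray,
                         n_y: int, positions: np.ndarray, length: int, *,
                         window_size: int = DEFAULT_WINDOW, chrom: str = "1",
                         fst: str = "hudson",
                         dxy_polymorphic: str = "pooled") -> pd.DataFrame:
    """Per-window pi, theta_W, Tajima's D (each population), d_XY and F_ST."""
    fst_fn = {"hudson": hudson_fst, "wc": wc_fst}[fst]
    win = windows(length, window_size)
    rows = []
    for start, end, partial in win.itertuples(index=False):
        w = (int(start), int(end))
        row = {"chrom": chrom, "start": w[0], "end": w[1], "partial": bool(partial)}
        for tag, f, n in (("x", freq_x, n_x), ("y", freq_y, n_y)):
            s = segregating_sites(f, positions, w)
            pi_bp = pi_window(f, n, positions, w)
            c = _tajima_constants(n)
            row[f"S_{tag}"] = s
            row[f"pi_{tag}"] = pi_bp
            row[f"thetaW_{tag}"] = s / c["a1"] / (w[1] - w[0])
            row[f"tajd_{tag}"] = tajimas_d(s, n, pi_bp * (w[1] - w[0]))
            row[f"n_{tag}"] = n
        row["dxy"] = dxy_window(freq_x, freq_y, positions, w,
                                polymorphic=dxy_polymorphic, n_x=n_x, n_y=n_y)
        row["fst"] = fst_fn(freq_x, freq_y, n_x, n_y, positions, w)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class RatioScan:
    ratios: pd.DataFrame       # per window: ratio pi_pop / pi_ref (NaN if undefined)
    ranking: pd.DataFrame      # defined windows ranked ascending with percentiles


def diversity_ratio_scan(pi_pop: np.ndarray, pi_ref: np.ndarray,
                         window_frame: pd.DataFrame,
                         names: np.ndarray | None = None) -> RatioScan:
    """Relative-diversity scan: per-window pi_pop / pi_ref, ranked ascending.

    Windows where the reference diversity is zero are flagged undefined and
    excluded from the ranking.  ``percentile`` is rank/N * 100 with rank 1
    for the lowest ratio, so "top 0.3% of diversity reduction" means
    percentile <= 0.3.
    """
    pi_pop = np.asarray(pi_pop, dtype=float)
    pi_ref = np.asarray(pi_ref, dtype=float)
    ratio = np.where(pi_ref > 0, pi_pop / np.where(pi_ref > 0, pi_ref, 1.0),
                     np.nan)
    out = window_frame.copy().reset_index(drop=True)
    out["name"] = names if names is not None else out.index.astype(str)
    out["ratio"] = ratio
    defined = out[np.isfinite(out["ratio"])].copy()
    defined = defined.sort_values(["ratio", "start"], kind="stable").reset_index(drop=True)
    defined["rank"] = np.arange(1, len(defined) + 1)
    defined["percentile"] = defined["rank"] / len(defined) * 100.0
    return RatioScan(ratios=out, ranking=defined)


def top_differentiated_snp(freq_a: np.ndarray, freq_b: np.ndarray,
                           positions: np.ndarray,
                           region: tuple | None = None) -> dict:
    """Site maximizing |p_A - p_B| (leftmost on ties) with both frequencies."""
    pa = np.asarray(freq_a, dtype=float)
    pb = np.asarray(freq_b, dtype=float)
    pos = np.asarray(positions)
    if region is not None:
        i0, i1 = np.searchsorted(pos, [region[0], region[1]])
        pa, pb, pos = pa[i0:i1], pb[i0:i1], pos[i0:i1]
    pbar = (pa + pb) / 2.0
    poly = (pbar > 0) & (pbar < 1)
    if not poly.any():
        raise ValueError("region has no polymorphic sites")
    diff = np.abs(pa - pb)
    diff[~poly] = -1.0
    best = int(np.argmax(diff))      # argmax returns the first (leftmost) max
    return {"pos": int(pos[best]), "freq_a": float(pa[best]),
            "freq_b": float(pb[best]), "diff": float(diff[best])}
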