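"""Genotype likelihoods and GL-native site-level inference.

At low sequencing depth, hard genotype calls are unreliable; every estimator
here therefore works on per-genotype log-likelihoods (GLs).  The read model
is the standard one: a read supports its true allele with probability
``1 - epsilon`` and the other allele with probability ``epsilon``, so for
genotype g (count of alt alleles, g in {0, 1, 2}),

    loglik(g) = n_ref * log((2-g)/2 * (1-eps) + g/2 * eps)
              + n_alt * log((2-g)/2 * eps + g/2 * (1-eps)),

normalized so the per-site maximum is 0.  Missing data is encoded as an
all-equal (flat) triplet, which contributes nothing to any EM below.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

LOG_ZERO = -1e10        # stand-in for log(0); large negative, never NaN
EM_TOL = 1e-8           # relative loglik change stopping rule
EM_MAX_ITER = 200
EM_INIT_P = 0.2


@dataclass
class GLMatrix:
    """Per-individual, per-site genotype log-likelihoods.

    ``loglik`` has shape (n_individuals, n_sites, 3), indexed by the count of
    alternate alleles, and is normalized so that max over genotypes is 0 at
    every individual-site.  Sites are strictly increasing within chromosome.
    """

    individuals: list
    sites: pd.DataFrame                 # columns chrom, pos, ref, alt
    loglik: np.ndarray

    def __post_init__(self) -> None:
        self.loglik = np.asarray(self.loglik, dtype=float)
        if self.loglik.shape != (len(self.individuals), len(self.sites), 3):
            raise ValueError("loglik shape does not match individuals x sites x 3")
        pos = self.sites["pos"].to_numpy()
        chrom = self.sites["chrom"].to_numpy()
        same = chrom[1:] == chrom[:-1]
        if np.any(same & (pos[1:] <= pos[:-1])):
            raise ValueError("sites must be strictly increasing within chromosome")
        self.loglik = self.loglik - self.loglik.max(axis=2, keepdims=True)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def linear(self) -> np.ndarray:
        """Likelihoods on the linear scale (max 1 per individual-site)."""
        return np.exp(self.loglik)

    def informative(self) -> np.ndarray:
        """(n_ind, n_sites) bool: True where the GL triplet is not flat."""
        return ~np.all(np.isclose(self.loglik, self.loglik[:, :, :1]), axis=2)

    def subset_sites(self, index) -> "GLMatrix":
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GLMatrix(self.individuals, self.sites.iloc[idx].reset_index(drop=True),
                        self.loglik[:, idx, :])

    def subset_individuals(self, index) -> "GLMatrix":
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GLMatrix([self.individuals[i] for i in idx], self.sites,
                        self.loglik[idx])

    @classmethod
    def from_read_counts(cls, counts: np.ndarray, epsilon: float,
                         individuals, sites: pd.DataFrame) -> "GLMatrix":
        """Build from (n_ind, n_sites, 2) (ref, alt) read counts."""
        return cls(list(individuals), sites.reset_index(drop=True),
                   compute_gl(counts[..., 0], counts[..., 1], epsilon))


def compute_gl(n_ref, n_alt, epsilon: float) -> np.ndarray:
    """Genotype log-likelihoods from ref/alt read counts (vectorized).

    Accepts scalars or arrays; the genotype axis is appended last.  With
    ``epsilon == 0`` conflicting reads produce a large negative number, never
    NaN.  Zero total depth gives a flat (0, 0, 0) triplet.
    """
    if epsilon < 0 or epsilon >= 0.5:
        raise ValueError("epsilon must be in [0, 0.5)")
    n_ref = np.asarray(n_ref, dtype=float)
    n_alt = np.asarray(n_alt, dtype=float)
    if np.any(n_ref < 0) or np.any(n_alt < 0):
        raise ValueError("read counts must be >= 0")
    g = np.arange(3.0)
    p_ref = (2.0 - g) / 2.0 * (1.0 - epsilon) + g / 2.0 * epsilon
    p_alt = (2.0 - g) / 2.0 * epsilon + g / 2.0 * (1.0 - epsilon)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = (n_ref[..., None] * np.log(p_ref)
              + n_alt[..., None] * np.log(p_alt))
    ll = np.nan_to_num(ll, nan=LOG_ZERO, neginf=LOG_ZERO)
    return ll - ll.max(axis=-1, keepdims=True)


@dataclass
class SiteFrequency:
    """Per-site alt-allele frequency with a variability LR statistic."""

    freq: float
    lrt: float
    informative: bool
    n_iter: int = 0


def _em_freqs(lin: np.ndarray, tol: float = EM_TOL,
              max_iter: int = EM_MAX_ITER):
    """Vectorized allele-frequency EM under HWE for all sites at once.

    lin: (n_ind, n_sites, 3) linear-scale likelihoods.  Returns
    (freqs (n_sites,), loglik_hat (n_sites,), n_iter).
    """
    n_sites = lin.shape[1]
    p = np.full(n_sites, EM_INIT_P)
    prev = np.full(n_sites, -np.inf)
    it = 0
    for it in range(1, max_iter + 1):
        prior = np.stack([(1 - p) ** 2, 2 * p * (1 - p), p ** 2], axis=-1)
        joint = lin * prior[None, :, :]
        denom = joint.sum(axis=2)
        ll = np.log(np.maximum(denom, 1e-300)).sum(axis=0)
        eg = (joint[:, :, 1] + 2.0 * joint[:, :, 2]) / np.maximum(denom, 1e-300)
        p = eg.mean(axis=0) / 2.0
        p = np.clip(p, 0.0, 1.0)
        if np.all(np.abs(ll - prev) <= tol * (np.abs(prev) + 1.0)):
            break
        prev = ll
    prior = np.stack([(1 - p) ** 2, 2 * p * (1 - p), p ** 2], axis=-1)
    ll_hat = np.log(np.maximum((lin * prior[None]).sum(axis=2), 1e-300)).sum(axis=0)
    return p, ll_hat, it


def estimate_allele_freqs(gl: GLMatrix) -> pd.DataFrame:
    """EM alt-allele frequency and variability LRT for every site.

    The LR statistic compares the fitted frequency against p = 0
    (monomorphic reference): LR = 2 * (l(p_hat) - l(0)), distributed
    ~chi-square(1) under the null.  Sites whose GLs are flat in every
    individual are flagged non-informative and keep the initialization
    value.
    """
    lin = gl.linear()
    p, ll_hat, n_iter = _em_freqs(lin)
    ll0 = gl.loglik[:, :, 0].sum(axis=0)       # p=0: genotype 0 with prob 1
    lrt = np.maximum(2.0 * (ll_hat - ll0), 0.0)
    informative = gl.informative().any(axis=0)
    p = np.where(informative, p, EM_INIT_P)
    lrt = np.where(informative, lrt, 0.0)
    out = gl.sites.copy()
    out["freq"] = p
    out["lrt"] = lrt
    out["informative"] = informative
    return out


def estimate_allele_freq_em(gl_column: np.ndarray) -> SiteFrequency:
    """Single-site convenience wrapper around the vectorized EM.

    ``gl_column``: (n_individuals, 3) genotype log-likelihoods for one site.
    """
    col = np.asarray(gl_column, dtype=float)
    if col.ndim != 2 or col.shape[1] != 3:
        raise ValueError("expected an (n_individuals, 3) GL column")
    if col.shape[0] < 1:
        raise ValueError("need at least one individual")
    col = col - col.max(axis=1, keepdims=True)
    lin = np.exp(col)[:, None, :]
    informative = bool(np.any(~np.all(np.isclose(col, col[:, :1]), axis=1)))
    if not informative:
        return SiteFrequency(EM_INIT_P, 0.0, False, 0)
    p, ll_hat, n_iter = _em_freqs(lin)
    ll0 = col[:, 0].sum()
    return SiteFrequency(float(p[0]), float(max(2.0 * (ll_hat[0] - ll0), 0.0)),
                         True, n_iter)


def call_variable_sites(gl: GLMatrix, alpha_lrt: float = 1e-6,
                        freqs: pd.DataFrame | None = None) -> np.ndarray:
    """Boolean mask of sites whose variability LRT rejects p=0 at alpha_lrt."""
    if freqs is None:
        freqs = estimate_allele_freqs(gl)
    crit = stats.chi2.ppf(1.0 - alpha_lrt, df=1)
    return (freqs["lrt"].to_numpy() > crit) & freqs["informative"].to_numpy()


def thin_markers(sites: pd.DataFrame, window_bp: int = 5000,
                 seed: int = 0) -> np.ndarray:
    """One site per non-empty window, uniformly at random; returns row indices.

    Thinning to (by default) one marker per 5 kb reduces linkage
    disequilibrium between retained markers before clustering.
    """
    pos = sites["pos"].to_numpy()
    chrom = sites["chrom"].to_numpy()
    rng = np.random.default_rng(seed)
    keys = pd.DataFrame({"chrom": chrom, "bin": pos // window_bp,
                         "row": np.arange(len(sites))})
    picked = []
    for _, grp in keys.groupby(["chrom", "bin"], sort=True):
        picked.append(int(rng.choice(grp["row"].to_numpy())))
    return np.array(sorted(picked), dtype=int)


def _inbreeding_prior(p: np.ndarray, f: float) -> np.ndarray:
    """Genotype prior under HWE with inbreeding coefficient F."""
    q = 1.0 - p
    return np.stack([
        q * q + f * p * q,
        2.0 * p * q * (1.0 - f),
        p * p + f * p * q,
    ], axis=-1)


def estimate_inbreeding(gl: GLMatrix, freqs: pd.DataFrame) -> pd.DataFrame:
    """Per-individual inbreeding coefficient F in [0, 1].

    Maximizes, for each individual, the marginal likelihood
    sum_m log sum_g GL_mg * P(g | p_m, F) with the HWE-with-inbreeding
    genotype prior.  Individuals with no informative sites are flagged and
    get F = NaN.
    """
    p = np.clip(freqs["freq"].to_numpy(), 1e-9, 1 - 1e-9)
    lin = gl.linear()
    inform = gl.informative()
    rows = []
    for i, ind in enumerate(gl.individuals):
        if not inform[i].any():
            rows.append((ind, np.nan, False))
            continue
        li = lin[i]

        def nll(f):
            prior = _inbreeding_prior(p, f)
            return -np.log(np.maximum((li * prior).sum(axis=1), 1e-300)).sum()

        res = optimize.minimize_scalar(nll, bounds=(0.0, 1.0), method="bounded",
                                       options={"xatol": 1e-6})
        rows.append((ind, float(np.clip(res.x, 0.0, 1.0)), True))
    return pd.DataFrame(rows, columns=["individual", "F", "informative"])
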