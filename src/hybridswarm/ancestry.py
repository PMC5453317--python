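"""ADMIXTURE-style clustering on genotype likelihoods, and its downstream uses.

Model: individual i carries ancestry proportions Q_i (a point on the
K-simplex); cluster k has allele frequency F_km at site m.  The expected
alt-allele dose of one allele copy is h_im = sum_k Q_ik F_km, and the data
log-likelihood integrates over the unobserved genotype,

    loglik = sum_im log sum_g GL_img * C(2,g) h_im^g (1 - h_im)^(2-g),

maximized by EM.  Working directly on GLs (rather than called genotypes)
propagates low-coverage uncertainty into the ancestry estimates.

The same machinery, restricted to a window around a domestication locus and
combined with reference-panel composition of the clusters, yields local
"domesticated ancestry" fractions from which carriers of a domestication
allele are called at a 95% cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from hybridswarm.gl_core import GLMatrix, estimate_allele_freqs

F_CLIP = 1e-6
CARRIER_CUTOFF = 0.95
PANEL_REFERENCE_CUTOFF = 0.80
PANEL_ADMIXED_CUTOFF = 0.20


@dataclass
class AdmixtureFit:
    """Result of one admixture EM run.

    Q: (n_individuals, K) ancestry proportions (rows sum to 1).
    F: (K, n_sites) ancestral alt-allele frequencies.
    """

    K: int
    Q: np.ndarray
    F: np.ndarray
    loglik: float
    seed: int
    n_iter: int
    converged: bool
    loglik_path: np.ndarray
    individuals: list

    def summary(self) -> str:
        lines = [
            "Genotype-likelihood admixture fit",
            "=" * 48,
            f"K (clusters)        : {self.K}",
            f"individuals         : {len(self.individuals)}",
            f"sites               : {self.F.shape[1]}",
            f"log-likelihood      : {self.loglik:.4f}",
            f"EM iterations       : {self.n_iter} ({'converged' if self.converged else 'iteration cap'})",
            f"seed                : {self.seed}",
            "",
            "mean ancestry proportion per cluster:",
        ]
        for k, m in enumerate(self.Q.mean(axis=0)):
            lines.append(f"  cluster {k}: {m:.4f}")
        return "\n".join(lines)

    def q_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.Q, columns=[f"Q{k}" for k in range(self.K)])
        df.insert(0, "individual", self.individuals)
        return df


class AdmixtureModel:
    """EM estimator for the GL admixture model (fit() -> AdmixtureFit)."""

    def __init__(self, gl: GLMatrix, K: int, *, tol: float = 1e-6,
                 max_iter: int = 2000):
        if K < 1:
            raise ValueError("K must be >= 1")
        if K > gl.n_individuals:
            raise ValueError(f"K={K} exceeds the number of individuals ({gl.n_individuals})")
        if gl.n_sites == 0:
            raise ValueError("empty site set")
        self.gl = gl
        self.K = K
        self.tol = tol
        self.max_iter = max_iter
        self._lin = gl.linear()

    def _init(self, rng: np.random.Generator):
        n, m = self.gl.n_individuals, self.gl.n_sites
        Q = rng.dirichlet(np.ones(self.K), size=n)
        base = estimate_allele_freqs(self.gl)["freq"].to_numpy()
        F = np.clip(base[None, :] + rng.uniform(-0.1, 0.1, size=(self.K, m)),
                    F_CLIP, 1 - F_CLIP)
        return Q, F

    def fit(self, seed: int = 0) -> AdmixtureFit:
        rng = np.random.default_rng(seed)
        Q, F = self._init(rng)
        lin = self._lin
        n, m = lin.shape[0], lin.shape[1]
        path = []
        prev = -np.inf
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            h = np.clip(Q @ F, 1e-9, 1 - 1e-9)
            prior = np.stack([(1 - h) ** 2, 2 * h * (1 - h), h * h], axis=-1)
            joint = lin * prior
            denom = np.maximum(joint.sum(axis=2), 1e-300)
            ll = float(np.log(denom).sum())
            path.append(ll)
            e_alt = (joint[:, :, 1] + 2 * joint[:, :, 2]) / denom   # E[# alt copies]
            e_ref = 2.0 - e_alt
            # per-copy attribution to clusters (standard admixture EM):
            # alt copies split with weight Q_ik F_km / h_im, ref with
            # Q_ik (1-F_km) / (1-h_im)
            A = Q.T @ (e_alt / h)                    # (K, m)
            R = Q.T @ (e_ref / (1 - h))              # (K, m)
            F_new = np.clip(F * A / np.maximum(F * A + (1 - F) * R, 1e-300),
                            F_CLIP, 1 - F_CLIP)
            Q_new = Q * ((e_alt / h) @ F.T + (e_ref / (1 - h)) @ (1 - F).T) / (2.0 * m)
            Q_new /= Q_new.sum(axis=1, keepdims=True)
            Q, F = Q_new, F_new
            if np.isfinite(prev) and abs(ll - prev) <= self.tol * (abs(prev) + 1.0):
                converged = True
                break
            prev = ll
        h = np.clip(Q @ F, 1e-9, 1 - 1e-9)
        prior = np.stack([(1 - h) ** 2, 2 * h * (1 - h), h * h], axis=-1)
        final_ll = float(np.log(np.maximum((lin * prior).sum(axis=2), 1e-300)).sum())
        path.append(final_ll)
        return AdmixtureFit(self.K, Q, F, final_ll, seed, it, converged,
                            np.array(path), list(self.gl.individuals))

    def fit_replicates(self, n_reps: int, base_seed: int = 0) -> AdmixtureFit:
        """Best-of-n replicate optimizations; ties broken by lowest seed."""
        if n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        best = None
        for r in range(n_reps):
            fit = self.fit(seed=base_seed + r)
            if best is None or fit.loglik > best.loglik:
                best = fit
        return best


def fit_admixture(gl: GLMatrix, K: int, seed: int = 0, **kwargs) -> AdmixtureFit:
    return AdmixtureModel(gl, K, **kwargs).fit(seed=seed)


def best_of_replicates(gl: GLMatrix, K: int, n_reps: int,
                       base_seed: int = 0, **kwargs) -> AdmixtureFit:
    return AdmixtureModel(gl, K, **kwargs).fit_replicates(n_reps, base_seed)


def align_cluster_labels(fit_a: AdmixtureFit, fit_b: AdmixtureFit) -> np.ndarray:
    """Permutation mapping fit_a's clusters onto fit_b's.

    Cluster labels are arbitrary ("label switching"), so fits are compared
    after matching columns.  Returns ``perm`` with ``perm[k]`` the column of
    fit_b corresponding to column k of fit_a, chosen to maximize the summed
    Q-column correlation (optimal assignment, exact).
    """
    if fit_a.individuals != fit_b.individuals:
        raise ValueError("fits must cover the same individuals in the same order")
    if fit_a.K != fit_b.K:
        raise ValueError("fits must share K")
    qa = fit_a.Q - fit_a.Q.mean(axis=0)
    qb = fit_b.Q - fit_b.Q.mean(axis=0)
    sa = np.sqrt((qa ** 2).sum(axis=0))
    sb = np.sqrt((qb ** 2).sum(axis=0))
    corr = (qa.T @ qb) / np.maximum(np.outer(sa, sb), 1e-12)
    rows, cols = linear_sum_assignment(-corr)
    perm = np.empty(fit_a.K, dtype=int)
    perm[rows] = cols
    return perm


@dataclass
class PCAResult:
    cov: np.ndarray
    eigenvalues: np.ndarray
    components: np.ndarray    # (n_individuals, n_components), PC scores
    n_sites_used: int


def gl_pca(gl: GLMatrix, freqs: pd.DataFrame | None = None) -> PCAResult:
    """Covariance/PCA from posterior-mean genotypes standardized by p(1-p).

    Each site contributes (t_im - 2 p_m)(t_jm - 2 p_m) / (2 p_m (1 - p_m))
    where t is the posterior mean genotype under an HWE prior at the EM
    frequency; fixed sites (p in {0, 1}) are excluded.  Components are
    ordered by decreasing eigenvalue.
    """
    if gl.n_individuals < 2:
        raise ValueError("PCA needs at least 2 individuals")
    if freqs is None:
        freqs = estimate_allele_freqs(gl)
    p = freqs["freq"].to_numpy()
    keep = (p > 0) & (p < 1) & freqs["informative"].to_numpy()
    if not keep.any():
        raise ValueError("no polymorphic sites for PCA")
    p = p[keep]
    lin = gl.linear()[:, keep, :]
    prior = np.stack([(1 - p) ** 2, 2 * p * (1 - p), p ** 2], axis=-1)
    joint = lin * prior[None]
    post = joint / np.maximum(joint.sum(axis=2, keepdims=True), 1e-300)
    t = post[:, :, 1] + 2.0 * post[:, :, 2]
    x = (t - 2.0 * p[None, :]) / np.sqrt(2.0 * p * (1.0 - p))[None, :]
    cov = (x @ x.T) / x.shape[1]
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    scores = v * np.sqrt(np.maximum(w, 0.0))[None, :]
    return PCAResult(cov=cov, eigenvalues=w, components=scores,
                     n_sites_used=int(keep.sum()))


@dataclass
class CarrierCall:
    individual: str
    locus: str
    fraction: float
    carrier: bool


def classify_carriers(fractions: pd.Series | dict, locus: str,
                      cutoff: float = CARRIER_CUTOFF) -> list:
    """Carrier calls at a domestication locus: carrier iff fraction >= cutoff.

    The boundary is inclusive ("at least 95% domesticated ancestry").
    """
    items = fractions.items() if hasattr(fractions, "items") else fractions
    calls = []
    for ind, frac in items:
        if not 0.0 <= frac <= 1.0 + 1e-9:
            raise ValueError(f"fraction {frac} outside [0, 1] for {ind}")
        calls.append(CarrierCall(ind, locus, float(frac), bool(frac >= cutoff)))
    return calls


def window_ancestry(gl_region: GLMatrix, K: int, panel: dict, *,
                    seed: int = 0, n_reps: int = 5, min_sites: int = 10,
                    dom_mass_cutoff: float = 0.5) -> pd.Series:
    """Per-individual domesticated-ancestry fraction in a genomic region.

    Fits the admixture model on the region's sites only, then labels a
    cluster "domesticated" when more than ``dom_mass_cutoff`` of its Q mass
    over the reference-panel individuals comes from the domesticated
    references.  ``panel`` maps individual -> 'dom' | 'wild' for reference
    individuals (others are targets).  Returns the summed ancestry from
    domesticated clusters, indexed by individual.
    """
    if gl_region.n_sites < min_sites:
        raise ValueError(
            f"region has {gl_region.n_sites} sites; minimum is {min_sites}")
    fit = AdmixtureModel(gl_region, K).fit_replicates(n_reps, base_seed=seed)
    ind = list(gl_region.individuals)
    dom_ref = np.array([panel.get(i) == "dom" for i in ind])
    wild_ref = np.array([panel.get(i) == "wild" for i in ind])
    if not dom_ref.any() or not wild_ref.any():
        raise ValueError("panel must contain both 'dom' and 'wild' reference individuals")
    dom_mass = fit.Q[dom_ref].sum(axis=0)
    wild_mass = fit.Q[wild_ref].sum(axis=0)
    frac_dom = dom_mass / np.maximum(dom_mass + wild_mass, 1e-300)
    dom_clusters = frac_dom > dom_mass_cutoff
    return pd.Series(fit.Q[:, dom_clusters].sum(axis=1), index=ind,
                     name="dom_fraction")


@dataclass
class PanelAssignment:
    individual: str
    role: str          # reference_wild | reference_<group> | admixed | unassigned


def build_reference_panels(fit: AdmixtureFit, carrier_calls: list,
                           is_wild: dict, wild_clusters: list,
                           donor_clusters: dict) -> pd.DataFrame:
    """Partition individuals into reference and target panels.

    Rules (applied exactly):
      * wild individual with >= 80% ancestry from ONE wild-specific cluster
        and carrying no domestication allele at any scored locus
        -> reference wild;
      * domesticated individual with >= 80% ancestry from one donor cluster
        -> reference panel of that donor group;
      * wild individual with summed donor-cluster ancestry >= 20%
        -> admixed target;
      * everyone else -> unassigned.
    """
    carriers = {}
    for c in carrier_calls:
        carriers.setdefault(c.individual, False)
        carriers[c.individual] = carriers[c.individual] or c.carrier
    rows = []
    for i, ind in enumerate(fit.individuals):
        q = fit.Q[i]
        wildq = q[wild_clusters] if wild_clusters else np.array([])
        donorq = {g: q[k] for g, k in donor_clusters.items()}
        role = "unassigned"
        if is_wild[ind]:
            if wildq.size and wildq.max() >= PANEL_REFERENCE_CUTOFF \
                    and not carriers.get(ind, False):
                role = "reference_wild"
            elif sum(donorq.values()) >= PANEL_ADMIXED_CUTOFF:
                role = "admixed"
        else:
            for g, qk in donorq.items():
                if qk >= PANEL_REFERENCE_CUTOFF:
                    role = f"reference_{g}"
                    break
        rows.append((ind, role))
    out = pd.DataFrame(rows, columns=["individual", "role"])
    required = ["reference_wild"] + [f"reference_{g}" for g in donor_clusters]
    missing = [r for r in required if not (out["role"] == r).any()]
    if missing:
        raise ValueError(
            "empty reference panel(s): " + ", ".join(missing)
            + " — check cluster assignments and the 80% rule")
    return out
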