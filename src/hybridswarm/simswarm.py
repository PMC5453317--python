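"""Synthetic hybrid-swarm generator with known truth.

Emulates the population-genetic structure of a crop-wild species complex:
two long-diverged source populations (wild and domesticated, the latter
bottlenecked and split into subgroups), hard selective sweeps at
"domestication loci" shared by all domesticated subgroups, timed one-way
admixture pulses from domesticated subgroups into wild demes, recombination
generating ancestry tracts, low-coverage read sampling with sequencing
error, and maternally inherited non-recombining chloroplast haplotypes.

Neutral variation is simulated with msprime (coalescent with demography).
Admixture pulses are then painted onto recipient haplotypes with a
two-state Markov mosaic along the genetic map: a pulse of proportion
``alpha`` that occurred ``g`` generations ago leaves donor tracts whose
lengths are approximately exponential with mean ``1/((1-alpha)*g)`` Morgans
and whose genome-wide expectation is ``alpha``.  This yields exact truth
tracts (the acceptance oracle) while keeping all background structure
coalescent.

Coordinates are 0-based, half-open everywhere in memory; VCF output is
1-based.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import msprime
import numpy as np
import pandas as pd

WILD_LABEL = "wild"


@dataclass(frozen=True)
class Pulse:
    """A one-way admixture pulse from a domesticated donor group into a wild deme.

    Parameters
    ----------
    donor : name of the domesticated donor subgroup.
    recipient : name of the recipient wild deme.
    alpha : admixture proportion in [0, 1].
    g : generations since the pulse (> 0).
    seed_mediated : if True the pulse transmits the donor chloroplast down
        the maternal line (seed dispersal); pollen-mediated pulses do not.
    """

    donor: str
    recipient: str
    alpha: float
    g: int
    seed_mediated: bool = False

    def validate(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"pulse alpha {self.alpha} outside [0, 1]")
        if self.g <= 0:
            raise ValueError(f"pulse age g={self.g} must be > 0")


@dataclass
class GeneticMap:
    """Piecewise-linear bp <-> cM map (monotone, covering [0, L])."""

    positions: np.ndarray
    cm: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.cm = np.asarray(self.cm, dtype=float)
        if np.any(np.diff(self.positions) <= 0) or np.any(np.diff(self.cm) < 0):
            raise ValueError("genetic map must be strictly increasing in bp and monotone in cM")

    @classmethod
    def uniform(cls, length_bp: float, cm_per_mb: float) -> "GeneticMap":
        return cls(np.array([0.0, float(length_bp)]),
                   np.array([0.0, float(length_bp) / 1e6 * cm_per_mb]))

    @property
    def length_bp(self) -> float:
        return float(self.positions[-1])

    @property
    def total_cm(self) -> float:
        return float(self.cm[-1])

    def bp_to_cm(self, bp) -> np.ndarray:
        return np.interp(bp, self.positions, self.cm)

    def cm_to_bp(self, cm) -> np.ndarray:
        return np.interp(cm, self.cm, self.positions)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"pos_bp": self.positions.astype(int), "cm": self.cm})


def _default_dom_groups() -> dict:
    return {"indica": 12, "aus": 12, "japonica": 12}


def _default_pulses() -> list:
    # Study conditions: recent seed-mediated gene flow from indica, older
    # pollen-mediated gene flow from japonica, into the single wild deme.
    return [
        Pulse("japonica", WILD_LABEL, alpha=0.10, g=80, seed_mediated=False),
        Pulse("indica", WILD_LABEL, alpha=0.25, g=10, seed_mediated=True),
    ]


@dataclass
class ScenarioConfig:
    """Full parameterization of a synthetic hybrid swarm.

    Defaults describe a rice-like system: annual generations, domestication
    ~9000 generations ago with a strong bottleneck, two hard-swept
    domestication loci shared by all domesticated subgroups, high selfing in
    the crop and partial selfing in the wild.
    """

    n_wild: int | Mapping[str, int] = 24
    n_dom_per_group: Mapping[str, int] = field(default_factory=_default_dom_groups)
    L: int = 1_000_000
    rho: float = 1e-8           # recombination / bp / generation (1 cM/Mb)
    mu: float = 3e-8            # mutation / bp / generation
    Ne_wild: int = 25_000
    Ne_dom: int = 10_000
    t_split: int = 9_000        # generations since wild/domesticated divergence
    t_dom_groups: int = 3_000   # domesticated subgroups diverge post-domestication
    t_wild_demes: int = 5_000
    bottleneck: tuple = (6_500, 2_000, 1_500)  # (start gen ago, duration, size)
    sweep_loci: Sequence[tuple] = ((250_000, 1_500), (750_000, 1_500))
    sweep_names: Sequence[str] = ("sh4", "prog1")
    sweep_width: int = 200_000
    pulses: Sequence[Pulse] = field(default_factory=_default_pulses)
    selfing_rate_wild: float = 0.3
    selfing_rate_dom: float = 0.99
    depth_mean: float = 5.0
    error_rate: float = 0.01
    cp_L: int = 120_000
    map_cm_per_mb: float | None = None   # genetic map density; default rho*1e8
    deme_coords: Mapping[str, tuple] | None = None
    seed: int = 1

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise ValueError("L must be > 0")
        for name, val in (("selfing_rate_wild", self.selfing_rate_wild),
                          ("selfing_rate_dom", self.selfing_rate_dom)):
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} outside [0, 1]")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        if self.depth_mean < 0:
            raise ValueError("depth_mean must be >= 0")
        self.pulses = [p if isinstance(p, Pulse) else Pulse(**p) for p in self.pulses]
        for p in self.pulses:
            p.validate()
            if p.g >= self.t_split:
                raise ValueError(f"pulse age g={p.g} must predate the split ({self.t_split})")
            if p.donor not in self.n_dom_per_group:
                raise ValueError(f"unknown pulse donor {p.donor!r}")
            if p.recipient not in self.wild_demes:
                raise ValueError(f"unknown pulse recipient deme {p.recipient!r}")
        for pos, _ in self.sweep_loci:
            if not 0 <= pos < self.L:
                raise ValueError(f"sweep locus {pos} outside [0, L)")
        if len(self.sweep_names) != len(self.sweep_loci):
            raise ValueError("sweep_names must match sweep_loci")

    @property
    def wild_demes(self) -> dict:
        if isinstance(self.n_wild, Mapping):
            return dict(self.n_wild)
        return {WILD_LABEL: int(self.n_wild)}

    @property
    def cm_per_mb(self) -> float:
        if self.map_cm_per_mb is not None:
            return float(self.map_cm_per_mb)
        return self.rho * 1e8

    @property
    def genetic_map(self) -> GeneticMap:
        return GeneticMap.uniform(self.L, self.cm_per_mb)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["pulses"] = [dataclasses.asdict(p) for p in self.pulses]
        d["sweep_loci"] = [list(x) for x in self.sweep_loci]
        d["sweep_names"] = list(self.sweep_names)
        if isinstance(d["n_dom_per_group"], Mapping):
            d["n_dom_per_group"] = dict(d["n_dom_per_group"])
        return d


@dataclass
class TruthSet:
    """Ground truth of a simulated swarm (the acceptance oracle).

    dosage : (n_individuals, n_sites) donor-ancestry dosage in {0, 0.5, 1}.
    tracts : one row per ancestry tract per haplotype; tracts tile each
        chromosome without overlap.  Columns: individual, hap, chrom,
        start, end, start_cm, end_cm, length_cm, label.
    cp_donor : per-individual chloroplast donor group ("" if the maternal
        line is wild).
    sweep_sites : locus name -> column index of the focal domestication SNP.
    """

    dosage: np.ndarray
    tracts: pd.DataFrame
    cp_donor: np.ndarray
    sweep_sites: dict

    def donor_tracts(self) -> pd.DataFrame:
        return self.tracts[self.tracts["label"] != WILD_LABEL].reset_index(drop=True)

    def donor_fraction(self, individual: str) -> float:
        t = self.tracts[self.tracts["individual"] == individual]
        tot = float((t["end"] - t["start"]).sum())
        don = float((t.loc[t["label"] != WILD_LABEL, "end"]
                     - t.loc[t["label"] != WILD_LABEL, "start"]).sum())
        return don / tot if tot else 0.0


@dataclass
class SwarmDataset:
    """A simulated hybrid swarm: phased haplotypes, map, metadata and truth."""

    config: ScenarioConfig
    individuals: list
    group: np.ndarray          # source deme / subgroup per individual
    is_wild: np.ndarray
    lat: np.ndarray
    lon: np.ndarray
    selfed: np.ndarray
    haplotypes: np.ndarray     # (2n, n_sites) int8, phased: ind i <-> rows 2i, 2i+1
    positions: np.ndarray      # bp, strictly increasing
    genetic_map: GeneticMap
    truth: TruthSet
    cp_haplotypes: np.ndarray  # (n, n_cp_sites) int8, haploid
    cp_positions: np.ndarray
    chrom: str = "1"

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    def genotypes(self) -> np.ndarray:
        """Diploid alt-allele dosage matrix (n_individuals, n_sites)."""
        return (self.haplotypes[0::2] + self.haplotypes[1::2]).astype(np.int8)

    def hap_indices(self, mask: np.ndarray) -> np.ndarray:
        """Haplotype row indices for the individuals selected by ``mask``."""
        idx = np.flatnonzero(mask)
        return np.ravel(np.column_stack([2 * idx, 2 * idx + 1]))

    def sites(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chrom": self.chrom,
            "pos": self.positions.astype(int),
            "ref": "A",
            "alt": "C",
        })

    def metadata(self) -> pd.DataFrame:
        return pd.DataFrame({
            "individual": self.individuals,
            "group": self.group,
            "class": np.where(self.is_wild, "wild", "domesticated"),
            "region": self.group,
            "lat": self.lat,
            "lon": self.lon,
        })


# ---------------------------------------------------------------------------
# demography and raw coalescent haplotypes


def _demography(cfg: ScenarioConfig) -> msprime.Demography:
    dem = msprime.Demography()
    dem.add_population(name="anc", initial_size=cfg.Ne_wild)
    dem.add_population(name="wild_anc", initial_size=cfg.Ne_wild)
    dem.add_population(name="dom_anc", initial_size=cfg.Ne_dom)
    wild = list(cfg.wild_demes)
    dom = list(cfg.n_dom_per_group)
    for d in wild:
        dem.add_population(name=d, initial_size=cfg.Ne_wild)
    for g in dom:
        dem.add_population(name=g, initial_size=cfg.Ne_dom)
    if len(wild) > 1 or wild != ["wild_anc"]:
        dem.add_population_split(time=cfg.t_wild_demes, derived=wild, ancestral="wild_anc")
    dem.add_population_split(time=cfg.t_dom_groups, derived=dom, ancestral="dom_anc")
    if cfg.bottleneck is not None:
        start, duration, size = cfg.bottleneck
        dem.add_population_parameters_change(time=start, population="dom_anc",
                                             initial_size=size)
        dem.add_population_parameters_change(time=min(start + duration, cfg.t_split - 1),
                                             population="dom_anc",
                                             initial_size=cfg.Ne_dom)
    dem.add_population_split(time=cfg.t_split, derived=["wild_anc", "dom_anc"],
                             ancestral="anc")
    dem.sort_events()
    return dem


def _simulate_haplotypes(cfg: ScenarioConfig, n_per_pop: Mapping[str, int],
                         length: int, recomb: float, seed: int):
    """Haploid coalescent sample: returns (haplotypes (n, sites), positions)."""
    samples = [msprime.SampleSet(n, population=p, ploidy=1)
               for p, n in n_per_pop.items() if n > 0]
    ts = msprime.sim_ancestry(
        samples=samples, demography=_demography(cfg), sequence_length=length,
        recombination_rate=recomb, ploidy=1, random_seed=seed,
    )
    mts = msprime.sim_mutations(ts, rate=cfg.mu, random_seed=seed + 7,
                                model=msprime.BinaryMutationModel())
    hap = mts.genotype_matrix().T.astype(np.int8)
    hap = np.clip(hap, 0, 1)
    positions = np.array([int(s.position) for s in mts.sites()], dtype=np.int64)
    keep = np.ones(len(positions), dtype=bool)
    keep[1:] = positions[1:] > positions[:-1]   # discrete genome: dedupe collisions
    return hap[:, keep], positions[keep]


# ---------------------------------------------------------------------------
# sweeps


def impose_sweep(haplotypes: np.ndarray, positions: np.ndarray, L: int,
                 locus: int, width: int, swept_rows: np.ndarray, *,
                 post_mut_mean: float = 0.0,
                 rng: np.random.Generator | None = None):
    """Impose a hard selective sweep on the given haplotype rows.

    All ``swept_rows`` are replaced, within ``[locus - width/2, locus + width/2)``,
    by copies of one founder haplotype (the lowest swept row); each swept
    haplotype then receives ``Poisson(post_mut_mean)`` post-sweep mutations at
    random in-window sites.  A focal "domestication SNP" at ``locus`` is
    created if absent and set to the alternate allele on every swept
    haplotype.

    Returns (haplotypes, positions, focal_site_index); arrays are new objects
    when a focal column is inserted, otherwise modified in place.
    """
    if not 0 <= locus < L:
        raise ValueError(f"locus {locus} outside [0, {L})")
    if width > L:
        raise ValueError(f"sweep width {width} exceeds chromosome length {L}")
    if width == 0:
        focal = int(np.searchsorted(positions, locus))
        if focal >= len(positions) or positions[focal] != locus:
            raise ValueError("width=0 requires an existing focal site")
        return haplotypes, positions, focal
    rng = np.random.default_rng() if rng is None else rng
    lo, hi = locus - width // 2, locus + width // 2
    in_win = np.flatnonzero((positions >= lo) & (positions < hi))
    founder = int(np.min(swept_rows))
    haplotypes[swept_rows[:, None], in_win[None, :]] = haplotypes[founder, in_win]
    if post_mut_mean > 0 and len(in_win):
        for row in swept_rows:
            k = rng.poisson(post_mut_mean)
            if k:
                cols = rng.choice(in_win, size=min(k, len(in_win)), replace=False)
                haplotypes[row, cols] = 1 - haplotypes[row, cols]
    idx = int(np.searchsorted(positions, locus))
    if idx < len(positions) and positions[idx] == locus:
        focal = idx
    else:
        col = np.zeros((haplotypes.shape[0], 1), dtype=haplotypes.dtype)
        haplotypes = np.concatenate([haplotypes[:, :idx], col, haplotypes[:, idx:]], axis=1)
        positions = np.insert(positions, idx, locus)
        focal = idx
    haplotypes[swept_rows, focal] = 1
    return haplotypes, positions, focal


# ---------------------------------------------------------------------------
# admixture mosaics


def _mosaic_segments(alpha: float, g: int, total_morgans: float,
                     rng: np.random.Generator) -> list:
    """Donor/wild segment structure (in Morgans) of one admixed haplotype.

    Two-state Markov process along the map: stationary donor probability
    ``alpha``; switch rates per Morgan are ``(1 - alpha) * g`` out of donor
    and ``alpha * g`` into donor, so donor tract lengths are ~Exp with mean
    ``1 / ((1 - alpha) * g)`` Morgans.
    """
    if alpha == 0.0:
        return [(0.0, total_morgans, False)]
    if alpha == 1.0:
        return [(0.0, total_morgans, True)]
    rates = {True: (1.0 - alpha) * g, False: alpha * g}
    state = bool(rng.random() < alpha)
    segs, pos = [], 0.0
    while pos < total_morgans:
        step = rng.exponential(1.0 / rates[state])
        end = min(pos + step, total_morgans)
        segs.append((pos, end, state))
        pos, state = end, not state
    return segs


def _overlay(base: list, donor_intervals: list, label: str) -> list:
    """Overlay labelled donor intervals onto a (start, end, label) tiling."""
    if not donor_intervals:
        return base
    out = []
    for s, e, lab in base:
        cur = s
        for ds, de in donor_intervals:
            if de <= cur or ds >= e:
                continue
            ds_, de_ = max(ds, cur), min(de, e)
            if ds_ > cur:
                out.append((cur, ds_, lab))
            out.append((ds_, de_, label))
            cur = de_
        if cur < e:
            out.append((cur, e, lab))
    merged = [out[0]]
    for seg in out[1:]:
        if seg[2] == merged[-1][2] and seg[0] == merged[-1][1]:
            merged[-1] = (merged[-1][0], seg[1], seg[2])
        else:
            merged.append(seg)
    return merged


def _paint_pulse(hap_rows: np.ndarray, segments: dict, haplotypes: np.ndarray,
                 positions: np.ndarray, donor_pool: np.ndarray, pulse: Pulse,
                 gmap: GeneticMap, selfed_pairs: dict,
                 rng: np.random.Generator) -> None:
    """Apply one pulse's mosaics to recipient haplotype rows, in place."""
    total_m = gmap.total_cm / 100.0
    done = set()
    for row in hap_rows:
        if row in done:
            continue
        partner = selfed_pairs.get(row)
        segs_m = _mosaic_segments(pulse.alpha, pulse.g, total_m, rng)
        donor_iv = []
        for s, e, is_donor in segs_m:
            if not is_donor:
                continue
            bs = float(gmap.cm_to_bp(s * 100.0))
            be = float(gmap.cm_to_bp(e * 100.0))
            donor_iv.append((bs, be))
            src = int(rng.choice(donor_pool))
            i0, i1 = np.searchsorted(positions, [bs, be])
            haplotypes[row, i0:i1] = haplotypes[src, i0:i1]
        segments[row] = _overlay(segments[row], donor_iv, pulse.donor)
        done.add(row)
        if partner is not None:
            haplotypes[partner] = haplotypes[row]
            segments[partner] = list(segments[row])
            done.add(partner)


# ---------------------------------------------------------------------------
# reads and chloroplast


def emit_reads(haplotypes: np.ndarray, depth_mean: float, epsilon: float,
               seed: int) -> np.ndarray:
    """Sample per-individual, per-site read counts from phased haplotypes.

    Depth is Poisson(``depth_mean``); each read draws one of the two parental
    alleles uniformly and reports it correctly with probability
    ``1 - epsilon``.  Returns an int array (n_individuals, n_sites, 2) of
    (ref, alt) counts.
    """
    if depth_mean < 0:
        raise ValueError("depth_mean must be >= 0")
    if not 0.0 <= epsilon < 0.5:
        raise ValueError("epsilon must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    gt = haplotypes[0::2].astype(np.int16) + haplotypes[1::2]
    depth = rng.poisson(depth_mean, size=gt.shape)
    alt_true = np.where(gt == 1, rng.binomial(depth, 0.5),
                        np.where(gt == 2, depth, 0))
    alt_obs = rng.binomial(alt_true, 1.0 - epsilon) + rng.binomial(depth - alt_true, epsilon)
    return np.stack([depth - alt_obs, alt_obs], axis=-1)


def simulate_chloroplast(cfg: ScenarioConfig, n_per_pop: Mapping[str, int],
                         pulse_membership: Mapping[str, np.ndarray],
                         seed: int):
    """Haploid, non-recombining chloroplast haplotypes plus maternal-line donors.

    Seed-mediated pulses transmit the donor chloroplast: each recipient
    individual's maternal line traces to the donor with probability alpha
    (independently per seed-mediated pulse, oldest first); pollen-mediated
    pulses never do.  Returns (cp_haplotypes (n, sites), positions,
    cp_donor (n,) of donor-group names, "" for wild maternal lines).
    """
    rng = np.random.default_rng(seed)
    hap, positions = _simulate_haplotypes(cfg, n_per_pop, cfg.cp_L, 0.0, seed + 13)
    n = hap.shape[0]
    cp_donor = np.array([""] * n, dtype=object)
    for pulse in sorted(cfg.pulses, key=lambda p: -p.g):
        recipients = pulse_membership["recipient:" + pulse.recipient]
        donors = pulse_membership["donor:" + pulse.donor]
        if not pulse.seed_mediated:
            continue
        for i in recipients:
            if rng.random() < pulse.alpha:
                src = int(rng.choice(donors))
                hap[i] = hap[src]
                cp_donor[i] = pulse.donor
    return hap, positions, cp_donor


# ---------------------------------------------------------------------------
# main entry


def _deme_coords(cfg: ScenarioConfig) -> dict:
    if cfg.deme_coords is not None:
        return dict(cfg.deme_coords)
    coords = {}
    for i, d in enumerate(cfg.wild_demes):
        coords[d] = (22.0 - 3.0 * i, 90.0 + 4.0 * i)
    for i, g in enumerate(cfg.n_dom_per_group):
        coords[g] = (25.0 - 2.0 * i, 100.0 + 3.0 * i)
    return coords


def simulate_swarm(cfg: ScenarioConfig) -> SwarmDataset:
    """Simulate a hybrid swarm with known truth.

    Order of operations: coalescent haplotypes for all demes/groups; hard
    sweeps imposed on all domesticated haplotypes at each domestication
    locus; diploid pairing with selfing-controlled haplotype identity;
    admixture-pulse mosaics painted onto recipient wild individuals (oldest
    pulse first, recent pulses overwrite); chloroplast transmission down the
    maternal line.  Fully deterministic under ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    wild_demes = cfg.wild_demes
    dom_groups = dict(cfg.n_dom_per_group)
    pops = {**wild_demes, **dom_groups}
    n_hap_per_pop = {p: 2 * n for p, n in pops.items()}
    hap, positions = _simulate_haplotypes(cfg, n_hap_per_pop, cfg.L, cfg.rho,
                                          cfg.seed + 1)

    # haplotype row bookkeeping, in sample-set order
    hap_slices, start = {}, 0
    for p, n in n_hap_per_pop.items():
        hap_slices[p] = np.arange(start, start + n)
        start += n
    dom_rows = np.concatenate([hap_slices[g] for g in dom_groups]) if dom_groups else np.array([], int)

    # domestication sweeps, shared founder across all domesticated subgroups
    sweep_sites = {}
    for name, (locus, t_origin) in zip(cfg.sweep_names, cfg.sweep_loci):
        hap, positions, focal = impose_sweep(
            hap, positions, cfg.L, locus, cfg.sweep_width, dom_rows,
            post_mut_mean=cfg.mu * t_origin * cfg.sweep_width, rng=rng)
        sweep_sites[name] = focal

    # diploids: per population, pair consecutive haplotypes; with probability
    # F_eq = s/(2-s) (equilibrium inbreeding under partial selfing) the
    # second haplotype is an identical copy of the first
    individuals, group, is_wild, selfed = [], [], [], []
    selfed_pairs = {}
    for p in pops:
        s = cfg.selfing_rate_wild if p in wild_demes else cfg.selfing_rate_dom
        f_eq = s / (2.0 - s) if s < 1 else 1.0
        rows = hap_slices[p]
        for j in range(len(rows) // 2):
            a, b = int(rows[2 * j]), int(rows[2 * j + 1])
            ind_selfed = bool(rng.random() < f_eq)
            if ind_selfed:
                hap[b] = hap[a]
                selfed_pairs[a] = b
            individuals.append(f"{p}_{j:03d}")
            group.append(p)
            is_wild.append(p in wild_demes)
            selfed.append(ind_selfed)
    group = np.array(group, dtype=object)
    is_wild = np.array(is_wild, dtype=bool)
    selfed = np.array(selfed, dtype=bool)
    n_ind = len(individuals)

    gmap = cfg.genetic_map
    segments = {r: [(0.0, float(cfg.L), WILD_LABEL)] for r in range(hap.shape[0])}

    # pulses, oldest first so recent donor tracts overwrite older ones
    for pulse in sorted(cfg.pulses, key=lambda p: -p.g):
        rec_rows = hap_slices[pulse.recipient]
        donor_pool = hap_slices[pulse.donor]
        _paint_pulse(rec_rows, segments, hap, positions, donor_pool, pulse,
                     gmap, selfed_pairs, rng)

    # truth: tracts and per-site dosage
    tract_rows = []
    ind_of_hap = np.repeat(np.arange(n_ind), 2)
    donor_mask = np.zeros((hap.shape[0], len(positions)), dtype=bool)
    for r in range(hap.shape[0]):
        for s, e, lab in segments[r]:
            tract_rows.append((individuals[ind_of_hap[r]], r % 2, "1",
                               int(round(s)), int(round(e)),
                               float(gmap.bp_to_cm(s)), float(gmap.bp_to_cm(e)),
                               float(gmap.bp_to_cm(e) - gmap.bp_to_cm(s)), lab))
            if lab != WILD_LABEL:
                i0, i1 = np.searchsorted(positions, [s, e])
                donor_mask[r, i0:i1] = True
    tracts = pd.DataFrame(tract_rows, columns=[
        "individual", "hap", "chrom", "start", "end",
        "start_cm", "end_cm", "length_cm", "label"])
    dosage = (donor_mask[0::2].astype(float) + donor_mask[1::2]) / 2.0

    # chloroplast
    membership = {}
    ind_idx_of_pop = {p: np.flatnonzero(group == p) for p in pops}
    for pulse in cfg.pulses:
        membership["recipient:" + pulse.recipient] = ind_idx_of_pop[pulse.recipient]
        membership["donor:" + pulse.donor] = ind_idx_of_pop[pulse.donor]
    cp_hap, cp_pos, cp_donor = simulate_chloroplast(cfg, pops, membership,
                                                    cfg.seed + 2)

    coords = _deme_coords(cfg)
    lat = np.array([coords[g][0] for g in group]) + rng.normal(0, 0.4, n_ind)
    lon = np.array([coords[g][1] for g in group]) + rng.normal(0, 0.4, n_ind)

    truth = TruthSet(dosage=dosage, tracts=tracts, cp_donor=cp_donor,
                     sweep_sites=sweep_sites)
    return SwarmDataset(
        config=cfg, individuals=individuals, group=group, is_wild=is_wild,
        lat=lat, lon=lon, selfed=selfed, haplotypes=hap, positions=positions,
        genetic_map=gmap, truth=truth, cp_haplotypes=cp_hap,
        cp_positions=cp_pos,
    )
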