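# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limits of what the test suite demonstrates.

## The inference problem

Wild relatives of a selfing crop form a hybrid swarm: genomes that are
mosaics of wild and domesticated ancestry, produced by recurrent pollen
flow and by feralization (escaped crop seed re-establishing in the wild and
backcrossing). The package infers, from low-coverage sequencing data:

1. global ancestry proportions per accession (GL admixture model),
2. which "wild" accessions carry domestication alleles at swept loci
   (window local ancestry, 95 % carrier cutoff),
3. the sweep signature itself (π-ratio reduction, negative Tajima's D,
   d_XY collapse between carriers and the crop),
4. the age ordering of admixture sources (ancestry-tract lengths in cM),
5. the seed- vs pollen-mediated route (chloroplast haplotype sharing), and
6. geographic structure of the gene flow (distance correlations, χ²).

## Genotype-likelihood core

All estimators consume GLs rather than called genotypes, because at ~5×
coverage hard calls systematically under-call heterozygotes. The read model
assumes symmetric error ε and independent reads. Missing data is a flat GL
triplet; because every EM weights genotypes by GL × prior, flat triplets
contribute exactly their prior and thus no information — no special-casing
is needed.

Allele-frequency EM (HWE prior) stops when the relative log-likelihood
change is < 1e−8 or at 200 iterations, initialized at p = 0.2. Variability
is tested with LR = 2(l(p̂) − l(0)) against χ²(1); the calling threshold
`alpha_lrt` defaults to 1e−6 (exposed in config: the appropriate stringency
depends on site count). Inbreeding coefficients maximize the per-individual
marginal likelihood under the HWE-with-inbreeding prior
P(het) = 2pq(1−F); the optimizer is bounded scalar maximization on [0, 1],
which is equivalent to (and simpler than) an EM fixed point here.

## Admixture model

The K-cluster model treats each of an individual's two allele copies at
site m as drawn from cluster k with probability Q_ik and then alt with
probability F_km. EM updates attribute expected alt/ref copies to clusters
by Q_ik F_km / h_im and Q_ik (1−F_km) / (1−h_im). Numerics: F is clipped to
[1e−6, 1−1e−6] (keeps the objective finite; the fitted log-likelihood can
therefore sit within ~1e−3 of the unconstrained optimum on degenerate toy
data); Q rows are renormalized each iteration; convergence is relative
log-likelihood change < 1e−6 with a 2000-iteration cap. Initialization: Q
from a symmetric Dirichlet(1), F from jittered EM site frequencies, all
seeded. Multi-start (`fit_replicates`) keeps the best log-likelihood, ties
broken by lowest seed. Label switching across fits is resolved by optimal
assignment (Hungarian) on Q-column correlations.

K selection is left to the user: fits are reported for a K range, and the
window classifier takes K explicitly (K = 5 is the default at domestication
loci, where the crop's single swept haplotype plus four wild components is
the expected structure).

**Domesticated-cluster identification.** In `window_ancestry`, a cluster is
"domesticated" when more than half its Q mass *over the reference-panel
individuals* comes from domesticated references. Restricting the mass to
panel members prevents heavily introgressed targets (which legitimately
load on the domesticated cluster) from diluting the identification.

## Window statistics

Windows are 10 kb, non-overlapping, half-open; the last partial window is
kept and flagged. π uses the unbiased per-site form 2p̂q̂·n/(n−1) summed and
divided by window bp — frequencies come from the GL EM rather than from an
SFS likelihood; this matches the estimator class at desk scale and is the
documented simplification relative to full SFS machinery. Tajima's D uses
the standard constants and is undefined (NaN, flagged) at S = 0. d_XY
averages p_X q_Y + p_Y q_X over sites polymorphic in the pooled sample by
default ("either"/"both" rules are switchable — the choice matters only for
fixed differences, which the pooled rule includes). F_ST is Hudson's
ratio-of-averages by default with Weir–Cockerham as the alternative.

Diversity-reduction scans rank windows (or genes) ascending by
π_pop/π_ref; the reported percentile is rank/N·100, so "top 0.3 %" means
percentile ≤ 0.3. Windows with π_ref = 0 are excluded and flagged.

## Local ancestry and tract dating

The classifier is an unphased per-window maximum composite likelihood:
label = argmax over panels of Σ_sites log Σ_g GL(g)·Binom(g; 2, p_panel),
with a margin to the runner-up, a minimum of 10 informative sites per
window (otherwise "unassigned"), and an optional majority filter of radius
1 that cannot erase runs longer than the radius. Maximal same-label runs
become tracts; cM lengths come from interpolating the genetic map at run
boundaries. Unassigned runs are emitted as their own tracts so the tract
set tiles the chromosome exactly, but they are excluded from donor
summaries.

This replaces a phased CRF/HMM classifier deliberately: the downstream use
is only the per-donor tract-length distribution, and in a predominantly
selfing system most individuals are homozygous along their mosaics, so the
diploid window label coincides with the haplotype label. The limit of this
design is outbred heterozygous-ancestry regions (diploid dosage 0.5), where
the window label is genuinely ambiguous and tracts fragment; tract dating
should therefore be read on selfed/homozygous material, which is the
realistic regime here. Tract means order admixture events in time (mean
≈ 1/((1−α)g) Morgans); no absolute calendar dating is attempted because
that would additionally require a trusted map length and generation time.

## Chloroplast network

Haplotypes are defined over sites with minor-allele frequency ≥ 0.05
(default) and collapsed exactly; haplotypes with fewer than 2 carriers
(default) are dropped from the network but reported. The network is a
minimum spanning tree over Hamming distances with deterministic
tie-breaking (distance, then lexicographic ids) — topology choice does not
affect the sharing counts the inference rests on, which only require
haplotype identity. Rooting picks the in-network haplotype nearest the
outgroup string; ties are flagged. Per-subgroup sharing excess is tested
against the overall wild sharing rate by χ² goodness of fit, with Fisher's
exact test on the subgroup-vs-rest table as a companion, since the
appropriate null proportion is itself a modelling choice.

## Geographic statistics

Geographic distance is great-circle (spherical Earth, R = 6371.0088 km).
The distance–genetic-distance correlation is Spearman by default (Pearson
switchable) and its p-value comes from permuting the genetic-distance
vector, because crop–wild pairs share members and parametric p-values are
invalid under that dependence. Genetic distance between accessions defaults
to 1 − IBS over thinned markers. The uniform-gene-flow test is the
carriers/non-carriers × region homogeneity χ² (no continuity correction),
with regions under 10 samples excluded; expected cells < 1 flag the result
and trigger Fisher's exact test in the two-region case. Label enrichment is
a one-sided hypergeometric tail per label with Bonferroni over tested
labels; the "top" set is round(N·fraction), at least 1.

## The synthetic-data generator

`simswarm` emulates the features the analysis relies on, with defaults
chosen as a realistic rice-like scenario and treated as fixed study
conditions:

- **Demography** (coalescent, msprime): wild Ne = 25 000; domesticated
  lineage splits 9 000 generations ago (annual generations), passes a
  bottleneck (size 1 500 between 6 500 and 8 500 generations ago) and runs
  at Ne = 10 000; subgroups (indica/aus/japonica-like) split 3 000
  generations ago; wild demes split 5 000 generations ago. μ = 3e−8,
  ρ = 1e−8. These values put the domesticated/wild background diversity
  ratio near 0.4 with a further ~4× local reduction inside sweeps, i.e.
  the relative-diversity geometry the analysis is designed to detect.
- **Sweeps**: all domesticated haplotypes are replaced by one founder
  haplotype across a 200-kb window around each domestication locus, then
  receive Poisson post-sweep mutations at rate μ·t_origin·width
  (t_origin = 1 500 generations by default). A focal "domestication SNP"
  fixed alt in the crop is guaranteed at the locus. This reproduces the
  diversity-reduction and rare-allele-excess signatures without a
  forward selection simulation.
- **Admixture pulses**: painted onto recipient haplotypes as a two-state
  Markov mosaic along the genetic map with switch rates (1−α)g out of and
  αg into donor ancestry — the standard exponential-tract approximation,
  which makes truth tracts exact and gives mean donor tract length
  1/((1−α)g) Morgans. Recent pulses overwrite older ones. The map used for
  painting is uniform, ρ·1e8 cM/Mb by default, independently configurable
  (`map_cm_per_mb`) so tract-scale experiments can use dense maps without
  inflating coalescent cost.
- **Selfing**: a diploid is fully inbred (identical haplotype pair) with
  probability s/(2−s), the equilibrium inbreeding coefficient under
  partial selfing; defaults s = 0.99 (crop) and 0.3 (wild) reproduce the
  crop-vs-wild inbreeding asymmetry.
- **Reads**: per-site Poisson depth (mean 5×), per-read error ε = 0.01.
- **Chloroplast**: a separate non-recombining haploid locus from the same
  demography; each seed-mediated pulse independently transmits a random
  donor's chloroplast with probability α down the maternal line;
  pollen-mediated pulses never do. The independence between an
  individual's nuclear mosaic and its maternal-line draw is an
  approximation; it preserves the population-level expectations the
  analyses use.

What the generator does **not** emulate: selection after admixture
(domestication alleles are neutral once introduced), gene conversion,
indels/multi-allelics, mapping artefacts, reference bias, or non-uniform
recombination unless a piecewise map is supplied. Passing tests therefore
demonstrate correctness of the estimators under the model's assumptions,
not robustness to real-data artefacts.

## Problem sizes

The bundled experiments run at desk scale, chosen so the whole suite and
the acceptance script each finish in minutes on one CPU: chromosomes of
0.2–10 Mb, 20–60 accessions, 5–10× depth, ~5 000 thinned markers for
global admixture, and 5–20 seeded replicates for rate-based checks. The
tract-law experiments decouple the painting map (up to 100 cM/Mb) from the
coalescent recombination rate to keep long-map tract statistics cheap.

## Known limitations

- The unphased window classifier fragments heterozygous-ancestry tracts in
  outbred individuals (see above); tract statistics assume high selfing.
- π/θ/D from EM frequencies inherit low-coverage bias at very low depth;
  no SFS-likelihood correction is applied.
- The admixture EM is plain (no quasi-Newton acceleration); hard problems
  should use `fit_replicates` with several seeds.
- The MST network is a summary, not an estimate of the true genealogy;
  reticulate relationships are not represented.
- Permutation p-values have Monte-Carlo resolution 1/(n_perm+1).
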