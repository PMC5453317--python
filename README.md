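# hybridswarm

Detecting and characterizing gene flow from a domesticated crop into its
wild relatives, at low sequencing coverage, with a bundled truth-known
simulator — modelled on the Asian rice (*Oryza sativa* / *O. rufipogon*)
system, where wild populations form a hybrid swarm connected to the crop by
continuous pollen- and seed-mediated gene flow.

## Who this is for

Population geneticists who want to (a) quantify crop-to-wild introgression
from low-coverage resequencing data without calling hard genotypes, and
(b) validate that inference chain end-to-end on synthetic data with known
truth before trusting it on real accessions.

## What it computes

Everything runs on **genotype likelihoods** (GLs). For reads supporting a
biallelic site with error rate ε, the likelihood of genotype *g* ∈ {0,1,2}
(alt-allele count) is

    L(g) = [(2−g)/2·(1−ε) + g/2·ε]^n_ref · [(2−g)/2·ε + g/2·(1−ε)]^n_alt

The analysis chain:

- **gl_core** — allele-frequency EM under HWE, a χ²(1) likelihood-ratio test
  for site variability, one-marker-per-5-kb thinning, and per-individual
  inbreeding coefficients *F* (HWE-with-inbreeding prior).
- **ancestry** — ADMIXTURE-style clustering on GLs:
  `AdmixtureModel(gl, K).fit()` maximizes
  Σᵢₘ log Σ_g GL·C(2,g)·hᵢₘᵍ(1−hᵢₘ)²⁻ᵍ with hᵢₘ = Σₖ QᵢₖFₖₘ by EM,
  returning an `AdmixtureFit` (Q, F, log-likelihood, `summary()`);
  best-of-replicates selection, label alignment, GL-based PCA, window local
  ancestry at domestication loci (*sh4*, *PROG1*), carrier calls at the
  ≥ 95 % cutoff, and 80 %/20 % reference-panel construction.
- **popstats** — per-window π, Watterson's θ, Tajima's D,
  d_XY = p_X q_Y + p_Y q_X, Hudson's F_ST (ratio of averages),
  diversity-reduction ratio scans and most-differentiated-SNP lookup.
- **tracts** — unphased window-likelihood local-ancestry classification
  against reference panels, majority smoothing, tract extraction in cM, and
  tract-length comparisons: older admixture leaves shorter tracts (mean
  ≈ 1/((1−α)·g) Morgans for a pulse of proportion α, g generations ago).
- **cpnet** — chloroplast haplotype collapsing over common SNPs, minimum
  spanning tree networks over Hamming distances, outgroup rooting, and
  wild-with-domesticated-chloroplast sharing counts (seed-mediated gene
  flow moves the maternally inherited chloroplast; pollen does not).
- **geostats** — geographic-vs-genetic distance correlation with
  permutation inference, χ² tests of geographically uniform gene flow,
  domestication-allele co-occurrence, Fisher+Bonferroni label enrichment,
  and carrier-count arithmetic.
- **simswarm** — msprime-backed hybrid-swarm simulator: wild and
  bottlenecked domesticated populations, shared hard sweeps at
  domestication loci, timed admixture pulses painted as Markov ancestry
  mosaics (exact truth tracts), selfing-controlled diploids, Poisson read
  sampling, and maternally inherited chloroplasts.
- **pipeline** / **cli** — a YAML-configured driver
  (`hybridswarm run --config cfg.yaml`) writing VCF/BEAGLE/BED/TSV
  artifacts with a checksummed manifest; reruns are byte-identical.

## Worked example

```python
import numpy as np
import hybridswarm as hs

cfg = hs.ScenarioConfig(
    n_wild=36, n_dom_per_group={"indica": 24}, L=10_000_000, seed=11,
    sweep_loci=(), sweep_names=(),
    selfing_rate_wild=0.0, selfing_rate_dom=0.0,
    pulses=[hs.Pulse("indica", "wild", alpha=0.5, g=10)])
swarm = hs.simulate_swarm(cfg)

counts = hs.emit_reads(swarm.haplotypes, 5.0, 0.01, seed=7)
gl = hs.GLMatrix.from_read_counts(counts, 0.01, swarm.individuals,
                                  swarm.sites())
gl = gl.subset_sites(hs.call_variable_sites(gl))
gl = gl.subset_sites(hs.thin_markers(gl.sites, 2000, seed=1))

fit = hs.fit_admixture(gl, K=2, seed=0)
print(fit.summary())

dom_k = fit.Q[~swarm.is_wild].mean(axis=0).argmax()
truth = swarm.truth.dosage.mean(axis=1)
truth[~swarm.is_wild] = 1.0
print("mean |Q - truth dosage|:",
      round(float(np.abs(fit.Q[:, dom_k] - truth).mean()), 4))
```

prints

```
Genotype-likelihood admixture fit
================================================
K (clusters)        : 2
individuals         : 60
sites               : 5000
log-likelihood      : -111825.8688
EM iterations       : 144 (converged)
seed                : 0

mean ancestry proportion per cluster:
  cluster 0: 0.6864
  cluster 1: 0.3136
mean |Q - truth dosage|: 0.0172
```

i.e. on a 60-accession swarm where every wild genome is on average half
*indica* (a pulse of α = 0.5 ten generations back), sequencing at 5×, the
GL admixture model recovers each individual's true domesticated-ancestry
dosage to within 0.02 on average.

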