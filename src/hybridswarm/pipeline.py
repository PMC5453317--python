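"""End-to-end pipeline driver: simulation -> GLs -> admixture -> carriers ->
window statistics -> tracts -> chloroplast network -> geographic summary.

Stages run in dependency order; each artifact is recorded in a manifest
(parameters, seeds, sha256 checksums), and a rerun with the same config is
byte-identical.  A requested stage whose dependency was not run fails with
an error naming the missing stage.
"""

from __future__ import annotations

import json
import logging

import numpy as np
import pandas as pd

from hybridswarm import ancestry, cpnet, geostats, popstats, tracts
from hybridswarm import io as hio
from hybridswarm.config import ALL_STAGES, PipelineConfig
from hybridswarm.gl_core import (GLMatrix, call_variable_sites,
                                 estimate_allele_freqs, thin_markers)
from hybridswarm.simswarm import WILD_LABEL, emit_reads, simulate_swarm

log = logging.getLogger("hybridswarm.pipeline")

_DEPS = {
    "simulate": [],
    "gl": ["simulate"],
    "admixture": ["gl"],
    "carriers": ["gl", "admixture"],
    "popstats": ["gl"],
    "tracts": ["gl", "admixture", "carriers"],
    "cpnet": ["simulate"],
    "geostats": ["carriers"],
}


def _dom_clusters(fit, is_wild: np.ndarray) -> np.ndarray:
    """Cluster indices whose Q mass is carried mostly by domesticated samples."""
    dom_mass = fit.Q[~is_wild].sum(axis=0)
    wild_mass = fit.Q[is_wild].sum(axis=0)
    return np.flatnonzero(dom_mass > wild_mass)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the enabled stages; returns a report dict (also written to
    ``manifest.json`` with per-artifact checksums)."""
    out = cfg.outdir
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}
    ctx: dict = {}
    report: dict = {"stages": []}

    def record(name, path, stage):
        artifacts[name] = {"path": str(path), "stage": stage,
                           "sha256": hio.sha256_of(path)}

    for stage in [s for s in ALL_STAGES if s in cfg.stages]:
        missing = [d for d in _DEPS[stage] if d not in report["stages"]]
        if missing:
            raise RuntimeError(
                f"stage '{stage}' requires stage(s) {missing} to run first")
        log.info("stage %s starting", stage)

        if stage == "simulate":
            swarm = simulate_swarm(cfg.scenario_config())
            ctx["swarm"] = swarm
            hio.write_vcf(out / "swarm.vcf", swarm.individuals, swarm.sites(),
                          swarm.haplotypes, contig_length=swarm.config.L)
            truth_bed = swarm.truth.tracts.rename(columns={})
            hio.write_tract_bed(out / "truth_tracts.bed", truth_bed)
            hio.write_genetic_map(out / "genetic_map.tsv", swarm.genetic_map)
            hio.write_metadata(out / "metadata.tsv", swarm.metadata())
            hio.write_chloroplast(out / "chloroplast.tsv", swarm.individuals,
                                  swarm.cp_haplotypes, swarm.truth.cp_donor)
            for name in ("swarm.vcf", "truth_tracts.bed", "genetic_map.tsv",
                         "metadata.tsv", "chloroplast.tsv"):
                record(name, out / name, stage)

        elif stage == "gl":
            swarm = ctx["swarm"]
            counts = emit_reads(swarm.haplotypes, swarm.config.depth_mean,
                                swarm.config.error_rate, cfg.seeds["reads"])
            gl = GLMatrix.from_read_counts(counts, swarm.config.error_rate,
                                           swarm.individuals, swarm.sites())
            freqs = estimate_allele_freqs(gl)
            variable = call_variable_sites(gl, cfg.alpha_lrt, freqs)
            gl_var = gl.subset_sites(variable)
            thin_idx = thin_markers(gl_var.sites, cfg.thin_bp, cfg.seeds["thin"])
            ctx.update(gl=gl, freqs=freqs, gl_var=gl_var,
                       gl_thin=gl_var.subset_sites(thin_idx))
            hio.write_beagle_gl(out / "markers.beagle", ctx["gl_thin"])
            record("markers.beagle", out / "markers.beagle", stage)

        elif stage == "admixture":
            fit = ancestry.best_of_replicates(ctx["gl_thin"], cfg.k_global,
                                              cfg.n_reps,
                                              base_seed=cfg.seeds["admixture"])
            ctx["fit"] = fit
            np.savetxt(out / "admixture.Q", fit.Q, fmt="%.6f")
            np.savetxt(out / "admixture.P", fit.F.T, fmt="%.6f")
            record("admixture.Q", out / "admixture.Q", stage)
            record("admixture.P", out / "admixture.P", stage)
            report["admixture_loglik"] = fit.loglik

        elif stage == "carriers":
            swarm, gl, fit = ctx["swarm"], ctx["gl"], ctx["fit"]
            is_wild = swarm.is_wild
            dom_k = _dom_clusters(fit, is_wild)
            global_dom = fit.Q[:, dom_k].sum(axis=1)
            ctx["global_dom"] = global_dom
            panel = {}
            for i, ind in enumerate(swarm.individuals):
                if not is_wild[i]:
                    panel[ind] = "dom"
                elif global_dom[i] <= 1.0 - ancestry.PANEL_REFERENCE_CUTOFF:
                    panel[ind] = "wild"
            ctx["panel"] = panel
            calls = []
            for name, (locus, _t) in zip(swarm.config.sweep_names,
                                         swarm.config.sweep_loci):
                lo = max(0, locus - cfg.locus_window // 2)
                hi = min(swarm.config.L, locus + cfg.locus_window // 2)
                region = (gl.sites["pos"] >= lo) & (gl.sites["pos"] < hi)
                frac = ancestry.window_ancestry(
                    gl.subset_sites(region.to_numpy()), cfg.k_window, panel,
                    seed=cfg.seeds["window"], min_sites=cfg.min_sites_window)
                calls += ancestry.classify_carriers(
                    frac[is_wild], name, cfg.carrier_cutoff)
            ctx["carrier_calls"] = calls
            df = pd.DataFrame([(c.individual, c.locus, round(c.fraction, 6),
                                int(c.carrier)) for c in calls],
                              columns=["individual", "locus", "fraction",
                                       "carrier"])
            df.to_csv(out / "carriers.tsv", sep="\t", index=False)
            record("carriers.tsv", out / "carriers.tsv", stage)

        elif stage == "popstats":
            swarm, freqs = ctx["swarm"], ctx["freqs"]
            is_wild = swarm.is_wild
            gl = ctx["gl"]
            fw = estimate_allele_freqs(gl.subset_individuals(is_wild))
            fd = estimate_allele_freqs(gl.subset_individuals(~is_wild))
            pos = gl.sites["pos"].to_numpy()
            stats_df = popstats.compute_window_stats(
                fd["freq"].to_numpy(), 2 * int((~is_wild).sum()),
                fw["freq"].to_numpy(), 2 * int(is_wild.sum()),
                pos, swarm.config.L, window_size=cfg.stats_window)
            scan = popstats.diversity_ratio_scan(
                stats_df["pi_x"].to_numpy(), stats_df["pi_y"].to_numpy(),
                stats_df[["start", "end", "partial"]])
            ctx["window_stats"] = stats_df
            ctx["ratio_scan"] = scan
            stats_df.round(8).to_csv(out / "window_stats.tsv", sep="\t",
                                     index=False)
            scan.ranking.round(8).to_csv(out / "diversity_ranking.tsv",
                                         sep="\t", index=False)
            record("window_stats.tsv", out / "window_stats.tsv", stage)
            record("diversity_ranking.tsv", out / "diversity_ranking.tsv", stage)

        elif stage == "tracts":
            swarm, gl = ctx["swarm"], ctx["gl"]
            panel, global_dom = ctx["panel"], ctx["global_dom"]
            groups = list(swarm.config.n_dom_per_group)
            panel_freqs = {}
            wild_ref = [i for i, ind in enumerate(swarm.individuals)
                        if panel.get(ind) == "wild"]
            panel_freqs[WILD_LABEL] = estimate_allele_freqs(
                gl.subset_individuals(wild_ref))["freq"].to_numpy()
            for g in groups:
                rows = np.flatnonzero(swarm.group == g)
                panel_freqs[g] = estimate_allele_freqs(
                    gl.subset_individuals(rows))["freq"].to_numpy()
            targets = [ind for i, ind in enumerate(swarm.individuals)
                       if swarm.is_wild[i] and global_dom[i] >= cfg.admixed_cutoff]
            tr = tracts.infer_tracts(gl, panel_freqs, swarm.genetic_map,
                                     individuals=targets,
                                     window_size=cfg.tract_window,
                                     min_sites=cfg.min_sites_window)
            summ = tracts.tract_length_summary(tr, groups)
            ctx["tracts"] = tr
            hio.write_tract_bed(out / "tracts.bed", tr)
            summ.table.round(6).to_csv(out / "tract_summary.tsv", sep="\t",
                                       index=False)
            record("tracts.bed", out / "tracts.bed", stage)
            record("tract_summary.tsv", out / "tract_summary.tsv", stage)

        elif stage == "cpnet":
            swarm = ctx["swarm"]
            net = cpnet.define_haplotypes(swarm.cp_haplotypes,
                                          swarm.individuals,
                                          min_hap_count=1)
            cpnet.build_network(net)
            sample_class = {ind: ("wild" if w else "domesticated")
                            for ind, w in zip(swarm.individuals, swarm.is_wild)}
            sharing = cpnet.count_domesticated_sharing(net, sample_class)
            ctx["cp_sharing"] = sharing
            haps, edges = cpnet.network_tables(net)
            haps.to_csv(out / "cp_haplotypes.tsv", sep="\t", index=False)
            edges.to_csv(out / "cp_edges.tsv", sep="\t", index=False)
            record("cp_haplotypes.tsv", out / "cp_haplotypes.tsv", stage)
            record("cp_edges.tsv", out / "cp_edges.tsv", stage)
            report["cp_sharing_fraction"] = sharing["fraction"]

        elif stage == "geostats":
            swarm = ctx["swarm"]
            calls = ctx["carrier_calls"]
            carriers = {}
            for c in calls:
                carriers.setdefault(c.individual, set())
                if c.carrier:
                    carriers[c.individual].add(c.locus)
            wild_idx = np.flatnonzero(swarm.is_wild)
            regions = sorted(set(swarm.group[wild_idx]))
            rows = []
            names = list(swarm.config.sweep_names)
            for r in regions:
                members = [swarm.individuals[i] for i in wild_idx
                           if swarm.group[i] == r]
                n_a = sum(names[0] in carriers.get(m, ()) for m in members)
                if len(names) > 1:
                    n_b = sum(names[1] in carriers.get(m, ()) for m in members)
                    n_both = sum({names[0], names[1]} <= carriers.get(m, set())
                                 for m in members)
                else:
                    n_b = n_both = 0
                rows.append((r, len(members), n_a, n_b, n_both))
            summary = geostats.region_summary(
                [r[0] for r in rows], [r[1] for r in rows],
                [r[2] for r in rows], [r[3] for r in rows],
                [r[4] for r in rows])
            summary.to_csv(out / "region_summary.tsv", sep="\t", index=False)
            record("region_summary.tsv", out / "region_summary.tsv", stage)
            if (summary["n"] >= cfg.min_region_n).sum() >= 2:
                report["uniform_geography"] = geostats.uniform_geography_test(
                    summary, min_region_n=cfg.min_region_n)

        report["stages"].append(stage)
        log.info("stage %s done", stage)

    manifest = {"config": cfg.to_dict(), "artifacts": artifacts,
                "stages": report["stages"]}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    report["manifest"] = manifest
    report["context"] = ctx
    return report
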