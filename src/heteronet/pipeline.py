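"""End-to-end pipeline driver: simulate -> filter -> score -> enrichment suite.

``run_pipeline`` executes every stage of the integrated analysis on a
synthetic dataset with planted ground truth, writes all artifacts as TSV/GMT
and records a YAML manifest (parameters, seeds, diagnostics and artifact
hashes). Given an identical configuration the run is bit-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path

from . import __version__, enrichment, io, profiles, scoring, synthetic
from .synthetic import GENOTYPES, HYBRIDS

logger = logging.getLogger(__name__)

MEASURES = ("mph", "bph")

#: Study-condition defaults: a 2000-gene genome, 1000 analyzed genes with 100
#: planted heterosis genes (3 extra hybrid edges each), 30 samples/genotype,
#: and 90 narrow QTL regions capturing ~80% of the planted genes.
DEFAULTS: dict = {
    "n_genes": 2000,
    "chrom_lengths_cM": list(synthetic.DEFAULT_CHROM_LENGTHS_CM),
    "duplicated_fraction": 0.25,
    "n_analyzed": 1000,
    "base_edges_per_gene": 1.0,
    "extra_hybrid_edges": 3,
    "n_heterosis_genes": 100,
    "n_timepoints": 5,
    "n_replicates": 6,
    "time_effect_sd": 0.3,
    "flat_gene_fraction": 0.1,
    "n_qtl_regions": 90,
    "capture_fraction": 0.8,
    "region_width_cM": 1.0,
    "n_pathways": 80,
    "pathway_size_range": [10, 1000],
    "enrichment_odds": 10.0,
    "alpha": 0.3,
    "step": 100,
    "resample_B": 1000,
    "resample_ns": [100, 200, 300, 400, 500],
    "top_n": 300,
    "fdr_threshold": 0.05,
    "bin_width_cM": 2.0,
}

REQUIRED_KEYS = ("seed", "outdir")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and the cause."""


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def validate_config(config: dict) -> dict:
    for key in REQUIRED_KEYS:
        if key not in config:
            raise ValueError(f"config missing required key: {key!r}")
    unknown = set(config) - set(DEFAULTS) - set(REQUIRED_KEYS)
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    merged = dict(DEFAULTS)
    merged.update(config)
    return merged


def run_pipeline(config: dict | str | Path, log_level: str | None = None) -> dict:
    """Run every stage and return the manifest (also written to the outdir)."""
    if log_level:
        logging.basicConfig(level=getattr(logging, log_level.upper()))
    if not isinstance(config, dict):
        config = io.load_config(config)
    cfg = validate_config(config)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    artifacts: dict[str, str] = {}
    diagnostics: dict = {}

    def save(name: str, writer, obj) -> Path:
        path = outdir / name
        writer(obj, path)
        artifacts[name] = io.sha256_of(path)
        return path

    # -- simulate -----------------------------------------------------------
    @_stage("simulate")
    def simulate():
        catalog = synthetic.generate_gene_catalog(
            n_genes=cfg["n_genes"],
            chrom_lengths_cM=tuple(cfg["chrom_lengths_cM"]),
            duplicated_fraction=cfg["duplicated_fraction"],
            seed=seed,
        )
        ensemble = synthetic.plant_networks(
            catalog,
            n_analyzed=cfg["n_analyzed"],
            base_edges_per_gene=cfg["base_edges_per_gene"],
            extra_hybrid_edges=cfg["extra_hybrid_edges"],
            n_heterosis_genes=cfg["n_heterosis_genes"],
            seed=seed + 1,
        )
        panels = synthetic.simulate_expression(
            ensemble,
            n_timepoints=cfg["n_timepoints"],
            n_replicates=cfg["n_replicates"],
            seed=seed + 2,
            time_effect_sd=cfg["time_effect_sd"],
            flat_gene_fraction=cfg["flat_gene_fraction"],
        )
        qtl = synthetic.define_qtl_regions(
            catalog,
            ensemble.heterosis_genes,
            n_regions=cfg["n_qtl_regions"],
            capture_fraction=cfg["capture_fraction"],
            region_width_cM=cfg["region_width_cM"],
            seed=seed + 3,
        )
        pathways = synthetic.assign_pathways(
            catalog,
            ensemble.gene_ids,
            n_pathways=cfg["n_pathways"],
            size_range=tuple(cfg["pathway_size_range"]),
            planted_set=ensemble.heterosis_genes,
            seed=seed + 4,
            enrichment_odds=cfg["enrichment_odds"],
        )
        save("catalog.tsv", io.write_catalog, catalog)
        for g in GENOTYPES:
            save(f"expression_{g}.tsv", io.write_panel, panels[g])
        save("qtl_regions.tsv", io.write_qtl_regions, qtl)
        save("qtl_test_set.txt", io.write_gene_list, qtl.test_set)
        save("pathways.gmt", io.write_gmt, pathways)
        save("heterosis_genes.txt", io.write_gene_list, ensemble.heterosis_genes)
        return catalog, ensemble, panels, qtl, pathways

    catalog, ensemble, panels, qtl, pathways = simulate()

    # -- filter + score -----------------------------------------------------
    @_stage("filter")
    def anova_filter():
        retained = scoring.filter_genes_anova(panels, alpha=cfg["alpha"])
        save("anova_retained.txt", io.write_gene_list, retained)
        return retained

    retained = anova_filter()
    diagnostics["n_retained"] = len(retained)

    @_stage("score")
    def score():
        result = scoring.score_panels(panels, genes=retained)
        save("h_table.tsv", io.write_table, result.h_table)
        save("scores.tsv", io.write_table, result.scores)
        for hyb in HYBRIDS:
            for meas in MEASURES:
                save(f"ranking_{meas}_{hyb}.txt", io.write_gene_list,
                     result.ranking(hyb, meas))
        return result

    scored = score()
    diagnostics["scoring"] = {
        g: {
            "shrinkage_lambda": float(scored.pcor_results[g].shrinkage_lambda),
            "kappa": float(scored.pcor_results[g].kappa),
        }
        for g in GENOTYPES
    }
    diagnostics["n_scored"] = len(scored.gene_ids)
    diagnostics["n_zero_variance_dropped"] = len(scored.dropped_genes)

    reference = set(catalog.gene_ids)
    analyzed_ref = set(scored.gene_ids)
    test_set = set(qtl.test_set)
    rankings = {
        (hyb, meas): scored.ranking(hyb, meas)
        for hyb in HYBRIDS for meas in MEASURES
    }

    # -- ORA sweeps ---------------------------------------------------------
    from .ora import sweep_ora

    @_stage("ora-sweep")
    def sweeps():
        out = {}
        for (hyb, meas), ranked in rankings.items():
            sweep = sweep_ora(reference, test_set, ranked, step=cfg["step"],
                              provenance={"hybrid": hyb, "measure": meas})
            save(f"sweep_{meas}_{hyb}.tsv", io.write_sweep, sweep)
            out[(hyb, meas)] = sweep
        return out

    sweep_results = sweeps()

    # -- resampling ---------------------------------------------------------
    @_stage("resample")
    def resample():
        import pandas as pd

        ranked = rankings[("H12", "mph")]
        rows = []
        for i, n in enumerate(cfg["resample_ns"]):
            n = min(int(n), len(ranked))
            res = enrichment.empirical_pvalue(
                reference, test_set, ranked, n=n,
                B=cfg["resample_B"], seed=seed + 5 + i,
            )
            rows.append({"n": res.n, "k_orig": res.k_orig, "B": res.B,
                         "count_ge": res.count_ge, "p_emp": res.p_emp})
        frame = pd.DataFrame(rows)
        save("resampling_mph_H12.tsv",
             lambda obj, path: obj.to_csv(path, sep="\t", index=False), frame)
        return frame

    resampling = resample()

    # -- chromosome-wise sweeps ----------------------------------------------
    @_stage("ora-chrom")
    def chrom():
        ranked = rankings[("H12", "mph")]
        sweeps_by_chrom = enrichment.chromosome_sweep(
            reference, test_set, ranked, catalog, step=cfg["step"])
        for c, sweep in sweeps_by_chrom.items():
            save(f"sweep_chrom{c}_mph_H12.tsv", io.write_sweep, sweep)
        return sweeps_by_chrom

    chrom_sweeps = chrom()

    # -- duplicated-gene annotation ORA ---------------------------------------
    @_stage("annotation-ora")
    def annotation():
        dup = set(catalog.duplicated_genes())
        ranked = rankings[("H12", "mph")]
        n = min(cfg["top_n"], len(ranked))
        return enrichment.annotation_ora(ranked, n, dup, reference)

    dup_ora = annotation()
    diagnostics["duplicated_gene_ora"] = {
        "k": dup_ora.k, "k_expected": dup_ora.k_expected, "p_value": dup_ora.p_value,
    }

    # -- candidate group + pathway ORA ---------------------------------------
    @_stage("ora-pathway")
    def pathway():
        ranked = rankings[("H12", "mph")]
        top_n = min(cfg["top_n"], len(ranked))
        candidate = enrichment.candidate_overlap(ranked, qtl.test_set, top_n=top_n)
        candidate = [g for g in candidate if g in analyzed_ref]
        save("candidate_group.txt", io.write_gene_list, candidate)
        results = enrichment.pathway_ora(
            analyzed_ref, candidate, pathways,
            fdr_threshold=cfg["fdr_threshold"],
            size_range=tuple(cfg["pathway_size_range"]),
        )
        table = enrichment.pathway_table(results)
        save("pathway_ora.tsv",
             lambda obj, path: obj.to_csv(path, sep="\t", index=False, na_rep="NA"),
             table)
        return candidate, results

    candidate, pathway_results = pathway()
    diagnostics["n_candidate"] = len(candidate)

    # -- frequency profile ----------------------------------------------------
    @_stage("profile")
    def profile():
        ranked = rankings[("H12", "mph")]
        top = set(ranked[: min(cfg["top_n"], len(ranked))])
        prof = profiles.relative_frequency_profile(
            top, catalog, bin_width_cM=cfg["bin_width_cM"], qtl=qtl)
        save("frequency_profile.tsv",
             lambda obj, path: obj.table.to_csv(path, sep="\t", index=False,
                                                na_rep="NA"),
             prof)
        return prof

    prof = profile()
    diagnostics["profile_medians"] = {int(c): m for c, m in prof.medians.items()}

    manifest = {
        "package": "heteronet",
        "version": __version__,
        "config": {k: cfg[k] for k in sorted(cfg)},
        "artifacts": artifacts,
        "diagnostics": diagnostics,
        "ground_truth": {
            "heterosis_genes": list(ensemble.heterosis_genes),
            "planted_pathway": pathways.planted_enriched,
            "n_qtl_test_set": len(qtl.test_set),
        },
    }
    io.write_manifest(manifest, outdir / "manifest.yaml")
    logger.info("pipeline complete; %d artifacts under %s", len(artifacts), outdir)
    return manifest
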