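"""Simulate the study dataset: genome, planted networks, expression, QTL, pathways.

Generates a 2000-gene genome on 5 chromosomes, four genotype-specific Gaussian
graphical models in which 100 of 1000 analyzed genes carry 3 extra regulatory
edges in each hybrid, 30 expression samples per genotype (5 time points x 6
replicates), 90 QTL candidate regions anchored so ~80% of the planted genes
fall inside, and 80 pathways of which one is enriched for the planted genes.

Writes all inputs plus the ground truth under results/data/.
"""

from pathlib import Path

from heteronet import io, synthetic

SEED = 11
OUT = Path("results/data")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    catalog = synthetic.generate_gene_catalog(2000, seed=SEED)
    ensemble = synthetic.plant_networks(
        catalog, n_analyzed=1000, base_edges_per_gene=1.0,
        extra_hybrid_edges=3, n_heterosis_genes=100, seed=SEED + 1)
    panels = synthetic.simulate_expression(
        ensemble, n_timepoints=5, n_replicates=6, seed=SEED + 2)
    qtl = synthetic.define_qtl_regions(
        catalog, ensemble.heterosis_genes, n_regions=90,
        capture_fraction=0.8, region_width_cM=1.0, seed=SEED + 3)
    pathways = synthetic.assign_pathways(
        catalog, ensemble.gene_ids, n_pathways=80, size_range=(10, 1000),
        planted_set=ensemble.heterosis_genes, seed=SEED + 4,
        enrichment_odds=10.0)

    io.write_catalog(catalog, OUT / "catalog.tsv")
    for g, panel in panels.items():
        io.write_panel(panel, OUT / f"expression_{g}.tsv")
    io.write_qtl_regions(qtl, OUT / "qtl_regions.tsv")
    io.write_gene_list(qtl.test_set, OUT / "qtl_test_set.txt")
    io.write_gmt(pathways, OUT / "pathways.gmt")
    io.write_gene_list(ensemble.heterosis_genes, OUT / "heterosis_genes.txt")
    io.write_manifest(
        {"seed": SEED, "planted_pathway": pathways.planted_enriched},
        OUT / "manifest.yaml")

    captured = set(ensemble.heterosis_genes) & set(qtl.test_set)
    print(f"catalog: {catalog.n_genes} genes on {len(catalog.chrom_lengths_cM)} chromosomes")
    print(f"analyzed: {len(ensemble.gene_ids)} genes, planted heterosis genes: "
          f"{len(ensemble.heterosis_genes)}")
    print(f"expression: {panels['P1'].n_samples} samples per genotype")
    print(f"QTL test set: {len(qtl.test_set)} genes in {len(qtl.regions)} regions; "
          f"{len(captured)}/{len(ensemble.heterosis_genes)} planted genes captured")
    print(f"pathways: {len(pathways.sets)}, planted-enriched: {pathways.planted_enriched}")
    print(f"-> {OUT}/")


if __name__ == "__main__":
    main()
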