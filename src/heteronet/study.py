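"""Canonical simulation scenario: the study conditions used throughout.

One function bundles the full chain — catalog, planted networks, expression,
ANOVA filter, scoring, QTL regions, pathways — at the scale the package's
analyses and validation runs use: a 2000-gene genome, 1000 analyzed genes of
which 100 are planted heterosis genes with 3 extra hybrid edges each, 30
expression samples per genotype (5 time points x 6 replicates), and QTL
candidate regions anchored on planted genes so that ~80% of them fall inside.
All randomness derives from one seed.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import scoring, synthetic


@dataclass
class StudyResult:
    """All artifacts of one simulated study."""

    seed: int
    catalog: synthetic.GeneCatalog
    ensemble: synthetic.NetworkEnsemble
    panels: dict[str, synthetic.ExpressionPanel]
    retained: list[str]
    scored: scoring.ScoringResult
    qtl: synthetic.QTLRegionSet
    pathways: synthetic.GeneSetCollection | None = None

    def ranking(self, hybrid: str = "H12", measure: str = "mph") -> list[str]:
        return self.scored.ranking(hybrid, measure)

    @property
    def reference(self) -> set[str]:
        return set(self.catalog.gene_ids)

    @property
    def test_set(self) -> set[str]:
        return set(self.qtl.test_set)


def simulate_study(
    seed: int,
    *,
    n_genes: int = 2000,
    n_analyzed: int = 1000,
    n_heterosis_genes: int = 100,
    base_edges_per_gene: float = 1.0,
    extra_hybrid_edges: int = 3,
    n_timepoints: int = 5,
    n_replicates: int = 6,
    time_effect_sd: float = 0.3,
    flat_gene_fraction: float = 0.1,
    alpha: float = 0.3,
    n_qtl_regions: int = 90,
    capture_fraction: float = 0.8,
    region_width_cM: float = 1.0,
    restrict_chromosome: int | None = None,
    with_pathways: bool = False,
    n_pathways: int = 80,
    pathway_size_range: tuple[int, int] = (10, 1000),
    enrichment_odds: float = 10.0,
    apply_filter: bool = True,
) -> StudyResult:
    """Simulate and score one study under the canonical conditions.

    ``restrict_chromosome`` confines the planted heterosis genes to one
    chromosome (the chromosome-stratification scenario).
    """
    catalog = synthetic.generate_gene_catalog(n_genes, seed=seed)
    pool = None
    if restrict_chromosome is not None:
        pool = [
            g for g, c in zip(catalog.gene_ids, catalog.table["chromosome"])
            if c == restrict_chromosome
        ]
    ensemble = synthetic.plant_networks(
        catalog,
        n_analyzed=n_analyzed,
        base_edges_per_gene=base_edges_per_gene,
        extra_hybrid_edges=extra_hybrid_edges,
        n_heterosis_genes=n_heterosis_genes,
        seed=seed + 1,
        heterosis_pool=pool,
    )
    panels = synthetic.simulate_expression(
        ensemble,
        n_timepoints=n_timepoints,
        n_replicates=n_replicates,
        seed=seed + 2,
        time_effect_sd=time_effect_sd,
        flat_gene_fraction=flat_gene_fraction,
    )
    retained = (scoring.filter_genes_anova(panels, alpha=alpha)
                if apply_filter else list(ensemble.gene_ids))
    scored = scoring.score_panels(panels, genes=retained)
    qtl = synthetic.define_qtl_regions(
        catalog,
        ensemble.heterosis_genes,
        n_regions=n_qtl_regions,
        capture_fraction=capture_fraction,
        region_width_cM=region_width_cM,
        seed=seed + 3,
    )
    pathways = None
    if with_pathways:
        pathways = synthetic.assign_pathways(
            catalog,
            ensemble.gene_ids,
            n_pathways=n_pathways,
            size_range=pathway_size_range,
            planted_set=ensemble.heterosis_genes,
            seed=seed + 4,
            enrichment_odds=enrichment_odds,
        )
    return StudyResult(
        seed=seed,
        catalog=catalog,
        ensemble=ensemble,
        panels=panels,
        retained=retained,
        scored=scored,
        qtl=qtl,
        pathways=pathways,
    )
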