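"""Shared fixtures: small catalogs, ensembles and scored datasets.

Heavy simulations (the 20-seed planted studies used by the recovery and
stratification checks) are session-scoped so every test reads the same runs.
"""

from __future__ import annotations

import numpy as np
import pytest

from heteronet import scoring, synthetic
from heteronet.study import simulate_study


@pytest.fixture(scope="session")
def catalog_small() -> synthetic.GeneCatalog:
    return synthetic.generate_gene_catalog(300, seed=11)


@pytest.fixture(scope="session")
def scored_small():
    """A small planted study (120 analyzed genes) with full scoring."""
    study = simulate_study(
        7000,
        n_genes=400,
        n_analyzed=120,
        n_heterosis_genes=15,
        n_qtl_regions=12,
        apply_filter=False,
    )
    return study


@pytest.fixture(scope="session")
def planted_studies():
    """20 planted studies at the canonical conditions (1000 analyzed genes,
    100 planted heterosis genes with 3 extra hybrid edges, 30 samples per
    genotype, QTL regions capturing ~80% of the planted genes)."""
    return [simulate_study(1000 * (i + 1)) for i in range(20)]


@pytest.fixture(scope="session")
def chrom2_studies():
    """20 planted studies with every heterosis gene on chromosome 2."""
    return [
        simulate_study(
            500_000 + 1000 * (i + 1),
            restrict_chromosome=2,
            n_qtl_regions=50,
        )
        for i in range(20)
    ]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20121116)
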