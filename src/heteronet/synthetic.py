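"""Synthetic genomes, genotype-specific networks, expression panels, QTL regions and pathways.

The generator emulates the data layout of a heterosis network study on two
homozygous parents and their two reciprocal F1 hybrids: a gene catalog on five
chromosomes with Kosambi-cM positions, genotype-specific Gaussian graphical
models in which a designated subset of "heterosis genes" carries extra edges in
the hybrid networks, expression panels sampled from those models, QTL candidate
regions that capture a configurable fraction of the planted genes, and pathway
collections (GMT-style gene sets) with one optionally planted-enriched pathway.

Every generator is a pure function of its arguments including ``seed``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Genotype labels: two homozygous parents and the two reciprocal hybrids.
GENOTYPES: tuple[str, ...] = ("P1", "P2", "H12", "H21")
PARENTS: tuple[str, ...] = ("P1", "P2")
HYBRIDS: tuple[str, ...] = ("H12", "H21")

#: Arabidopsis-like genetic map lengths (Kosambi cM) for a 5-chromosome genome.
DEFAULT_CHROM_LENGTHS_CM: tuple[float, ...] = (130.0, 75.0, 90.0, 80.0, 110.0)


# ---------------------------------------------------------------------------
# gene catalog
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneCatalog:
    """Genome coordinates and annotations per gene.

    ``table`` has columns ``gene_id`` (unique, AGI-like), ``chromosome``
    (1..C), ``position_cM`` (within the chromosome length) and
    ``is_duplicated`` (annotation flag for duplicated genes).
    """

    table: pd.DataFrame
    chrom_lengths_cM: tuple[float, ...]

    def __post_init__(self) -> None:
        required = ["gene_id", "chromosome", "position_cM", "is_duplicated"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"catalog table missing columns: {missing}")
        ids = self.table["gene_id"]
        if ids.duplicated().any():
            raise ValueError("gene_ids must be unique")
        chrom = self.table["chromosome"].to_numpy()
        if chrom.min() < 1 or chrom.max() > len(self.chrom_lengths_cM):
            raise ValueError("chromosome index outside configured genome")
        lengths = np.asarray(self.chrom_lengths_cM)[chrom - 1]
        pos = self.table["position_cM"].to_numpy()
        if (pos < 0).any() or (pos > lengths).any():
            raise ValueError("position_cM outside chromosome bounds")

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(self.table["gene_id"])

    @property
    def n_genes(self) -> int:
        return len(self.table)

    def positions(self) -> pd.Series:
        return self.table.set_index("gene_id")["position_cM"]

    def chromosome_of(self) -> pd.Series:
        return self.table.set_index("gene_id")["chromosome"]

    def duplicated_genes(self) -> tuple[str, ...]:
        mask = self.table["is_duplicated"].astype(bool)
        return tuple(self.table.loc[mask, "gene_id"])


def _gene_id(i: int) -> str:
    # zero-padded so lexicographic order == generation order
    return f"ATSG{i:05d}"


def generate_gene_catalog(
    n_genes: int,
    chrom_lengths_cM: tuple[float, ...] | list[float] = DEFAULT_CHROM_LENGTHS_CM,
    duplicated_fraction: float = 0.25,
    seed: int = 0,
) -> GeneCatalog:
    """Generate a gene catalog with genes spread proportionally to map length.

    Positions are uniform on each chromosome; ``is_duplicated`` flags are
    Bernoulli(``duplicated_fraction``). Deterministic given ``seed``.
    """
    lengths = np.asarray(chrom_lengths_cM, dtype=float)
    if lengths.ndim != 1 or len(lengths) == 0 or (lengths <= 0).any():
        raise ValueError("chrom_lengths_cM must be positive reals")
    if n_genes < len(lengths):
        raise ValueError(f"n_genes={n_genes} must be >= number of chromosomes ({len(lengths)})")
    if not 0.0 <= duplicated_fraction <= 1.0:
        raise ValueError("duplicated_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    chrom = rng.choice(len(lengths), size=n_genes, p=lengths / lengths.sum()) + 1
    pos = rng.uniform(0.0, lengths[chrom - 1])
    dup = rng.random(n_genes) < duplicated_fraction
    table = pd.DataFrame(
        {
            "gene_id": [_gene_id(i) for i in range(n_genes)],
            "chromosome": chrom.astype(int),
            "position_cM": pos,
            "is_duplicated": dup,
        }
    )
    return GeneCatalog(table=table, chrom_lengths_cM=tuple(lengths))


# ---------------------------------------------------------------------------
# genotype-specific networks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NetworkEnsemble:
    """Ground-truth Gaussian graphical models for the four genotypes.

    ``precisions`` maps genotype to a symmetric positive definite precision
    matrix over ``gene_ids`` (catalog order). ``heterosis_genes`` are planted
    with extra edges in both hybrids; outside those genes the hybrid networks
    equal the shared parental network.
    """

    gene_ids: tuple[str, ...]
    precisions: dict[str, np.ndarray]
    heterosis_genes: tuple[str, ...]

    def adjacency(self, genotype: str) -> np.ndarray:
        p = self.precisions[genotype]
        adj = p != 0.0
        np.fill_diagonal(adj, False)
        return adj

    def degrees(self, genotype: str) -> pd.Series:
        return pd.Series(
            self.adjacency(genotype).sum(axis=1), index=list(self.gene_ids)
        )

    def true_partial_correlations(self, genotype: str) -> np.ndarray:
        omega = self.precisions[genotype]
        d = np.sqrt(np.diag(omega))
        pcor = -omega / np.outer(d, d)
        np.fill_diagonal(pcor, 1.0)
        return pcor


#: Target partial-correlation magnitudes of background (parental) edges.
BASE_PCOR_RANGE: tuple[float, float] = (0.05, 0.15)
#: Per-gene positive-definiteness budget: sum of squared partial correlations
#: incident to a gene stays below THETA^2 (the star-graph PD frontier is 1).
THETA: float = 0.95
#: Required smallest eigenvalue of every precision matrix.
EIG_MARGIN: float = 0.05


def _sample_pairs(n: int, m: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    iu, ju = np.triu_indices(n, k=1)
    pick = rng.choice(len(iu), size=m, replace=False)
    return iu[pick], ju[pick]


def plant_networks(
    catalog: GeneCatalog,
    n_analyzed: int,
    base_edges_per_gene: float = 1.0,
    extra_hybrid_edges: int = 3,
    n_heterosis_genes: int = 0,
    seed: int = 0,
    heterosis_pool: tuple[str, ...] | list[str] | None = None,
) -> NetworkEnsemble:
    """Build the four genotype networks with planted hybrid-specific edges.

    Networks are constructed in partial-correlation space: the precision
    matrix is ``K = I - gamma * R`` where ``R`` carries the target partial
    correlations. The parents share one sparse background network with weak
    edges (``BASE_PCOR_RANGE``); each hybrid independently adds
    ``extra_hybrid_edges`` strong new edges incident to every heterosis gene,
    sized to fill the gene's positive-definiteness budget (sum of squared
    partial correlations up to ``THETA**2``). Extra edges within one hybrid
    use mutually distinct non-planted partners (disjoint stars), which keeps
    the spectrum controlled; one global factor ``gamma`` (shared by all four
    genotypes, so parental edges stay bit-identical across genotypes) enforces
    a smallest eigenvalue of at least ``EIG_MARGIN``.

    ``heterosis_pool`` optionally restricts the candidate genes the planted
    set is drawn from (default: all analyzed genes).
    """
    if not 0 <= n_heterosis_genes <= n_analyzed <= catalog.n_genes:
        raise ValueError(
            "require 0 <= n_heterosis_genes <= n_analyzed <= catalog size, got "
            f"{n_heterosis_genes}, {n_analyzed}, {catalog.n_genes}"
        )
    if base_edges_per_gene < 0:
        raise ValueError("base_edges_per_gene must be non-negative")
    if extra_hybrid_edges < 1:
        raise ValueError("extra_hybrid_edges must be a positive integer")
    n = n_analyzed
    m_base = int(round(base_edges_per_gene * n / 2.0))
    if m_base > n * (n - 1) // 2:
        raise ValueError("requested base density exceeds the complete graph")
    if n_heterosis_genes * extra_hybrid_edges > n - n_heterosis_genes:
        raise ValueError(
            f"{n_heterosis_genes} planted genes with {extra_hybrid_edges} extra "
            f"edges need {n_heterosis_genes * extra_hybrid_edges} distinct "
            f"non-planted partners; only {n - n_heterosis_genes} available"
        )

    rng = np.random.default_rng(seed)
    all_ids = np.asarray(catalog.gene_ids)
    analyzed_idx = np.sort(rng.choice(catalog.n_genes, size=n, replace=False))
    gene_ids = tuple(all_ids[analyzed_idx])

    if heterosis_pool is None:
        pool = np.arange(n)
    else:
        pool_set = set(heterosis_pool)
        pool = np.array([i for i, g in enumerate(gene_ids) if g in pool_set])
        if len(pool) < n_heterosis_genes:
            raise ValueError(
                f"heterosis_pool provides only {len(pool)} analyzed genes, "
                f"{n_heterosis_genes} required"
            )
    het_idx = (rng.choice(pool, size=n_heterosis_genes, replace=False)
               if n_heterosis_genes else np.array([], dtype=int))
    het_set = set(int(i) for i in het_idx)

    r_base = np.zeros((n, n))
    if m_base:
        bi, bj = _sample_pairs(n, m_base, rng)
        wts = rng.uniform(*BASE_PCOR_RANGE, size=m_base) * rng.choice([-1.0, 1.0], m_base)
        r_base[bi, bj] = wts
        r_base[bj, bi] = wts

    def add_planted_edges() -> np.ndarray:
        r = r_base.copy()
        used: set[int] = set()
        for g in het_idx:
            g = int(g)
            rho = np.sqrt(max(THETA**2 - (r[g] ** 2).sum(), 0.0) / extra_hybrid_edges)
            avail = np.array(
                [j for j in range(n)
                 if j != g and j not in het_set and j not in used and r[g, j] == 0.0],
                dtype=int,
            )
            if len(avail) < extra_hybrid_edges:
                raise ValueError(
                    f"cannot add {extra_hybrid_edges} new edges to gene index {g}: "
                    f"only {len(avail)} free partners"
                )
            partners = rng.choice(avail, size=extra_hybrid_edges, replace=False)
            signs = rng.choice([-1.0, 1.0], size=extra_hybrid_edges)
            r[g, partners] = rho * signs
            r[partners, g] = rho * signs
            used.update(int(j) for j in partners)
        return r

    r_by_genotype = {
        "P1": r_base,
        "P2": r_base,
        "H12": add_planted_edges(),
        "H21": add_planted_edges(),
    }
    worst = min(
        float(np.linalg.eigvalsh(np.eye(n) - r_by_genotype[g])[0])
        for g in ("P1", "H12", "H21")
    )
    gamma = min(1.0, (1.0 - EIG_MARGIN) / (1.0 - worst)) if worst < EIG_MARGIN else 1.0

    precisions: dict[str, np.ndarray] = {}
    for g, r in r_by_genotype.items():
        k = np.eye(n) - gamma * r
        # standardize to unit marginal variances: partial correlations are
        # invariant under diagonal scaling, but equal variances keep planted
        # hub genes statistically comparable to the rest
        d = np.sqrt(np.diag(np.linalg.inv(k)))
        prec = k * np.outer(d, d)
        prec = (prec + prec.T) / 2.0
        np.linalg.cholesky(prec)  # verify positive definiteness
        precisions[g] = prec
    return NetworkEnsemble(
        gene_ids=tuple(str(g) for g in gene_ids),
        precisions=precisions,
        heterosis_genes=tuple(str(g) for g in all_ids[analyzed_idx[sorted(het_set)]]),
    )


# ---------------------------------------------------------------------------
# expression panels
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpressionPanel:
    """Expression samples (rows) x genes (columns) for one genotype.

    Each sample carries a time-point index (1..T) and a replicate index
    (1..R); sample names follow ``GENOTYPE_Tt_Rr``.
    """

    genotype: str
    values: np.ndarray
    gene_ids: tuple[str, ...]
    time: np.ndarray
    replicate: np.ndarray

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if self.values.shape != (len(self.time), len(self.gene_ids)):
            raise ValueError("values shape inconsistent with metadata")
        if not np.isfinite(self.values).all():
            raise ValueError("expression values must be finite")
        if len(self.time) < 4:
            raise ValueError("at least 4 samples per genotype required")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def sample_names(self) -> tuple[str, ...]:
        return tuple(
            f"{self.genotype}_T{t}_R{r}" for t, r in zip(self.time, self.replicate)
        )

    def to_frame(self) -> pd.DataFrame:
        """Genes x samples table (the on-disk layout)."""
        return pd.DataFrame(
            self.values.T, index=list(self.gene_ids), columns=list(self.sample_names)
        ).rename_axis("gene_id")


def simulate_expression(
    ensemble: NetworkEnsemble,
    n_timepoints: int = 7,
    n_replicates: int = 3,
    seed: int = 0,
    time_effect_sd: float = 0.3,
    flat_gene_fraction: float = 0.1,
) -> dict[str, ExpressionPanel]:
    """Sample multivariate-normal expression per genotype along a time course.

    Each of the ``n_timepoints * n_replicates`` samples is an independent
    draw from N(mu_t, Omega_G^-1) with Omega_G the genotype's precision
    matrix. The time-point means ``mu_t`` are per-(gene, time) Gaussian
    offsets with scale ``time_effect_sd``, *shared across all four genotypes*
    — they give most genes a genuine time effect for the ANOVA pre-filter
    while cancelling exactly in hybrid-vs-parent network contrasts. A random
    ``flat_gene_fraction`` of genes receives no time effect (these are the
    genes the pre-filter is meant to exclude).
    """
    if n_timepoints < 4:
        raise ValueError("n_timepoints must be >= 4")
    if n_replicates < 1:
        raise ValueError("n_replicates must be positive")
    if time_effect_sd < 0:
        raise ValueError("time_effect_sd must be non-negative")
    if not 0.0 <= flat_gene_fraction <= 1.0:
        raise ValueError("flat_gene_fraction must lie in [0, 1]")
    from scipy.linalg import solve_triangular

    p = len(ensemble.gene_ids)
    m = n_timepoints * n_replicates
    time = np.repeat(np.arange(1, n_timepoints + 1), n_replicates)
    repl = np.tile(np.arange(1, n_replicates + 1), n_timepoints)
    children = np.random.SeedSequence(seed).spawn(len(GENOTYPES) + 1)

    trend_rng = np.random.default_rng(children[0])
    trend = trend_rng.standard_normal((n_timepoints, p))
    # centre and normalise so every non-flat gene's trend has sd exactly
    # time_effect_sd across time points (a real, detectable time dependency)
    trend -= trend.mean(axis=0)
    norms = np.sqrt((trend**2).mean(axis=0))
    norms[norms == 0] = 1.0
    trend *= time_effect_sd / norms
    flat = trend_rng.random(p) < flat_gene_fraction
    trend[:, flat] = 0.0

    panels: dict[str, ExpressionPanel] = {}
    for genotype, child in zip(GENOTYPES, children[1:]):
        rng = np.random.default_rng(child)
        prec = ensemble.precisions[genotype]
        L = np.linalg.cholesky(prec)
        z = rng.standard_normal((p, m))
        # x = L^-T z  =>  cov(x) = (L L^T)^-1 = Omega^-1
        x = solve_triangular(L.T, z, lower=False).T
        x += trend[time - 1, :]
        panels[genotype] = ExpressionPanel(
            genotype=genotype,
            values=x,
            gene_ids=ensemble.gene_ids,
            time=time.copy(),
            replicate=repl.copy(),
        )
    return panels


# ---------------------------------------------------------------------------
# QTL regions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QTLRegionSet:
    """QTL candidate regions (half-open cM intervals) and the derived test set.

    ``test_set`` lists exactly the catalog genes whose position falls inside a
    region, in catalog order.
    """

    regions: pd.DataFrame  # columns: chromosome, cM_start, cM_end
    test_set: tuple[str, ...]


def _genes_in_regions(catalog: GeneCatalog, regions: pd.DataFrame) -> tuple[str, ...]:
    chrom = catalog.table["chromosome"].to_numpy()
    pos = catalog.table["position_cM"].to_numpy()
    inside = np.zeros(catalog.n_genes, dtype=bool)
    for _, row in regions.iterrows():
        inside |= (chrom == row["chromosome"]) & (pos >= row["cM_start"]) & (pos < row["cM_end"])
    return tuple(np.asarray(catalog.gene_ids)[inside])


def define_qtl_regions(
    catalog: GeneCatalog,
    heterosis_genes: tuple[str, ...] | list[str],
    n_regions: int = 7,
    capture_fraction: float = 0.8,
    region_width_cM: float = 8.0,
    seed: int = 0,
) -> QTLRegionSet:
    """Place QTL regions so ~``capture_fraction`` of heterosis genes fall inside.

    Regions are centred on sampled heterosis genes until the capture target is
    met (or anchors run out), the remainder placed uniformly at random;
    regions never overlap within a chromosome. With ``capture_fraction=0`` the
    placement ignores the planted genes entirely (null construction).
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    if not 0.0 <= capture_fraction <= 1.0:
        raise ValueError("capture_fraction must lie in [0, 1]")
    lengths = np.asarray(catalog.chrom_lengths_cM)
    if region_width_cM <= 0 or region_width_cM > lengths.min():
        raise ValueError(
            f"region_width_cM={region_width_cM} must be positive and fit every "
            f"chromosome (min length {lengths.min()})"
        )
    rng = np.random.default_rng(seed)
    pos_of = catalog.positions()
    chrom_of = catalog.chromosome_of()
    w = float(region_width_cM)

    target = int(round(capture_fraction * len(heterosis_genes)))
    placed: list[tuple[int, float, float]] = []
    captured: set[str] = set()
    het_order = list(rng.permutation(np.asarray(heterosis_genes))) if len(heterosis_genes) else []

    def overlaps(c: int, start: float, end: float) -> bool:
        return any(
            pc == c and not (end <= pstart or start >= pend)
            for pc, pstart, pend in placed
        )

    def capture_update(c: int, start: float, end: float) -> None:
        for g in heterosis_genes:
            if chrom_of[g] == c and start <= pos_of[g] < end:
                captured.add(g)

    def place_uniform() -> tuple[int, float, float]:
        eligible = np.flatnonzero(lengths >= w)
        probs = lengths[eligible] / lengths[eligible].sum()
        for _ in range(500):
            c = int(rng.choice(eligible, p=probs)) + 1
            start = float(rng.uniform(0.0, lengths[c - 1] - w))
            if not overlaps(c, start, start + w):
                return c, start, start + w
        raise RuntimeError("could not place a non-overlapping QTL region")

    for _ in range(n_regions):
        region = None
        if len(captured) < target:
            for g in het_order:
                if g in captured:
                    continue
                c = int(chrom_of[g])
                start = float(np.clip(pos_of[g] - w / 2.0, 0.0, lengths[c - 1] - w))
                if not overlaps(c, start, start + w):
                    region = (c, start, start + w)
                    break
        if region is None:
            region = place_uniform()
        placed.append(region)
        capture_update(*region)

    regions = pd.DataFrame(placed, columns=["chromosome", "cM_start", "cM_end"])
    regions["chromosome"] = regions["chromosome"].astype(int)
    test_set = _genes_in_regions(catalog, regions)
    logger.info(
        "placed %d QTL regions capturing %d/%d heterosis genes; test set %d genes",
        n_regions, len(captured), len(heterosis_genes), len(test_set),
    )
    return QTLRegionSet(regions=regions, test_set=test_set)


# ---------------------------------------------------------------------------
# pathway collections
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets (pathways); at most one flagged as planted-enriched."""

    sets: dict[str, tuple[str, ...]] = field(default_factory=dict)
    planted_enriched: str | None = None

    def sizes(self) -> dict[str, int]:
        return {name: len(members) for name, members in self.sets.items()}


def assign_pathways(
    catalog: GeneCatalog,
    analyzed_genes: tuple[str, ...] | list[str],
    n_pathways: int = 80,
    size_range: tuple[int, int] = (10, 4000),
    planted_set: tuple[str, ...] | list[str] = (),
    seed: int = 0,
    enrichment_odds: float = 10.0,
) -> GeneSetCollection:
    """Draw pathway gene sets from the analyzed genes.

    Sizes are uniform in ``size_range``. If ``planted_set`` is non-empty one
    pathway is over-sampled from it with per-gene odds ``enrichment_odds``
    (odds 1 makes the planted pathway indistinguishable from the rest).
    """
    analyzed = np.asarray(analyzed_genes)
    lo, hi = size_range
    if not (1 <= lo <= hi <= len(analyzed)):
        raise ValueError(
            f"size_range {size_range} infeasible for {len(analyzed)} analyzed genes"
        )
    if n_pathways < 1:
        raise ValueError("n_pathways must be positive")
    catalog_ids = set(catalog.gene_ids)
    if not set(analyzed) <= catalog_ids:
        raise ValueError("analyzed_genes must be drawn from the catalog")
    planted = tuple(planted_set)
    if planted and not set(planted) <= set(analyzed):
        raise ValueError("planted_set must be a subset of analyzed_genes")
    if enrichment_odds <= 0:
        raise ValueError("enrichment_odds must be positive")

    rng = np.random.default_rng(seed)
    sizes = rng.integers(lo, hi + 1, size=n_pathways)
    planted_idx = int(rng.integers(n_pathways)) if planted else None
    weights = np.ones(len(analyzed))
    if planted:
        weights[np.isin(analyzed, planted)] = enrichment_odds

    sets: dict[str, tuple[str, ...]] = {}
    planted_name = None
    for i, size in enumerate(sizes):
        name = f"PW{i:04d}"
        if planted_idx is not None and i == planted_idx:
            members = rng.choice(
                analyzed, size=size, replace=False, p=weights / weights.sum()
            )
            planted_name = name
        else:
            members = rng.choice(analyzed, size=size, replace=False)
        sets[name] = tuple(sorted(members))
    return GeneSetCollection(sets=sets, planted_enriched=planted_name)
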