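"""Derived enrichment analyses on top of the core ORA.

Four analyses mirror the integrated study design:

* resampling empirical p-values — the gene set is redrawn B times uniformly
  from the reference and the observed overlap is compared with the resampled
  overlaps, p_emp = #{k_b >= k_orig} / B (distribution-free check of the
  hypergeometric tail);
* chromosome-wise sweeps — each top-n gene set is split by chromosome while
  reference and test set stay unchanged;
* annotation ORA — enrichment of an annotation flag (e.g. duplicated genes)
  in the top-n genes;
* pathway ORA — the candidate group (top-n ranked genes intersected with the
  QTL test set) is tested against a pathway collection with BH-FDR control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ora import ORAResult, SweepResult, _make_result, run_ora, sweep_grid
from .scoring import fdr_adjust
from .synthetic import GeneCatalog, GeneSetCollection

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ResamplingResult:
    """Empirical resampling p-value for one gene-set size."""

    n: int
    k_orig: int
    B: int
    count_ge: int
    p_emp: float
    seed: int


def empirical_pvalue(
    reference: Iterable[str],
    test_set: Iterable[str],
    ranked_genes: Sequence[str],
    n: int,
    B: int = 1000,
    seed: int = 0,
    plus_one: bool = False,
) -> ResamplingResult:
    """Resampling p-value for the top-n gene set.

    Draws ``B`` size-n gene sets uniformly without replacement from the
    reference, counts how many overlap the test set at least as much as the
    original top-n set, and returns ``count / B`` (or the conservative
    ``(count+1)/(B+1)`` with ``plus_one``). Deterministic given ``seed``.
    """
    if B <= 0:
        raise ValueError("B must be positive")
    ref = sorted(set(reference))
    a = len(ref)
    if n > a:
        raise ValueError(f"n={n} exceeds reference size {a}")
    ranked = list(ranked_genes)
    if n > len(ranked):
        raise ValueError(f"n={n} exceeds ranking length {len(ranked)}")
    test = set(test_set)
    if not test <= set(ref):
        raise ValueError("test_set must be a subset of the reference set")
    k_orig = len(test & set(ranked[:n]))

    member = np.fromiter((g in test for g in ref), dtype=bool, count=a)
    rng = np.random.default_rng(seed)
    count_ge = 0
    if n == 0:
        count_ge = B if k_orig == 0 else 0
    else:
        chunk = max(1, min(B, int(4e7 // max(a, 1))))
        done = 0
        while done < B:
            b = min(chunk, B - done)
            keys = rng.random((b, a))
            top = np.argpartition(keys, n - 1, axis=1)[:, :n]
            k_b = member[top].sum(axis=1)
            count_ge += int((k_b >= k_orig).sum())
            done += b
    p = (count_ge + 1) / (B + 1) if plus_one else count_ge / B
    return ResamplingResult(n=n, k_orig=k_orig, B=B, count_ge=count_ge, p_emp=p, seed=seed)


def chromosome_sweep(
    reference: Iterable[str],
    test_set: Iterable[str],
    ranked_genes: Sequence[str],
    catalog: GeneCatalog,
    step: int = 100,
    n_max: int | None = None,
    max_unmapped_fraction: float = 0.05,
) -> dict[int, SweepResult]:
    """Per-chromosome ORA sweeps.

    At each grid point n the chromosome-c gene set is the subset of the top-n
    ranked genes located on chromosome c; reference and test set are the same
    as in the plain sweep. Ranked genes absent from the catalog are dropped
    (counted in each sweep's provenance); more than
    ``max_unmapped_fraction`` unmapped genes raises.
    """
    ref = set(reference)
    if not ref:
        raise ValueError("reference set must not be empty")
    test = set(test_set)
    if not test <= ref:
        raise ValueError("test_set must be a subset of the reference set")
    ranked = list(ranked_genes)
    if len(set(ranked)) != len(ranked):
        raise ValueError("ranked_genes contains duplicate ids")
    if n_max is None:
        n_max = len(ranked)
    if n_max > len(ranked):
        raise ValueError("n_max exceeds the length of the ranking")

    chrom_of = catalog.chromosome_of()
    chrom = np.array([chrom_of.get(g, 0) for g in ranked], dtype=int)
    n_unmapped_total = int((chrom == 0).sum())
    if n_unmapped_total > max_unmapped_fraction * max(len(ranked), 1):
        raise ValueError(
            f"{n_unmapped_total}/{len(ranked)} ranked genes missing from the catalog"
        )
    if n_unmapped_total:
        logger.warning("%d ranked gene(s) not in the catalog; dropped from "
                       "chromosome gene sets", n_unmapped_total)
    in_test = np.fromiter((g in test for g in ranked), dtype=bool, count=len(ranked))

    a, t = len(ref), len(test)
    grid = sweep_grid(n_max, step)
    unmapped_prefix = np.concatenate([[0], np.cumsum(chrom == 0)])
    sweeps: dict[int, SweepResult] = {}
    for c in sorted(set(int(x) for x in catalog.table["chromosome"])):
        on_c = chrom == c
        size_prefix = np.concatenate([[0], np.cumsum(on_c)])
        k_prefix = np.concatenate([[0], np.cumsum(on_c & in_test)])
        results = tuple(
            _make_result(a, t, int(size_prefix[n]), int(k_prefix[n])) for n in grid
        )
        sweeps[c] = SweepResult(
            grid=tuple(grid),
            results=results,
            provenance={
                "chromosome": c,
                "n_unmapped_total": n_unmapped_total,
                "unmapped_by_n": tuple(int(unmapped_prefix[n]) for n in grid),
            },
        )
    return sweeps


def annotation_ora(
    ranked_genes: Sequence[str],
    n: int,
    annotation_set: Iterable[str],
    reference: Iterable[str],
) -> ORAResult:
    """Enrichment of an annotation flag (test set) in the top-n ranked genes."""
    ranked = list(ranked_genes)
    if n > len(ranked):
        raise ValueError(f"n={n} exceeds ranking length {len(ranked)}")
    return run_ora(reference, annotation_set, ranked[:n])


def candidate_overlap(
    ranked_genes: Sequence[str],
    qtl_test_set: Iterable[str],
    top_n: int = 3000,
) -> list[str]:
    """Candidate group: top-n ranked genes also in the QTL test set.

    Returned in catalog (gene-id) order.
    """
    ranked = list(ranked_genes)
    if top_n > len(ranked):
        raise ValueError(f"top_n={top_n} exceeds ranking length {len(ranked)}")
    overlap = set(ranked[:top_n]) & set(qtl_test_set)
    return sorted(overlap)


@dataclass(frozen=True)
class PathwayORAResult:
    """One pathway's over-representation test with BH-FDR adjustment."""

    pathway_id: str
    n_set: int
    k: int
    k_expected: float
    p_raw: float | None
    p_adjusted: float
    significant: bool


def pathway_ora(
    reference: Iterable[str],
    candidate_set: Iterable[str],
    pathways: GeneSetCollection,
    fdr_threshold: float = 0.05,
    size_range: tuple[int, int] = (10, 4000),
) -> list[PathwayORAResult]:
    """ORA of the candidate group against every pathway, BH-FDR corrected.

    Pathways are filtered to those whose intersection with the reference has
    a size within ``size_range``. Pathways without a computed p-value (no
    over-representation) enter the BH adjustment with p = 1 so the ranked
    table is total. Results are sorted by adjusted then raw p-value.
    """
    ref = set(reference)
    if not ref:
        raise ValueError("reference set must not be empty")
    cand = set(candidate_set)
    if not cand <= ref:
        raise ValueError("candidate_set must be a subset of the reference set")
    lo, hi = size_range
    kept: list[tuple[str, set[str]]] = []
    for name in sorted(pathways.sets):
        members = set(pathways.sets[name]) & ref
        if lo <= len(members) <= hi:
            kept.append((name, members))
    if not kept:
        raise ValueError("no pathway within the size range after reference filtering")

    results = [run_ora(ref, cand, members) for _, members in kept]
    p_for_bh = np.array([r.p_value if r.p_value is not None else 1.0 for r in results])
    p_adj = fdr_adjust(p_for_bh)
    rows = [
        PathwayORAResult(
            pathway_id=name,
            n_set=r.n,
            k=r.k,
            k_expected=r.k_expected,
            p_raw=r.p_value,
            p_adjusted=float(adj),
            significant=bool(adj <= fdr_threshold),
        )
        for (name, _), r, adj in zip(kept, results, p_adj)
    ]
    rows.sort(key=lambda r: (r.p_adjusted, r.p_raw if r.p_raw is not None else 1.0,
                             r.pathway_id))
    return rows


def pathway_table(results: list[PathwayORAResult]) -> pd.DataFrame:
    """Ranked pathway ORA results as a table."""
    return pd.DataFrame(
        {
            "pathway_id": [r.pathway_id for r in results],
            "n_set": [r.n_set for r in results],
            "k": [r.k for r in results],
            "k_expected": [r.k_expected for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_adjusted": [r.p_adjusted for r in results],
            "significant": [r.significant for r in results],
        }
    )
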