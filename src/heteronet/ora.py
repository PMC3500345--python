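"""Hypergeometric over-representation analysis (ORA) of ranked gene lists.

Terminology follows the standard enrichment setup: the *reference set* holds
all genes under consideration (size ``a``), the *test set* (size ``t``) the
genes singled out by an independent analysis (e.g. QTL candidate regions),
and the *gene set* (size ``n``) the genes whose enrichment in the test set is
assessed (here: top-n of a score ranking). With ``k`` the observed overlap,

    k_expected = n * t / a
    p = P(X >= k),  X ~ Hypergeometric(a, t, n)

which is identical to a one-tailed Fisher exact test. Following the study
design, p-values are only computed when the observed overlap exceeds the
expected one (over-representation only), and the whole analysis is swept over
gene-set sizes n = 0, step, 2*step, ... because the overlap probability at
fixed true signal depends on n.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

logger = logging.getLogger(__name__)


def expected_overlap(a: int, t: int, n: int) -> float:
    """Expected overlap n*t/a for a random size-t test set from the reference."""
    _check_counts(a, t, n)
    return n * t / a


def _check_counts(a: int, t: int, n: int) -> None:
    if a <= 0:
        raise ValueError("reference-set size a must be positive")
    if not 0 <= t <= a:
        raise ValueError(f"test-set size t={t} must lie in [0, a={a}]")
    if not 0 <= n <= a:
        raise ValueError(f"gene-set size n={n} must lie in [0, a={a}]")


def _log_binom(n: float | np.ndarray, k: float | np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_pvalue(a: int, t: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k), inclusive of k.

    X counts the overlap between a fixed size-n gene set and a size-t test
    set drawn uniformly from a reference of a genes. The tail is accumulated
    in log space (no 1-CDF subtraction), so tiny p-values keep full relative
    precision.
    """
    _check_counts(a, t, n)
    if not 0 <= k <= min(t, n):
        raise ValueError(f"k={k} must lie in [0, min(t={t}, n={n})]")
    lo = max(k, t + n - a)
    hi = min(t, n)
    if k <= max(0, t + n - a):
        return 1.0
    i = np.arange(lo, hi + 1)
    logp = _log_binom(t, i) + _log_binom(a - t, n - i) - _log_binom(a, n)
    return float(min(1.0, np.exp(logsumexp(logp))))


@dataclass(frozen=True)
class ORAResult:
    """One over-representation test.

    ``p_value`` is present only when the observed overlap ``k`` exceeds the
    expected overlap; ``enrichment_fraction`` = (k - k_expected)/k_expected
    is present only when ``k_expected`` > 0.
    """

    a: int
    t: int
    n: int
    k: int
    k_expected: float
    p_value: float | None
    enrichment_fraction: float | None


def _make_result(a: int, t: int, n: int, k: int) -> ORAResult:
    ke = expected_overlap(a, t, n)
    p = hypergeom_pvalue(a, t, n, k) if k > ke else None
    ef = (k - ke) / ke if ke > 0 else None
    return ORAResult(a=a, t=t, n=n, k=k, k_expected=ke, p_value=p, enrichment_fraction=ef)


def run_ora(
    reference: Iterable[str], test_set: Iterable[str], gene_set: Iterable[str]
) -> ORAResult:
    """Over-representation of ``gene_set`` in ``test_set`` within ``reference``.

    ``test_set`` must be contained in the reference; gene-set members outside
    the reference are dropped with a logged count.
    """
    ref = set(reference)
    if not ref:
        raise ValueError("reference set must not be empty")
    test = set(test_set)
    if not test <= ref:
        raise ValueError("test_set must be a subset of the reference set")
    gset = set(gene_set)
    outside = len(gset - ref)
    if outside:
        logger.warning("dropping %d gene-set member(s) outside the reference", outside)
        gset &= ref
    return _make_result(a=len(ref), t=len(test), n=len(gset), k=len(test & gset))


@dataclass(frozen=True)
class SweepResult:
    """ORA results along a grid of gene-set sizes.

    ``grid`` holds the nominal top-n values; ``results[i].n`` is the actual
    gene-set size at grid point i (these differ in stratified sweeps where the
    gene set is the on-chromosome part of the top-n genes).
    """

    grid: tuple[int, ...]
    results: tuple[ORAResult, ...]
    provenance: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "n_top": g,
                "n_set": r.n,
                "k": r.k,
                "k_expected": r.k_expected,
                "p_value": r.p_value,
                "enrichment_fraction": r.enrichment_fraction,
            }
            for g, r in zip(self.grid, self.results)
        ]
        return pd.DataFrame(rows)


def sweep_grid(n_max: int, step: int) -> list[int]:
    """0, step, 2*step, ..., plus n_max itself if the grid misses it."""
    if step <= 0:
        raise ValueError("step must be positive")
    grid = list(range(0, n_max + 1, step))
    if grid[-1] != n_max:
        grid.append(n_max)
    return grid


def sweep_ora(
    reference: Iterable[str],
    test_set: Iterable[str],
    ranked_genes: Sequence[str],
    step: int = 100,
    n_max: int | None = None,
    provenance: dict | None = None,
) -> SweepResult:
    """ORA swept over gene-set sizes: gene set = top-n of ``ranked_genes``."""
    ref = set(reference)
    if not ref:
        raise ValueError("reference set must not be empty")
    test = set(test_set)
    if not test <= ref:
        raise ValueError("test_set must be a subset of the reference set")
    ranked = list(ranked_genes)
    if len(set(ranked)) != len(ranked):
        raise ValueError("ranked_genes contains duplicate ids")
    if not set(ranked) <= ref:
        raise ValueError("ranked_genes must be a subset of the reference set")
    if n_max is None:
        n_max = len(ranked)
    if n_max > len(ranked):
        raise ValueError("n_max exceeds the length of the ranking")

    member = np.fromiter((g in test for g in ranked), dtype=bool, count=len(ranked))
    k_prefix = np.concatenate([[0], np.cumsum(member)])
    a, t = len(ref), len(test)
    grid = sweep_grid(n_max, step)
    results = tuple(_make_result(a, t, n, int(k_prefix[n])) for n in grid)
    return SweepResult(grid=tuple(grid), results=results, provenance=provenance or {})
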