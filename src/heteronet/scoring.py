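"""Per-gene network-heterosis scores from expression panels.

The scoring chain, per genotype, is:

1. ANOVA pre-filter: keep genes whose expression shows a time and/or
   genotype x time interaction effect (BH-adjusted p <= alpha, default 0.3).
2. Shrinkage partial correlations (Schaefer-Strimmer): shrink the empirical
   correlation matrix toward the identity with analytically estimated
   intensity lambda, then scale the negative inverse to partial correlations.
   The estimate stays well conditioned with fewer samples than genes.
3. Two-sided p-values for the null of zero partial correlation from the
   beta-family null density f(r) ~ (1 - r^2)^((kappa-3)/2) with kappa fitted
   by maximum likelihood over the off-diagonal entries (assumes most pairs
   are null), then BH-FDR adjusted across all unordered gene pairs.
4. h-values  h(i,j) = 1 - p_adj(i,j); per gene the mean over all partners.
5. Heterosis scores per hybrid H and gene g:
       MPH(g) = h_H(g) - (h_P1(g) + h_P2(g)) / 2
       BPH(g) = h_H(g) - max(h_P1(g), h_P2(g))
   so BPH <= MPH always; high scores mark genes with more significant
   partial correlations (denser network neighbourhood) in the hybrid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .synthetic import ExpressionPanel, GENOTYPES, HYBRIDS, PARENTS

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# ANOVA pre-filter
# ---------------------------------------------------------------------------


def anova_effect_pvalues(
    panels: Mapping[str, ExpressionPanel],
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene p-values for the time main effect and genotype x time interaction.

    Fits, per gene, the balanced fixed-effects two-way model
    ``expression ~ genotype + time + genotype:time`` (both factors
    categorical). Genes with no residual variation and no effect signal
    (constant genes) get p = 1; a perfect noiseless effect gets p = 0.

    Requires a balanced design with >= 2 time points and >= 2 replicates per
    cell (otherwise the interaction term is inestimable).
    """
    if set(panels) != set(GENOTYPES):
        raise ValueError(f"panels must cover genotypes {GENOTYPES}")
    gene_ids = panels[GENOTYPES[0]].gene_ids
    for g in GENOTYPES:
        if panels[g].gene_ids != gene_ids:
            raise ValueError("panels must share identical gene ordering")

    times = np.unique(np.concatenate([panels[g].time for g in GENOTYPES]))
    if len(times) < 2:
        raise ValueError("at least 2 time points required (interaction inestimable)")

    A, B = len(GENOTYPES), len(times)
    # reshape into (genotype, time, replicate, gene) verifying balance
    blocks = []
    n_rep = None
    for g in GENOTYPES:
        panel = panels[g]
        per_time = []
        for t in times:
            rows = panel.values[panel.time == t]
            if n_rep is None:
                n_rep = len(rows)
            if len(rows) != n_rep or n_rep == 0:
                raise ValueError("unbalanced design: unequal samples per genotype/time cell")
            per_time.append(rows)
        blocks.append(np.stack(per_time))
    if n_rep < 2:
        raise ValueError(
            "at least 2 replicates per genotype/time cell required "
            "(zero error degrees of freedom otherwise)"
        )
    y = np.stack(blocks)  # (A, B, R, G)
    R = n_rep

    m = y.mean(axis=(0, 1, 2))
    m_a = y.mean(axis=(1, 2))
    m_b = y.mean(axis=(0, 2))
    m_ab = y.mean(axis=2)
    ss_time = A * R * ((m_b - m) ** 2).sum(axis=0)
    ss_int = R * ((m_ab - m_a[:, None, :] - m_b[None, :, :] + m) ** 2).sum(axis=(0, 1))
    ss_err = ((y - m_ab[:, :, None, :]) ** 2).sum(axis=(0, 1, 2))
    df_time, df_int, df_err = B - 1, (A - 1) * (B - 1), A * B * (R - 1)

    def effect_pvalues(ss_eff: np.ndarray, df_eff: int) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (ss_eff / df_eff) / (ss_err / df_err)
            p = stats.f.sf(f, df_eff, df_err)
        p = np.asarray(p)
        p[~np.isfinite(f)] = np.where(ss_eff[~np.isfinite(f)] > 0, 0.0, 1.0)
        p[np.isnan(f)] = 1.0  # 0/0: constant gene, no signal
        return p

    return effect_pvalues(ss_time, df_time), effect_pvalues(ss_int, df_int)


def filter_genes_anova(
    panels: Mapping[str, ExpressionPanel], alpha: float = 0.3
) -> list[str]:
    """Keep genes with a time and/or genotype x time effect.

    BH-adjusts the per-effect ANOVA p-values (see ``anova_effect_pvalues``)
    across genes and retains a gene iff
    ``min(p_adj_time, p_adj_interaction) <= alpha``; the default cutoff 0.3
    removes only genes with nearly no time dependency. Returned in the
    panels' gene order.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    p_time, p_int = anova_effect_pvalues(panels)
    keep = np.minimum(fdr_adjust(p_time), fdr_adjust(p_int)) <= alpha
    gene_ids = panels[GENOTYPES[0]].gene_ids
    return [g for g, k in zip(gene_ids, keep) if k]


# ---------------------------------------------------------------------------
# shrinkage partial correlation
# ---------------------------------------------------------------------------


def estimate_shrinkage_pcor(X: np.ndarray) -> tuple[np.ndarray, float]:
    """Schaefer-Strimmer shrinkage partial correlations.

    ``X`` is samples x genes. The empirical correlation matrix is shrunk
    toward the identity with the analytic intensity

        lambda = sum Var(r_ij) / sum r_ij^2   (off-diagonal, clipped to [0,1])

    and inverted; off-diagonal entries of the scaled negative inverse are the
    partial correlations. Returns ``(pcor, lambda)``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D samples x genes matrix")
    n, p = X.shape
    if n < 4:
        raise ValueError("at least 4 samples required")
    if p < 2:
        raise ValueError("at least 2 genes required")
    sd = X.std(axis=0, ddof=1)
    zero_var = np.flatnonzero(sd == 0)
    if len(zero_var):
        raise ValueError(f"zero-variance gene column(s): {zero_var.tolist()}")

    z = (X - X.mean(axis=0)) / sd
    r = z.T @ z / (n - 1)
    # Var(r_ij) ~= n / (n-1)^3 * sum_k (w_kij - mean_k w_kij)^2,  w_kij = z_ki z_kj
    s1 = r * (n - 1)          # sum_k w_kij
    s2 = (z**2).T @ (z**2)    # sum_k w_kij^2
    var_r = n / (n - 1.0) ** 3 * (s2 - s1**2 / n)
    off = ~np.eye(p, dtype=bool)
    denom = (r[off] ** 2).sum()
    lam = 1.0 if denom == 0 else float(np.clip(var_r[off].sum() / denom, 0.0, 1.0))

    r_shrunk = (1.0 - lam) * r
    np.fill_diagonal(r_shrunk, 1.0)
    try:
        omega = np.linalg.inv(r_shrunk)
    except np.linalg.LinAlgError as exc:  # lambda == 0 with exact collinearity
        raise np.linalg.LinAlgError(
            f"shrunken correlation matrix singular (lambda={lam})"
        ) from exc
    d = np.sqrt(np.diag(omega))
    pcor = -omega / np.outer(d, d)
    np.fill_diagonal(pcor, 1.0)
    pcor = np.clip((pcor + pcor.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(pcor, 1.0)
    return pcor, lam


def pcor_pvalues(
    pcor: np.ndarray,
    fallback_kappa: float | None = None,
) -> tuple[np.ndarray, float]:
    """Two-sided p-values for the null of zero partial correlation.

    Fits the null density f(r) ~ (1 - r^2)^((kappa-3)/2) to the off-diagonal
    entries by maximum likelihood over kappa > 3 (most pairs assumed null);
    p(i,j) = P(|R| >= |pcor(i,j)|) under the fitted null, from the regularized
    incomplete beta function (R^2 ~ Beta(1/2, (kappa-1)/2)). The diagonal is
    excluded (NaN). Returns ``(pvalues, kappa)``.
    """
    pcor = np.asarray(pcor, dtype=float)
    p = pcor.shape[0]
    if pcor.shape != (p, p) or p < 2:
        raise ValueError("pcor must be a square matrix of size >= 2")
    iu = np.triu_indices(p, k=1)
    r2 = np.clip(pcor[iu] ** 2, 0.0, 1.0 - 1e-12)
    n_pairs = len(r2)
    s = np.log1p(-r2).sum()

    def negloglik(u: float) -> float:
        kappa = 3.0 + np.exp(u)
        return float(
            n_pairs * special.betaln(0.5, (kappa - 1.0) / 2.0) - (kappa - 3.0) / 2.0 * s
        )

    kappa = None
    if s < 0:  # all-zero pcor has s == 0: likelihood increases without bound
        res = optimize.minimize_scalar(
            negloglik, bounds=(-12.0, 30.0), method="bounded",
            options={"xatol": 1e-8},
        )
        if res.success and np.isfinite(res.fun) and res.x < 29.5:
            kappa = 3.0 + float(np.exp(res.x))
    if kappa is None:
        if fallback_kappa is None:
            raise FloatingPointError(
                "kappa fit failed to converge and no fallback_kappa given "
                f"(sum log(1-r^2) = {s:.3g} over {n_pairs} pairs)"
            )
        logger.warning("kappa fit diverged; falling back to kappa=%.3g", fallback_kappa)
        kappa = float(fallback_kappa)
    if kappa <= 3.0:
        kappa = 3.0 + 1e-9

    pvals = stats.beta.sf(pcor**2, 0.5, (kappa - 1.0) / 2.0)
    pvals = np.asarray(pvals, dtype=float)
    pvals[pcor**2 >= 1.0] = 0.0
    np.fill_diagonal(pvals, np.nan)
    pvals = (pvals + pvals.T) / 2.0
    return pvals, kappa


def fdr_adjust(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotone, order preserving)."""
    p = np.asarray(list(pvalues) if not isinstance(pvalues, np.ndarray) else pvalues,
                   dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be a 1-D vector")
    if p.size == 0:
        return p.copy()
    if not np.isfinite(p).all() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    adj = np.empty(m)
    adj[order] = adj_sorted
    return adj


# ---------------------------------------------------------------------------
# h-values and heterosis scores
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PartialCorrelationResult:
    """Partial correlations with raw and BH-adjusted significance."""

    pcor: np.ndarray
    shrinkage_lambda: float
    kappa: float
    pvalues: np.ndarray
    pvalues_adjusted: np.ndarray


def partial_correlation_analysis(
    X: np.ndarray, fallback_kappa: float | None = None
) -> PartialCorrelationResult:
    """Shrinkage pcor -> null p-values -> BH adjustment over all gene pairs."""
    pcor, lam = estimate_shrinkage_pcor(X)
    if fallback_kappa is None:
        fallback_kappa = max(4.0, X.shape[0] - 1.0)
    pvals, kappa = pcor_pvalues(pcor, fallback_kappa=fallback_kappa)
    p = pcor.shape[0]
    iu = np.triu_indices(p, k=1)
    adj_vec = fdr_adjust(pvals[iu])
    padj = np.full_like(pvals, np.nan)
    padj[iu] = adj_vec
    padj.T[iu] = adj_vec
    return PartialCorrelationResult(
        pcor=pcor, shrinkage_lambda=lam, kappa=kappa,
        pvalues=pvals, pvalues_adjusted=padj,
    )


def compute_h_table(
    adjusted_pvalues: Mapping[str, np.ndarray], gene_ids: Iterable[str]
) -> pd.DataFrame:
    """Per-genotype, per-gene mean h-values, h(i,j) = 1 - p_adj(i,j).

    ``adjusted_pvalues`` maps genotype to a symmetric matrix of BH-adjusted
    p-values (diagonal NaN / excluded). Returns genes x genotypes in [0, 1].
    """
    gene_ids = list(gene_ids)
    if set(adjusted_pvalues) != set(GENOTYPES):
        raise ValueError(f"adjusted p matrices required for genotypes {GENOTYPES}")
    cols = {}
    for g in GENOTYPES:
        padj = np.asarray(adjusted_pvalues[g], dtype=float)
        if padj.shape != (len(gene_ids), len(gene_ids)):
            raise ValueError(f"p matrix for {g} inconsistent with gene_ids")
        h = 1.0 - padj
        np.fill_diagonal(h, np.nan)
        cols[g] = np.nanmean(h, axis=1)
    table = pd.DataFrame(cols, index=gene_ids)[list(GENOTYPES)]
    return table.rename_axis("gene_id")


def mph_scores(h: pd.DataFrame, hybrid: str) -> pd.Series:
    """Mid-parent heterosis of h-values: h_H - (h_P1 + h_P2)/2."""
    _check_h(h, hybrid)
    return (h[hybrid] - (h["P1"] + h["P2"]) / 2.0).rename(f"mph_{hybrid}")


def bph_scores(h: pd.DataFrame, hybrid: str) -> pd.Series:
    """Best-parent heterosis of h-values: h_H - max(h_P1, h_P2)."""
    _check_h(h, hybrid)
    return (h[hybrid] - np.maximum(h["P1"], h["P2"])).rename(f"bph_{hybrid}")


def _check_h(h: pd.DataFrame, hybrid: str) -> None:
    if hybrid not in HYBRIDS:
        raise ValueError(f"hybrid must be one of {HYBRIDS}")
    missing = [g for g in (hybrid, *PARENTS) if g not in h.columns]
    if missing:
        raise ValueError(f"h-table missing genotype column(s): {missing}")


def score_table(h: pd.DataFrame) -> pd.DataFrame:
    """MPH and BPH scores for both hybrids, genes x (mph_H, bph_H) columns."""
    cols = {}
    for hyb in HYBRIDS:
        cols[f"mph_{hyb}"] = mph_scores(h, hyb)
        cols[f"bph_{hyb}"] = bph_scores(h, hyb)
    return pd.DataFrame(cols).rename_axis("gene_id")


def rank_genes(scores: pd.Series) -> list[str]:
    """Gene ids by descending score; ties broken by ascending gene id."""
    frame = scores.rename("score").rename_axis("gene_id").reset_index()
    frame = frame.sort_values(["score", "gene_id"], ascending=[False, True],
                              kind="stable")
    return frame["gene_id"].tolist()


def collapse_gene_models(
    scores: Mapping[str, float], model_to_gene: Mapping[str, str]
) -> tuple[dict[str, float], int]:
    """Average scores of gene models mapping to the same gene.

    Models without a gene mapping are dropped; returns ``(gene scores,
    dropped-model count)``.
    """
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    dropped = 0
    for model, value in scores.items():
        gene = model_to_gene.get(model)
        if gene is None:
            dropped += 1
            continue
        sums[gene] = sums.get(gene, 0.0) + float(value)
        counts[gene] = counts.get(gene, 0) + 1
    if dropped:
        logger.info("collapse_gene_models: dropped %d unmapped model(s)", dropped)
    return {g: sums[g] / counts[g] for g in sums}, dropped


# ---------------------------------------------------------------------------
# end-to-end scoring of panels
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScoringResult:
    """h-table, MPH/BPH scores and per-genotype estimation diagnostics."""

    gene_ids: tuple[str, ...]
    h_table: pd.DataFrame
    scores: pd.DataFrame
    pcor_results: dict[str, PartialCorrelationResult]
    dropped_genes: tuple[str, ...]

    def ranking(self, hybrid: str, measure: str = "mph") -> list[str]:
        return rank_genes(self.scores[f"{measure}_{hybrid}"])


def _detrend_by_time(panel: ExpressionPanel) -> np.ndarray:
    """Remove per-time-point means (the shared developmental trajectory)."""
    x = panel.values.astype(float).copy()
    for t in np.unique(panel.time):
        rows = panel.time == t
        x[rows] -= x[rows].mean(axis=0)
    return x


def score_panels(
    panels: Mapping[str, ExpressionPanel],
    genes: Iterable[str] | None = None,
    detrend_time: bool = False,
) -> ScoringResult:
    """Full scoring chain on four expression panels.

    ``genes`` optionally restricts to a subset (e.g. the ANOVA-retained
    genes). By default the partial correlations are computed on the raw time
    profiles; ``detrend_time`` optionally centres each gene within each time
    point per genotype first, at the cost of one degree of freedom per time
    point. Genes with zero variance in any genotype are excluded with a
    warning before estimation.
    """
    if set(panels) != set(GENOTYPES):
        raise ValueError(f"panels must cover genotypes {GENOTYPES}")
    base_ids = panels[GENOTYPES[0]].gene_ids
    for g in GENOTYPES:
        if panels[g].gene_ids != base_ids:
            raise ValueError("panels must share identical gene ordering")
    if genes is None:
        keep = list(base_ids)
    else:
        wanted = set(genes)
        keep = [g for g in base_ids if g in wanted]
    col_of = {g: i for i, g in enumerate(base_ids)}
    cols = np.array([col_of[g] for g in keep], dtype=int)
    data = {
        g: (_detrend_by_time(panels[g]) if detrend_time else panels[g].values)
        for g in GENOTYPES
    }

    degenerate: set[str] = set()
    for g in GENOTYPES:
        sd = data[g][:, cols].std(axis=0, ddof=1)
        for gene in np.asarray(keep)[sd == 0]:
            degenerate.add(str(gene))
    if degenerate:
        logger.warning(
            "excluding %d zero-variance gene(s) before partial correlation",
            len(degenerate),
        )
        keep = [g for g in keep if g not in degenerate]
        cols = np.array([col_of[g] for g in keep], dtype=int)
    if len(keep) < 2:
        raise ValueError("fewer than 2 usable genes after exclusions")

    pcor_results: dict[str, PartialCorrelationResult] = {}
    padj: dict[str, np.ndarray] = {}
    for g in GENOTYPES:
        res = partial_correlation_analysis(data[g][:, cols])
        pcor_results[g] = res
        padj[g] = res.pvalues_adjusted
    h = compute_h_table(padj, keep)
    return ScoringResult(
        gene_ids=tuple(keep),
        h_table=h,
        scores=score_table(h),
        pcor_results=pcor_results,
        dropped_genes=tuple(sorted(degenerate)),
    )
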