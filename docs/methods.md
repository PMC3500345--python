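# Methods

## Model and estimands

Each genotype's expression is modelled as a Gaussian graphical model (GGM):
samples are multivariate normal with precision matrix Ω_G, and a regulatory
interaction between genes i and j corresponds to a non-zero partial
correlation ρ_ij = −ω_ij / √(ω_ii ω_jj). The network-heterosis hypothesis is
that hybrids carry extra interactions relative to their parents, detectable
as an increase in the *significance* of pairwise partial correlations. The
scoring chain therefore works entirely on significance scales:

- h(i,j) = 1 − p_adj(i,j), with p_adj the BH-FDR-corrected two-sided p-value
  of the partial correlation between i and j;
- h_G(g) = mean over j ≠ g of h(g,j), one value per gene per genotype;
- MPH(g) = h_H(g) − (h_P1(g) + h_P2(g))/2 and
  BPH(g) = h_H(g) − max(h_P1(g), h_P2(g)) per hybrid H.

By construction h ∈ [0,1], MPH/BPH ∈ [−1,1] and BPH ≤ MPH (max ≥ mean).
Rankings are by descending score with ties broken by ascending gene id.

### Shrinkage partial correlations

With n samples and p genes (typically n ≪ p) the empirical correlation
matrix is singular; we use the Schäfer–Strimmer shrinkage estimate
R* = (1−λ*) R + λ* I with the analytic intensity
λ* = Σ_{i≠j} V̂ar(r_ij) / Σ_{i≠j} r_ij² clipped to [0,1], then
ρ̂ = −scale(R*⁻¹). The estimator is computed on the raw time profiles; an
optional `detrend_time` flag removes per-time-point means first (at one
degree of freedom per time point), which is not the default because the
shared developmental trend is part of the profile the method correlates.

### Null p-values

Under the null of zero partial correlation the estimated coefficients follow
f(r) ∝ (1−r²)^((κ−3)/2), i.e. r² ~ Beta(1/2, (κ−1)/2), where κ acts as an
effective degree of freedom that absorbs the shrinkage. κ is fitted by
maximizing the likelihood over all off-diagonal entries (valid when most
pairs are null), with the search on log(κ−3) bounded in [e⁻¹², e³⁰]; r² is
clipped to 1−10⁻¹² inside the fit only. If the optimizer fails or runs to
the boundary, a caller-supplied fallback (max(4, n−1) in the scoring chain)
is used with a logged warning. Two-sided p-values come from the regularized
incomplete beta function; |r| = 1 maps to p = 0 and r = 0 to p = 1.

### ANOVA pre-filter

A balanced two-way fixed-effects ANOVA per gene
(`expression ~ genotype + time + genotype:time`, categorical factors,
vectorized over genes) yields p-values for the time main effect and the
interaction; each vector is BH-adjusted across genes and a gene is kept iff
either adjusted p ≤ α (default 0.3). The liberal default removes only genes
with nearly no time dependency. Degenerate cases: a constant gene has zero
effect and error sums of squares and receives p = 1 (excluded); a noiseless
perfect effect receives p = 0 (retained). The design must be balanced with
≥ 2 time points and ≥ 2 replicates per genotype×time cell — with a single
replicate the saturated interaction model leaves no error degrees of
freedom, so such designs are rejected rather than silently mis-tested.

### Over-representation machinery

For reference size a, test-set size t, gene-set size n and overlap k:
k_expected = n·t/a and p = P(X ≥ k), X ~ Hypergeometric(a, t, n). The tail is
accumulated in log space (gammaln + logsumexp), never as 1 − CDF, so p-values
near 0 keep full relative precision; k at or below the support minimum
returns exactly 1. A p-value is reported only when k > k_expected
(over-representation only); the enrichment fraction (k − k_expected)/k_expected
is reported whenever k_expected > 0. Sweeps evaluate the top-n gene sets on
the grid 0, step, 2·step, …, n_max (n_max appended if the grid misses it);
k is non-decreasing in n because the gene sets are nested. The BH step-up
adjustment is the standard p_(i)·m/i with a right-to-left cumulative minimum
and cap at 1; order-preserving and idempotent.

Resampling p-values redraw the gene set B times (default 1000) uniformly
without replacement from the reference and report
p_emp = #{k_b ≥ k_orig}/B, exactly as defined; a `plus_one` flag gives the
conservative (count+1)/(B+1) variant. Redrawing a uniform size-n set is
implemented by ranking i.i.d. uniform keys, chunked to bound memory;
deterministic given the seed.

The chromosome-stratified sweep splits each top-n gene set by chromosome
while keeping reference and test set fixed; ranked genes missing from the
catalog are dropped and counted (an error above a 5% fraction). The
partition identity Σ_c |gene set on c| = n − (unmapped in top n) holds
exactly. Pathway ORA filters pathways to those whose intersection with the
reference falls in the configured size range, assigns p = 1 to pathways
without a computed p-value so the BH adjustment and ranking are total, and
flags significance at the FDR threshold (default 0.05).

## The synthetic-data generator

The generator emulates the *statistical structure* the analysis assumes, not
any particular microarray platform:

- **Genome.** 2000 genes on 5 chromosomes with Arabidopsis-like map lengths
  (130, 75, 90, 80, 110 Kosambi cM); genes multinomial across chromosomes
  proportionally to length, positions uniform, `is_duplicated` flags
  Bernoulli(0.25). Gene ids are zero-padded so lexicographic order equals
  generation order (deterministic tie-breaking downstream).
- **Networks.** Built in partial-correlation space: precision K = I − γR.
  Parents share one sparse background graph (one edge per gene on average)
  with weak partial correlations ±U[0.05, 0.15]. Each hybrid independently
  adds `extra_hybrid_edges` (default 3) strong edges to every planted
  heterosis gene, sized to fill the gene's positive-definiteness budget
  (Σ_j ρ²_gj ≤ θ² with θ = 0.95 — the exact PD frontier for a star graph is
  Σρ² < 1), with partners drawn without reuse from non-planted genes so the
  planted stars are disjoint and the spectrum stays controlled. One global
  factor γ, shared by all four genotypes, enforces a smallest eigenvalue
  ≥ 0.05, and each precision matrix is rescaled to unit marginal variances
  (partial correlations are invariant under diagonal scaling; equal variances
  keep planted hub genes statistically comparable to the rest). An earlier
  diagonally-dominant construction (diag = row sum + 0.1) was measured and
  rejected: it caps every partial correlation near 1/degree, leaving the
  planted edges statistically invisible at realistic sample sizes — a
  degenerate study condition rather than a conservative one.
- **Expression.** Per genotype, n_timepoints × n_replicates i.i.d. draws from
  N(μ_t, K⁻¹) via Cholesky. The time-point means μ_t are per-gene trends,
  centred and normalized to sd `time_effect_sd` (default 0.3) across time
  points, *shared across all four genotypes*; a `flat_gene_fraction`
  (default 0.1) of genes receives no trend. The shared trend gives the ANOVA
  filter genuine signal (it retains trend genes and excludes flat ones) while
  cancelling exactly in the hybrid-vs-parent contrasts; its leakage into
  pairwise correlations (≈ τ²/√T per pair, ~0.03 at the defaults) is an
  order of magnitude below the sampling noise of the correlations.
- **QTL regions.** Half-open [start, end) intervals, non-overlapping per
  chromosome. Regions are centred on sampled heterosis genes until
  ≈ `capture_fraction` of them fall inside (remaining regions uniform);
  with capture 0 the placement ignores the planted genes entirely, making
  the overlap between planted genes and the test set exactly hypergeometric.
  Because the planted genes are spatially uniform, high capture fractions
  require many narrow regions (the canonical scenario uses 90 × 1 cM); the
  few-wide-regions geometry (default 7 × 8 cM) emulates the look of real QTL
  studies but can only capture what chance co-location allows. Clustering
  the planted genes spatially would reconcile the two at the cost of
  overdispersed (miscalibrated) null overlaps — a deliberate trade
  documented here and kept out of the default generator.
- **Pathways.** n_pathways member sets drawn from the analyzed genes with
  sizes uniform in the configured range; one designated pathway over-samples
  the planted set with per-gene odds `enrichment_odds` (default 10; odds 1 is
  indistinguishable from the rest by construction).

What passing tests on these data do **not** show: robustness to microarray
normalization artifacts, probe-level noise, unbalanced designs, temporal
autocorrelation of residuals, linkage disequilibrium, or spatially clustered
causal genes. The generator draws samples i.i.d. around the time trend, so
the partial-correlation estimand is exactly the planted GGM — real
time-series data are friendlier to no method and harsher to all.

## Canonical study conditions and problem sizes

`heteronet.study.simulate_study` bundles the conditions used by the analysis
drivers, the validation suite and `scripts/acceptance.py`: 2000 catalog
genes, 1000 analyzed, 100 planted heterosis genes, 3 extra hybrid edges, 30
samples per genotype (5 time points × 6 replicates), ANOVA α = 0.3, 90 QTL
regions of 1 cM at capture 0.8, sweep step 100, B = 1000 resamples, 80
pathways sized 10–1000 within the reference. Multi-seed checks use 20
simulations for recovery/stratification properties, 200 region redraws for
null calibration, and 100 draws for pathway false-discovery control. At
these sizes the full test suite runs in roughly ten minutes on one core;
the acceptance script takes under a minute.

## Numerical and design choices

- Gene-set/test-set membership uses exact set semantics; gene-set members
  outside the reference are dropped with a logged count.
- Zero-variance genes are excluded before partial-correlation estimation
  (the coefficient is undefined), with a logged warning and a record in the
  scoring result.
- Gene-model collapsing averages scores of models mapping to the same gene
  and counts dropped unmapped models.
- Pair-significance BH correction is applied jointly across all unordered
  pairs per genotype (per-gene stratification would break the symmetry of
  the h matrix).
- Frequency profiles tile each chromosome with half-open bins of fixed width
  (last bin truncated at the chromosome end); bins without catalog genes are
  undefined and excluded from the per-chromosome median. Default bin width
  2 cM in the drivers (1 cM in the CLI) — comparable to the region scale
  without over-smoothing.
- The pipeline manifest records configuration, artifact SHA-256 hashes,
  estimation diagnostics (λ, κ per genotype) and the planted ground truth;
  identical configurations produce bit-identical artifacts.
- Exit codes of the CLI: 0 success, 2 validation error, 3 numerical failure.

## Known limitations

- The κ fit assumes most pairs are null; datasets dominated by true edges
  would widen the fitted null and lose power (conservative, not invalid).
- Power is sharply nonlinear in the per-edge signal: with 30 samples the
  method sits near a detection cliff, which is faithful to how the BH
  plateau behaves but makes single-seed results noisy; multi-seed criteria
  absorb this.
- The ANOVA filter requires balanced designs; real unbalanced data would
  need a regression-based filter (out of scope here).
- `define_qtl_regions` guarantees non-overlap by rejection sampling; extreme
  parameter combinations (regions nearly tiling a chromosome) can fail with
  a clear error rather than degrade silently.
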