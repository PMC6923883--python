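# Methods

## The skewness statistic

For gene g over a cohort of n patients, the package computes

    S_g = sign(m3) * |m3|^(1/3) / sigma_g,
    m3  = (1/(n-1)) * sum_x (g_x - mu_g)^3,

with sigma_g the (n−1)-denominator sample standard deviation.  The signed
real cube root is our resolution of the cube root of a negative third
moment: it preserves the sign of the asymmetry and is continuous through
zero.  Using (n−1) in both the third moment and the standard deviation
keeps the two estimators on the same footing.  The statistic is exactly
invariant under positive affine maps g → a·g + c and antisymmetric under
g → −g; both properties are enforced by tests at 1e−10 and the whole
statistic is checked against a literal loop evaluation at 1e−12.

An `unbiased` flag multiplies m3 by n/(n−2) before the cube root.  The
induced multiplicative change in S_g is (n/(n−2))^(1/3) − 1 ≈ 2/(3n):
0.13% at n = 500, 0.22% at n = 300.  The default is the uncorrected
statistic; at cohort scale the two are interchangeable.

A caution that matters for interpreting per-gene values: because the cube
root inflates small third moments, the *null* magnitude of S_g is not
small.  For Gaussian data m3 ≈ N(0, 6σ⁶/n), so |S_g| has null scale
(6/n)^(1/6)·E|z|^(1/3) ≈ 0.41 at n = 500.  Individual |S_g| values should
therefore be read against that scale; cohort-level summaries (the gene
split, skew differences between cohorts) are the intended use.

Genes with zero variance get an undefined (NaN) skewness and are excluded
from all downstream summaries rather than aborting a run; exact zeros count
as positive in the gene split (configurable), since exactly symmetric
samples are measure-zero events in practice.

## Gene splitting and its convergence in sample size

The gene split of a cohort is the fraction of genes with S_g < 0.  Splits
from different platforms are compared by Welch's unequal-variance t-test on
the per-dataset fractions, with Shapiro-Wilk p-values reported per group as
a normality sanity check (both via scipy).

Sensitivity to sample size is assessed by recomputing the split on random
subsamples (without replacement — subcohorts, not bootstrap) over a size
grid, 25 repeats per size by default, 10 log-spaced sizes from 20 to the
cohort size.  The mean split per size forms a sequence s_n assumed to decay
exponentially to its limit:

    s_n = a·exp(−b·n) + L,   rate of convergence C = exp(−b) ∈ (0,1),
    relative error E_n = (s_n − L)/L  (undefined when |L| < 1e−8).

(a, b, L) are least-squares estimates with b constrained positive.
Initialization: L₀ = s_last, b₀ from an ordinary least-squares fit of
log|s_n − L₀| on n, a₀ from its intercept; five starts (the data-driven one
plus four jittered copies) guard against local minima, and points are
sorted by n first so permuted input yields the identical fit.  Noiseless
synthetic series are recovered to 1e−6; at noise sd 0.005 over a 12-point
grid the limit lands within 0.02 of truth in ≥ 90% of replicates.  The
sub-linear (power-law) alternative decay model is out of scope.

## Skew-difference mixture and categories

For two cohorts, ΔS_g = S_g(first) − S_g(second) on the gene intersection
(exact identifier match, no aliasing).  ΔS distributions are typically
tri-modal, so genes are clustered with a univariate Gaussian mixture in
which each component has its own variance.  For each K = 1..10 the mixture
is fitted by EM and scored with BIC = 2·logL − p·ln(n), p = 3K − 1
(K−1 free weights, K means, K variances); the selected K maximizes BIC.

EM numerical choices: k-means++ seeding refined by Lloyd iterations to a
converged 1-D k-means partition; 10 restarts executed as one vectorized
batch; convergence at a relative log-likelihood change of 1e−6 with at most
500 iterations; a variance floor of 1e−6 times the data variance prevents
single-point collapse, and restarts that collapse anyway are discarded and
redrawn.  The restarts follow the emEM two-phase schedule: every restart
runs a 25-iteration burn-in, then the best-likelihood restart continues to
full convergence.  Running all ten restarts to full convergence is
substantially slower for the deliberately overfitted K ≥ 5 candidates
(redundant components creep for hundreds of iterations) and does not change
the BIC landscape on separated data; the K = 1 fit is closed-form.  The fit
is cross-checked against scikit-learn's GaussianMixture in the test suite.

Categories: components ordered by mean map to `<` (lowest), `>` (highest)
and `~` (everything between); each gene takes the category of its
maximum-posterior component.  The pipeline default forces the K = 3 fit
for categorization (the three-category reading) regardless of the BIC
winner, which is retained alongside every per-K fit so either convention is
available; K < 3 fits emit only the representable categories with a
warning.

## Over-representation analysis

Within each category, each gene set is tested with the upper-tail
hypergeometric probability P(X ≥ k) for X ~ Hypergeom(N, K_set, m), where
the universe N is the set of genes with a defined ΔS in the comparison —
the sampling frame from which the categories were drawn, not the whole
genome.  Sets are intersected with the universe first; empty intersections
are skipped.  BH correction runs within each (category, module) stratum,
significance at adjusted p < 0.05.  The top-10 summary ranks sets by
adjusted p (ties by raw p, then name — fully deterministic) and counts
module labels among the first ten.  Module labels (e.g. Immune System,
Metabolism, Translation) are consumed as input annotation, not recomputed.

## Tail detection

Genes with defined non-zero skewness are split on the side sign(S_g)
points to:

* **quantile**: the ⌈q·n⌉ most extreme samples (default q = 0.1), ties at
  the cut broken by sample id, so the tail area — and hence the two-group
  test's sample sizes — is constant across genes;
* **gaussian**: the central mode is located robustly by the median with
  scale 1.4826·MAD (a deterministic robust alternative to fitting the mode
  by EM, which is available upstream via `mixcat` if wanted), and samples
  beyond z = 2.5 robust units on the skew side form the tail.

Quantile splitting is the pipeline default; it avoids the degenerate cases
of density-based splitting (e.g. heavy central ties, zero MAD) at the cost
of forcing a tail even for weakly skewed genes.  Genes with tails smaller
than 5 samples are excluded from downstream testing.

## Tail-stratified differential methylation

Beta-values are transformed to M-values, M = log2(β/(1−β)) with β clipped
to [1e−6, 1−1e−6]; M-values have far more homogeneous variance across the
methylation range, which rank and location tests reward.

Each probe of each tailed gene is tested tail vs non-tail with the
two-sided Wilcoxon rank-sum (Mann-Whitney) test — the two groups are
unpaired and of unequal size, so a signed-rank design does not apply.  The
null is exact (full enumeration, via scipy) when the smaller group has at
most 25 samples and the data are tie-free, and the normal approximation
with continuity and tie correction otherwise; exactness is verified against
an in-repo enumeration oracle for all group-size pairs with total ≤ 12, and
the asymptotic branch's type-I error is calibration-checked at the study's
50-vs-450 split.  BH correction is applied jointly across all tested probes
of a cohort.

Gene-level summary: per gene, the minimum adjusted p over its probes, the
fraction of its probes significant at p < 0.01, and the mean ΔM (tail mean
M minus non-tail mean M) over *significant* probes, overall and per region
(Promoter = TSS1500 incl. TSS200; UTR = 5'/3' UTRs; Body = body plus first
exon; "All" is their union).  Genes are ranked by (min adjusted p
ascending, fraction significant descending, gene id), and the top N = 500
enter the downstream analyses:

* **quadrants**: counts by (sign S_g, sign ΔM) per region; exact zeros are
  excluded from quadrants and counted separately; region pairs are compared
  per quadrant with two-sided Fisher exact tests on quadrant-vs-rest 2×2
  tables;
* **correlation**: Pearson r of (S_g, ΔM_region) with the Fisher-z 95%
  interval tanh(atanh(r) ± 1.96/√(N−3)); degenerate (|r| = 1) and
  zero-variance inputs are flagged or rejected;
* **robustness**: the correlation recomputed over a grid of top-N values
  (default 100..500 step 25), optionally smoothed with a centered rolling
  mean (default window 3; window 1 is the raw series) — a deliberately
  simple replacement for presentation-grade spline smoothing;
* **cross-cohort selection**: the intersection of all cohorts' significant
  genes plus each cohort's top 1269 significant genes outside the
  intersection (the default matches equal-sized per-cohort comparison
  lists).

Whether "most significant probe" ranking should use raw or adjusted p is
ambiguous in principle; adjusted p is used, which also makes the ranking
invariant to probe-universe size at fixed ordering.  No causal direction
between methylation and expression asymmetry is claimed anywhere.

## Synthetic cohorts

The generator encodes the hypothesis the analysis probes: tails arise from
a shifted minority patient subgroup.  Per gene, n−round(π·n) samples come
from Normal(μ₀, σ₀) on the log2 scale and a tail subgroup of fraction π
from Normal(μ₀ + direction·δ, σ₀).  Expression is generated directly on
the log2 scale with no count model, because the analysis consumes log2
matrices and the statistic is scale-invariant.  The closed-form skewness of
this two-component model,

    S(π, d) = d·(π(1−π)(1−2π))^(1/3) / sqrt(1 + π(1−π)d²),   d = δ/σ₀,

is exposed as `expected_skewness` and used to size planted effects.  Note
it is *not* monotone in π over (0, 0.5): it peaks near π ≈ 0.15 for d = 3
and vanishes at π = 0.5 where the mixture is symmetric — monotonicity
holds, and is tested, on the small-π regime.

Defaults are study-scale: 500 samples, π = 0.1, δ = 3σ₀, baseline
Normal(8, 1) log2 units, half the genes planted negative.  Methylation
emulates a 450k-style array: 12 probes per gene with regions drawn as
Promoter 0.35 / UTR 0.20 / Body 0.45, probe baselines Normal(0, 2) in
M-units, within-probe noise sd 0.5.  Tail membership is an independent
draw per gene; for the configurable fraction of *linked* genes, the same
patient subgroup that forms the expression tail also receives a planted
M-value shift on probes of the configured regions (promoter −1 by
default), with sign opposite to the skew direction — hypermethylation
accompanies down-shifted tails and vice versa, the negative-correlation
regime.

When a target correlation ρ between skewness and the planted shift is
requested, shifts are drawn as ΔM_g = scale·(ρ·z_S + √(1−ρ²)·z_g), where
z_S is the standardized *realized* sample skewness of the linked genes and
scale is set so the positive-direction group mean equals the configured
shift.  Planting against realized (not expected) skewness makes the
planted correlation hold exactly for the quantities the pipeline actually
measures; the remaining attenuation is only the tail-estimation impurity
and ΔM measurement noise.  At study scale (2,000 genes × 500 samples, 20%
linked) the pipeline recovers ρ = −0.8 within ±0.1, ≥ 80% of linked genes
reach adjusted p < 0.01 and ≤ 5% of unlinked genes do.

All randomness derives from a single seed through spawned per-gene
sub-streams, so cohorts are bit-identical across runs and genes are
statistically independent.  What the generator does *not* emulate — array
chemistry, probe cross-hybridization, read counts, batch structure,
gene-gene correlation, tumor purity — bounds what passing tests show:
recovery results demonstrate the pipeline's correctness under its own
model, not robustness to those real-data complications.

## Problem sizes and determinism

Test and reference computations use 5,000-point mixture benchmarks, 100
convergence replicates, 2,000-probe null calibrations and one
2,000-gene × 500-sample linked cohort — sizes at which every planted
effect is comfortably identified while the full suite runs in a few
minutes on one CPU.  Every stochastic step takes an explicit seed; the
pipeline report records the seed and per-stage counts, and rerunning a
fixed config reproduces byte-identical artifacts.
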