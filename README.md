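# skewcohort

Analysis of gene-expression **distribution asymmetry** across patient
cohorts, and of its relationship to DNA methylation.

Most differential analyses compare the *centers* of expression
distributions.  `skewcohort` instead quantifies their *tails*: when a
minority subgroup of patients shifts a gene's expression, the cohort-wide
distribution becomes skewed, and the sign and magnitude of that skewness
carry information that mean- and variance-based statistics miss.  The
package is aimed at computational biologists working with bulk expression
matrices (microarray or RNA-seq, log2 scale) and, optionally, matched
Illumina 450k-style methylation data.

## The statistic

For a gene g observed in a cohort X of n = |X| patients with values g_x,

    S_g(X) = (1 / sigma_g) * cbrt( (1 / (n - 1)) * sum_x (g_x - mu_g)^3 )

the signed real cube root of the third central moment, divided by the
sample standard deviation.  Taking the cube root before standardizing keeps
the statistic on the scale of a z-score, so it separates wide, mildly
asymmetric distributions from narrow, strongly asymmetric ones; it is
invariant under g -> a*g + c for a > 0 and antisymmetric under sign flips.
An optional small-sample correction multiplies the third moment by
n / (n - 2); at n = 500 this changes S_g by about 0.13%, i.e. it is
negligible at cohort scale.

Around the statistic the package provides:

* **Gene splitting** — the fraction of genes with negative skewness in a
  cohort, with Welch/Shapiro-Wilk comparisons of splits across platforms
  (`skewcore`), and its sample-size sensitivity via subsampling plus an
  exponential convergence fit s_n = a·exp(−b·n) + L with rate C = exp(−b)
  and relative errors E_n = (s_n − L)/L (`convergence`).
* **Skew-difference categorization** — per-gene differences of skewness
  between two cohorts, clustered with a variable-variance univariate
  Gaussian mixture; the number of components is chosen by maximizing
  BIC = 2·logL − p·ln(n) over K = 1..10, and mean-ordered components map to
  the categories `<` / `~` / `>` (`mixcat`).
* **Pathway over-representation** — upper-tail hypergeometric tests of gene
  sets within each skew category, BH-corrected within (category, module)
  strata, with a top-10 per-module summary (`enrich`).
* **Tail detection** — per-gene partition of patients into tail vs non-tail
  by quantile splitting (fixed tail area) or Gaussian splitting (robust
  central-mode fit, threshold in z-units) (`tailsplit`).
* **Methylation link** — per-probe Wilcoxon rank-sum tests of tail vs
  non-tail M-values (M = log2(beta/(1−beta))), joint BH correction,
  gene-level ranking, top-N selection, region-stratified
  (Promoter/UTR/Body) quadrant and Pearson-correlation analyses with
  Fisher-z intervals, robustness sweeps over N, and cross-cohort
  intersection/unique gene selection (`methlink`).
* **Synthetic cohorts** — a generator that plants per-gene tail subgroups
  of controllable fraction and shift (hence controllable skewness) and,
  for "linked" genes, matched region-specific M-value shifts carried by
  the same patients, with full ground truth for recovery tests
  (`synthdata`).

## Worked example

```python
import numpy as np
from skewcohort import synthdata, skewcore, tailsplit, methlink

cfg = synthdata.CohortConfig(
    n_genes=500, n_samples=300, linked_fraction=0.2,
    methyl_shift={"Promoter": -1.0}, target_corr=-0.8, seed=42,
)
cohort = synthdata.generate_cohort(cfg)

skew = skewcore.compute_skewness(cohort.expression)
split = skewcore.gene_split(skew)
print(f"gene split: {split.fraction_negative:.3f} negative / "
      f"{split.fraction_positive:.3f} positive over {split.n_genes} genes")
print(f"bias correction at n=300: {skewcore.correction_magnitude(300) * 100:.3f}%")

tails = tailsplit.split_cohort(cohort.expression, skew, method="quantile", q=0.1)
probes = methlink.probe_dm_test(cohort.methylation, tails, cohort.annotation)
summaries = methlink.summarize_genes(probes, skew, alpha=0.01)
top = methlink.select_top_genes(summaries, n=100)
res = methlink.correlation_with_ci(top, "Promoter")
print(f"promoter skewness-vs-dM correlation on top {res.n} genes: "
      f"r = {res.r:.3f} (95% CI {res.ci_low:.3f} to {res.ci_high:.3f})")
```

prints

```
gene split: 0.488 negative / 0.512 positive over 500 genes
bias correction at n=300: 0.223%
promoter skewness-vs-dM correlation on top 85 genes: r = -0.842 (95% CI -0.895 to -0.767)
```

Half the genes were planted with negative skew, so the split sits near 0.5.
The 20% of genes whose tail patients also carry a planted promoter
methylation shift dominate the most significant differentially methylated
genes, and the negative correlation between skewness and methylation change
planted at −0.8 is recovered on the top-ranked genes (85 of the top 100
have a significant promoter probe).

## Command line

Every stage is also a subcommand of the `skewcohort` CLI:

```
skewcohort synth --outdir cohort/ --seed 7
skewcohort skew --in cohort/expression.tsv --out skew.tsv
skewcohort split --skew skew.tsv
skewcohort diff --first a_skew.tsv --second b_skew.tsv --out diff.tsv
skewcohort categorize --diffs diff.tsv --seed 7 --out categories.tsv
skewcohort enrich --categories categories.tsv --gmt sets.gmt --out enrich.tsv
skewcohort tails --in cohort/expression.tsv --skew skew.tsv --out tails.tsv
skewcohort methlink --meth cohort/methylation.tsv --ann cohort/probes.tsv \
    --tails tails.tsv --skew skew.tsv --outdir meth_out/
skewcohort converge --in cohort/expression.tsv --seed 7 --out fit.json
skewcohort run --config pipeline.yaml
```

Matrices are TSV (first column feature id, header sample ids), gene sets
are GMT, nested reports are JSON.  `skewcohort run` drives the whole
pipeline from one YAML config and writes a run report with per-stage
counts; a fixed config and seed reproduces byte-identical artifacts.

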