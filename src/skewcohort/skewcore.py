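"""Shift- and scale-invariant skewness of gene expression distributions.

The central statistic is the signed cube root of the (n-1)-denominator third
central moment, divided by the sample standard deviation:

    S_g = sign(m3) * |m3|**(1/3) / sigma_g,
    m3  = (1/(n-1)) * sum((x - mu_g)**3)

Taking the cube root before dividing by sigma keeps the statistic on the same
"scale" as a standard deviation, so it separates wide, mildly asymmetric
distributions from narrow, strongly asymmetric ones.  An optional small-sample
bias correction multiplies m3 by n/(n-2) before the cube root.

Derived summaries: the cohort-level *gene split* (fraction of genes with
negative skewness), cross-cohort *skew differences*, platform comparisons of
gene splits (Welch's t with Shapiro-Wilk normality checks), an FPKM->TPM
normalization helper, and a skewness-vs-mean independence diagnostic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

PLATFORMS = ("microarray", "rnaseq", "other")


@dataclass
class ExpressionMatrix:
    """Gene x sample log2 expression values.

    ``data`` is indexed by gene id with sample ids as columns.  ``platform``
    tags the profiling technology (microarray / rnaseq / other).
    """

    data: pd.DataFrame
    platform: str = "other"

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise ValueError(f"platform must be one of {PLATFORMS}, got {self.platform!r}")
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate gene id: {dup!r}")
        if self.data.columns.duplicated().any():
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        values = self.data.to_numpy(dtype=float)
        if values.size and not np.all(np.isfinite(values)):
            raise ValueError("expression matrix contains non-finite values")

    @property
    def gene_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class GeneSplit:
    """Fractions of genes with negative vs positive skewness in one cohort."""

    fraction_negative: float
    fraction_positive: float
    n_genes: int
    dataset: str = ""


@dataclass
class SplitComparison:
    """Welch's t-test on two groups of gene-split fractions, with per-group
    Shapiro-Wilk normality p-values supporting the t-test's assumption."""

    t_statistic: float
    p_value: float
    shapiro_p_a: float
    shapiro_p_b: float
    n_a: int
    n_b: int


def signed_cbrt(x):
    """Real signed cube root: sign(x) * |x|**(1/3)."""
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.abs(x) ** (1.0 / 3.0)


def _as_frame(matrix) -> pd.DataFrame:
    return matrix.data if isinstance(matrix, ExpressionMatrix) else pd.DataFrame(matrix)


def compute_skewness(matrix, unbiased: bool = False) -> pd.DataFrame:
    """Per-gene skewness table.

    Returns a DataFrame indexed by gene with columns ``skewness``, ``mean``,
    ``sd`` (n-1 denominator) and ``n``; ``unbiased`` is recorded in
    ``DataFrame.attrs``.  Zero-variance genes get NaN skewness (they are
    excluded from downstream splits) and are counted in the log.

    Raises ``ValueError`` with fewer than 3 samples.
    """
    frame = _as_frame(matrix)
    n = frame.shape[1]
    if n < 3:
        raise ValueError(f"skewness needs at least 3 samples, got {n}")
    values = frame.to_numpy(dtype=float)
    mu = values.mean(axis=1)
    centered = values - mu[:, None]
    sd = np.sqrt((centered**2).sum(axis=1) / (n - 1))
    m3 = (centered**3).sum(axis=1) / (n - 1)
    if unbiased:
        m3 = m3 * n / (n - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        skew = signed_cbrt(m3) / sd
    zero_var = sd == 0
    skew[zero_var] = np.nan
    if zero_var.any():
        log.info("compute_skewness: %d zero-variance gene(s) reported as undefined", int(zero_var.sum()))
    out = pd.DataFrame(
        {"skewness": skew, "mean": mu, "sd": sd, "n": n},
        index=frame.index,
    )
    out.attrs["unbiased"] = bool(unbiased)
    return out


def correction_magnitude(n: int) -> float:
    """Multiplicative change the n/(n-2) third-moment correction induces on
    the skewness statistic: (n/(n-2))**(1/3) - 1.  Requires n > 2."""
    if n <= 2:
        raise ValueError(f"correction requires n > 2, got {n}")
    return (n / (n - 2.0)) ** (1.0 / 3.0) - 1.0


def gene_split(table: pd.DataFrame, dataset: str = "", zero_as_positive: bool = True) -> GeneSplit:
    """Fraction of genes with negative (vs positive) skewness.

    Genes with undefined (NaN) skewness are excluded.  Exact zeros count as
    positive by default (few genes are exactly symmetric; configurable).
    """
    skew = table["skewness"].to_numpy(dtype=float)
    defined = skew[np.isfinite(skew)]
    if defined.size == 0:
        raise ValueError("gene_split: no genes with defined skewness")
    if zero_as_positive:
        neg = int((defined < 0).sum())
    else:
        neg = int((defined <= 0).sum())
    frac_neg = neg / defined.size
    return GeneSplit(
        fraction_negative=frac_neg,
        fraction_positive=1.0 - frac_neg,
        n_genes=int(defined.size),
        dataset=dataset,
    )


def skew_difference(
    first: pd.DataFrame,
    second: pd.DataFrame,
    first_name: str = "first",
    second_name: str = "second",
) -> pd.DataFrame:
    """Signed per-gene skew difference, first minus second, on the gene-id
    intersection.  Positive values mean greater skew in the first cohort."""
    shared = first.index.intersection(second.index)
    if len(shared) == 0:
        raise ValueError("skew_difference: empty gene-id intersection")
    delta = first.loc[shared, "skewness"] - second.loc[shared, "skewness"]
    out = pd.DataFrame({"delta": delta.to_numpy(dtype=float)}, index=shared)
    out = out[np.isfinite(out["delta"])]
    out.attrs["first"] = first_name
    out.attrs["second"] = second_name
    return out


def compare_splits(splits_a: list[GeneSplit], splits_b: list[GeneSplit]) -> SplitComparison:
    """Welch's unequal-variance t-test on fraction_negative values from two
    platform groups, with Shapiro-Wilk normality p-values per group."""
    a = np.array([s.fraction_negative for s in splits_a], dtype=float)
    b = np.array([s.fraction_negative for s in splits_b], dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("compare_splits: each group needs at least 3 gene splits")

    def _shapiro(x: np.ndarray) -> float:
        if np.ptp(x) == 0:
            return np.nan  # constant group: normality untestable
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return float(stats.shapiro(x).pvalue)

    if np.var(a) == 0 and np.var(b) == 0:
        # degenerate: no variance anywhere -> no evidence of a difference
        t_stat = 0.0
        p_val = 1.0
    else:
        res = stats.ttest_ind(a, b, equal_var=False)
        t_stat, p_val = float(res.statistic), float(res.pvalue)
    return SplitComparison(
        t_statistic=t_stat,
        p_value=p_val,
        shapiro_p_a=_shapiro(a),
        shapiro_p_b=_shapiro(b),
        n_a=a.size,
        n_b=b.size,
    )


def fpkm_to_tpm(matrix: ExpressionMatrix, input_is_log2: bool = False) -> ExpressionMatrix:
    """Convert FPKM to TPM per sample: TPM_g = FPKM_g / sum_g FPKM_g * 1e6.

    Conversion runs on the linear scale; with ``input_is_log2`` values are
    unlogged first and relogged after.  A sample whose FPKM total is zero is
    an error, as is any negative linear value.
    """
    frame = matrix.data
    linear = np.power(2.0, frame.to_numpy(dtype=float)) if input_is_log2 else frame.to_numpy(dtype=float)
    if (linear < 0).any():
        raise ValueError("fpkm_to_tpm: negative FPKM values")
    totals = linear.sum(axis=0)
    if (totals == 0).any():
        bad = frame.columns[np.where(totals == 0)[0][0]]
        raise ValueError(f"fpkm_to_tpm: sample {bad!r} has zero total FPKM")
    tpm = linear / totals * 1e6
    out = np.log2(tpm) if input_is_log2 else tpm
    return ExpressionMatrix(
        data=pd.DataFrame(out, index=frame.index, columns=frame.columns),
        platform=matrix.platform,
    )


def skew_vs_mean_diagnostic(table: pd.DataFrame, n_bins: int = 10) -> pd.DataFrame:
    """Pearson correlation of (mean, skewness) within bins of mean expression.

    Genes are binned by equal-width intervals of the per-gene mean; empty bins
    are collapsed (dropped with a warning).  The overall correlation across
    all genes is stored in ``attrs['overall_r']`` (NaN when undefined, e.g.
    constant skewness).
    """
    sub = table[np.isfinite(table["skewness"])]
    mu = sub["mean"].to_numpy(dtype=float)
    sk = sub["skewness"].to_numpy(dtype=float)
    if np.ptp(mu) == 0 or np.ptp(sk) == 0:
        overall = np.nan
    else:
        overall = float(stats.pearsonr(mu, sk).statistic)
    bins = pd.cut(mu, bins=n_bins, duplicates="drop")
    rows = []
    n_empty = 0
    for interval, grp in sub.groupby(bins, observed=False):
        if len(grp) == 0:
            n_empty += 1
            continue
        gmu = grp["mean"].to_numpy(dtype=float)
        gsk = grp["skewness"].to_numpy(dtype=float)
        if len(grp) < 2 or np.ptp(gmu) == 0 or np.ptp(gsk) == 0:
            r = np.nan
        else:
            r = float(stats.pearsonr(gmu, gsk).statistic)
        rows.append({"bin_left": interval.left, "bin_right": interval.right, "n_genes": len(grp), "r": r})
    if n_empty:
        warnings.warn(f"skew_vs_mean_diagnostic: {n_empty} empty bin(s) collapsed", stacklevel=2)
    out = pd.DataFrame(rows)
    out.attrs["overall_r"] = overall
    return out
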