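"""Link expression-distribution tails to differential DNA methylation.

Per methylation probe, tail and non-tail patients (from the expression tail
split of the probe's gene) are compared with a two-sided Wilcoxon rank-sum
test on M-values, BH-corrected jointly across all tested probes.  Genes are
then ranked by the adjusted p of their most significant probe (ties by the
fraction of their probes significant at p < 0.01, then gene id); the top-N
genes enter region-stratified quadrant and correlation analyses relating
per-gene skewness to the mean methylation change (dM = mean M in tail minus
mean M in non-tail) of significant probes.

M-values are log2 odds of methylation, M = log2(beta / (1 - beta)); they are
preferred over beta-values for rank and location tests because their variance
is far less dependent on the methylation level.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tailsplit import TailAssignment

log = logging.getLogger(__name__)

REGIONS = ("Promoter", "UTR", "Body")
ALL_REGIONS = ("All",) + REGIONS

#: largest min-group size for which the exact rank-sum null is enumerated
EXACT_LIMIT = 25


@dataclass
class MethylationMatrix:
    """Probe x sample M-values (log2 odds of methylation)."""

    data: pd.DataFrame
    origin: str = "native-M"  # "beta-converted" | "native-M"

    def __post_init__(self) -> None:
        if self.origin not in ("beta-converted", "native-M"):
            raise ValueError(f"unknown origin {self.origin!r}")
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate probe id: {dup!r}")
        values = self.data.to_numpy(dtype=float)
        if values.size and not np.all(np.isfinite(values)):
            raise ValueError("methylation matrix contains non-finite values")


@dataclass
class CorrelationResult:
    """Pearson correlation of (skewness, dM) with its Fisher-z 95% CI."""

    region: str
    n: int
    r: float
    ci_low: float
    ci_high: float
    degenerate: bool = False


def validate_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    """Probe annotation: index probe_id, columns gene_id and region
    (Promoter / UTR / Body); each probe maps to exactly one gene and region."""
    if annotation.index.duplicated().any():
        dup = annotation.index[annotation.index.duplicated()][0]
        raise ValueError(f"probe annotated more than once: {dup!r}")
    bad = set(annotation["region"]) - set(REGIONS)
    if bad:
        raise ValueError(f"unknown probe region(s): {sorted(bad)}")
    return annotation


def beta_to_mvalue(beta: pd.DataFrame, epsilon: float = 1e-6) -> MethylationMatrix:
    """Logit transform beta-values to M-values: M = log2(b / (1 - b)),
    with b clipped to [epsilon, 1 - epsilon].  Values outside [0, 1] error."""
    values = beta.to_numpy(dtype=float)
    if np.any(values < 0) or np.any(values > 1):
        raise ValueError("beta-values must lie in [0, 1]")
    clipped = np.clip(values, epsilon, 1.0 - epsilon)
    m = np.log2(clipped / (1.0 - clipped))
    return MethylationMatrix(
        data=pd.DataFrame(m, index=beta.index, columns=beta.columns),
        origin="beta-converted",
    )


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value for two unpaired
    groups: exact null enumeration when the smaller group has <= EXACT_LIMIT
    observations and the data are tie-free, otherwise the normal
    approximation with continuity and tie correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if min(len(x), len(y)) <= EXACT_LIMIT and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.pvalue)


def probe_dm_test(
    meth: MethylationMatrix,
    tails: dict[str, TailAssignment],
    annotation: pd.DataFrame,
    min_tail: int = 5,
) -> pd.DataFrame:
    """Tail-vs-non-tail rank-sum test on M-values for every probe of every
    gene with a tail assignment.

    Genes whose tail is smaller than ``min_tail`` are skipped (and counted in
    the log), as are probes with fewer than 2 values in either group.  BH
    correction is applied jointly across all tested probes.  Columns:
    probe, gene, region, delta_m (mean tail M minus mean non-tail M),
    n_tail, n_nontail, p, p_adj.
    """
    annotation = validate_annotation(annotation)
    frame = meth.data
    values = frame.to_numpy(dtype=float)
    probe_pos = {p: i for i, p in enumerate(frame.index)}
    sample_pos = {s: i for i, s in enumerate(frame.columns)}
    by_gene = annotation.groupby("gene_id").groups
    n_small, n_skipped_probes = 0, 0
    # gather per-probe slices, grouped by (n_tail, n_nontail) so that every
    # equal-sized batch goes through one vectorized rank-sum call
    batches: dict[tuple[int, int], dict] = {}
    for gene, assignment in tails.items():
        if len(assignment.tail) < min_tail:
            n_small += 1
            continue
        probes = by_gene.get(gene)
        if probes is None:
            continue
        probes = [p for p in probes if p in probe_pos]
        if not probes:
            continue
        tail_idx = [sample_pos[s] for s in assignment.tail if s in sample_pos]
        non_idx = [sample_pos[s] for s in assignment.nontail if s in sample_pos]
        if len(tail_idx) < 2 or len(non_idx) < 2:
            n_skipped_probes += len(probes)
            continue
        key = (len(tail_idx), len(non_idx))
        batch = batches.setdefault(key, {"x": [], "y": [], "probe": [], "gene": []})
        rows_idx = [probe_pos[p] for p in probes]
        batch["x"].append(values[np.ix_(rows_idx, tail_idx)])
        batch["y"].append(values[np.ix_(rows_idx, non_idx)])
        batch["probe"].extend(probes)
        batch["gene"].extend([gene] * len(probes))
    if n_small:
        log.info("probe_dm_test: %d gene(s) skipped (tail < %d)", n_small, min_tail)
    if n_skipped_probes:
        log.info("probe_dm_test: %d probe(s) skipped (fewer than 2 values in a group)", n_skipped_probes)
    parts = []
    for (n_tail, n_non), batch in batches.items():
        xm = np.vstack(batch["x"])
        ym = np.vstack(batch["y"])
        if min(n_tail, n_non) > EXACT_LIMIT:
            pvals = stats.mannwhitneyu(
                xm, ym, alternative="two-sided", method="asymptotic",
                use_continuity=True, axis=1,
            ).pvalue
        else:
            pvals = np.array([rank_sum_test(xm[i], ym[i]) for i in range(xm.shape[0])])
        parts.append(
            pd.DataFrame(
                {
                    "probe": batch["probe"],
                    "gene": batch["gene"],
                    "region": annotation.loc[batch["probe"], "region"].to_numpy(),
                    "delta_m": xm.mean(axis=1) - ym.mean(axis=1),
                    "n_tail": n_tail,
                    "n_nontail": n_non,
                    "p": pvals,
                }
            )
        )
    if not parts:
        return pd.DataFrame(
            columns=["probe", "gene", "region", "delta_m", "n_tail", "n_nontail", "p", "p_adj"]
        )
    results = pd.concat(parts, ignore_index=True)
    results["p_adj"] = multipletests(results["p"], method="fdr_bh")[1]
    return results


def summarize_genes(
    results: pd.DataFrame,
    skew: pd.DataFrame,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Gene-level aggregation of probe results, in ranking order.

    Per gene: ``min_p_adj`` (most significant probe), ``frac_significant``
    (fraction of its probes with adjusted p < alpha), per-region mean
    delta_m over *significant* probes (columns ``delta_m_All``,
    ``delta_m_Promoter``, ...; NaN when no probe in the region is
    significant), and the gene's skewness.  Rows are ordered by
    (min_p_adj ascending, frac_significant descending, gene id).
    """
    if results.empty:
        raise ValueError("summarize_genes: empty probe results")
    grouped = results.groupby("gene")
    out = grouped.agg(
        min_p_adj=("p_adj", "min"),
        n_probes=("probe", "size"),
    )
    out["frac_significant"] = grouped.apply(
        lambda g: float((g["p_adj"] < alpha).mean()), include_groups=False
    )
    sig = results[results["p_adj"] < alpha]
    out["delta_m_All"] = sig.groupby("gene")["delta_m"].mean()
    for region in REGIONS:
        out[f"delta_m_{region}"] = (
            sig[sig["region"] == region].groupby("gene")["delta_m"].mean()
        )
    out["skewness"] = skew["skewness"].reindex(out.index)
    out = out.reset_index().sort_values(
        ["min_p_adj", "frac_significant", "gene"],
        ascending=[True, False, True],
        kind="mergesort",
    )
    out = out.set_index("gene", drop=False)
    out.index.name = None
    return out


def select_top_genes(summaries: pd.DataFrame, n: int = 500) -> pd.DataFrame:
    """First ``n`` genes in summary (ranking) order; all of them, with a
    warning, when fewer are available."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(summaries) < n:
        warnings.warn(
            f"select_top_genes: only {len(summaries)} gene(s) available (requested {n})",
            stacklevel=2,
        )
    return summaries.head(n)


QUADRANTS = (
    ("S<0", "dM>0"),
    ("S>0", "dM>0"),
    ("S<0", "dM<0"),
    ("S>0", "dM<0"),
)


def _quadrant_counts(s: np.ndarray, dm: np.ndarray) -> tuple[dict, int]:
    on_axis = int(((s == 0) | (dm == 0)).sum())
    keep = (s != 0) & (dm != 0)
    s, dm = s[keep], dm[keep]
    counts = {
        ("S<0", "dM>0"): int(((s < 0) & (dm > 0)).sum()),
        ("S>0", "dM>0"): int(((s > 0) & (dm > 0)).sum()),
        ("S<0", "dM<0"): int(((s < 0) & (dm < 0)).sum()),
        ("S>0", "dM<0"): int(((s > 0) & (dm < 0)).sum()),
    }
    return counts, on_axis


@dataclass
class QuadrantReport:
    """Per-region quadrant counts and pairwise-region Fisher exact tests."""

    counts: pd.DataFrame  # index region, columns quadrant labels + n, on_axis
    fisher: pd.DataFrame  # region_a, region_b, quadrant, odds_ratio, p


def quadrant_analysis(top: pd.DataFrame, regions=ALL_REGIONS) -> QuadrantReport:
    """Classify top genes into quadrants by (sign of skewness, sign of dM)
    per region, and test each region pair for quadrant-composition
    differences with two-sided Fisher exact tests (quadrant vs rest).

    Genes lying exactly on an axis are excluded from quadrants and counted
    separately; regions with no usable genes are dropped with a warning.
    """
    count_rows = {}
    for region in regions:
        col = f"delta_m_{region}"
        if col not in top.columns:
            continue
        sub = top[["skewness", col]].dropna()
        if sub.empty:
            warnings.warn(f"quadrant_analysis: region {region!r} has no genes; excluded", stacklevel=2)
            continue
        counts, on_axis = _quadrant_counts(
            sub["skewness"].to_numpy(float), sub[col].to_numpy(float)
        )
        row = {f"{q[0]},{q[1]}": v for q, v in counts.items()}
        row["n"] = sum(counts.values())
        row["on_axis"] = on_axis
        count_rows[region] = row
    counts_df = pd.DataFrame.from_dict(count_rows, orient="index")
    fisher_rows = []
    region_list = list(counts_df.index)
    for i, ra in enumerate(region_list):
        for rb in region_list[i + 1 :]:
            for quad in QUADRANTS:
                label = f"{quad[0]},{quad[1]}"
                a_in, a_tot = counts_df.loc[ra, label], counts_df.loc[ra, "n"]
                b_in, b_tot = counts_df.loc[rb, label], counts_df.loc[rb, "n"]
                table = [[a_in, a_tot - a_in], [b_in, b_tot - b_in]]
                odds, p = stats.fisher_exact(table, alternative="two-sided")
                fisher_rows.append(
                    {"region_a": ra, "region_b": rb, "quadrant": label,
                     "odds_ratio": float(odds), "p": float(p)}
                )
    return QuadrantReport(counts=counts_df, fisher=pd.DataFrame(fisher_rows))


def correlation_with_ci(top: pd.DataFrame, region: str = "All") -> CorrelationResult:
    """Pearson r between skewness and per-region dM over the top genes, with
    the Fisher-z 95% CI: tanh(atanh(r) +/- 1.96 / sqrt(N - 3))."""
    col = f"delta_m_{region}"
    sub = top[["skewness", col]].dropna()
    if len(sub) < 4:
        raise ValueError(f"correlation_with_ci: need >= 4 genes with defined values, got {len(sub)}")
    s = sub["skewness"].to_numpy(float)
    dm = sub[col].to_numpy(float)
    if np.ptp(s) == 0 or np.ptp(dm) == 0:
        raise ValueError("correlation_with_ci: zero variance in skewness or dM")
    r = float(stats.pearsonr(s, dm).statistic)
    n = len(sub)
    if abs(r) >= 1.0 - 1e-12:  # collinear data: Fisher z diverges
        return CorrelationResult(region=region, n=n, r=r, ci_low=r, ci_high=r, degenerate=True)
    z = np.arctanh(r)
    half = 1.96 / np.sqrt(n - 3)
    return CorrelationResult(
        region=region, n=n, r=r,
        ci_low=float(np.tanh(z - half)), ci_high=float(np.tanh(z + half)),
    )


def robustness_sweep(
    summaries: pd.DataFrame,
    n_grid=None,
    regions=ALL_REGIONS,
    smooth_window: int = 1,
) -> pd.DataFrame:
    """``correlation_with_ci`` at each top-N in ``n_grid`` per region, with
    optional rolling-mean smoothing of the r series (window 1 = raw).

    The grid is truncated to the number of available genes.  Columns:
    top_n, region, n_used, r, ci_low, ci_high, r_smooth.
    """
    if n_grid is None:
        n_grid = list(range(100, 501, 25))
    n_grid = [n for n in sorted(set(int(n) for n in n_grid)) if n >= 1]
    n_grid = [min(n, len(summaries)) for n in n_grid]
    n_grid = sorted(set(n_grid))
    rows = []
    for n in n_grid:
        top = summaries.head(n)
        for region in regions:
            try:
                res = correlation_with_ci(top, region)
            except ValueError:
                rows.append({"top_n": n, "region": region, "n_used": np.nan,
                             "r": np.nan, "ci_low": np.nan, "ci_high": np.nan})
                continue
            rows.append({"top_n": n, "region": region, "n_used": res.n,
                         "r": res.r, "ci_low": res.ci_low, "ci_high": res.ci_high})
    out = pd.DataFrame(
        rows, columns=["top_n", "region", "n_used", "r", "ci_low", "ci_high"]
    )
    if out.empty:
        out["r_smooth"] = pd.Series(dtype=float)
        return out
    out["r_smooth"] = (
        out.groupby("region")["r"]
        .transform(lambda s: s.rolling(smooth_window, min_periods=1, center=True).mean())
    )
    return out


def intersect_and_unique(
    significant: dict[str, list],
    n_unique: int = 1269,
) -> tuple[set, dict[str, list]]:
    """Cross-cohort gene-set selection: the intersection of every cohort's
    significant genes, plus each cohort's top ``n_unique`` significant genes
    outside that intersection (lists must already be in ranking order)."""
    if len(significant) < 2:
        raise ValueError("intersect_and_unique needs >= 2 cohorts")
    shared = set.intersection(*(set(genes) for genes in significant.values()))
    uniques = {}
    for cohort, genes in significant.items():
        outside = [g for g in genes if g not in shared]
        if len(outside) < n_unique:
            warnings.warn(
                f"intersect_and_unique: cohort {cohort!r} has only {len(outside)} unique gene(s)",
                stacklevel=2,
            )
        uniques[cohort] = outside[:n_unique]
    return shared, uniques
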