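"""Sample-size sensitivity of gene splitting, and its exponential convergence.

The gene-split fraction is recomputed on random subsamples of increasing
size n, giving a sequence s_n.  Assuming the sequence approaches its limit
exponentially,

    s_n = a * exp(-b * n) + L,

the constants (a, b, L) are estimated by least squares; the limit of the
sequence is then approximately L, the rate of convergence is C = exp(-b)
(between 0 and 1 for b > 0), and the n-th relative error is
E_n = (s_n - L) / L.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from . import skewcore


@dataclass
class ConvergenceSeries:
    """Gene-split fraction (mean over repeats) at each subsample size."""

    sizes: np.ndarray
    values: np.ndarray
    repeats: int
    dispersion: np.ndarray  # per-size sd across repeats

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.dispersion = np.asarray(self.dispersion, dtype=float)
        if len(self.sizes) != len(self.values):
            raise ValueError("sizes and values length mismatch")
        if np.any(np.diff(self.sizes) <= 0):
            raise ValueError("sizes must be strictly increasing")


@dataclass
class ConvergenceFit:
    """Least-squares fit of s_n = a*exp(-b*n) + L."""

    a: float
    b: float
    L: float
    C: float  # exp(-b), the rate of convergence
    errors: np.ndarray | None  # E_n = (s_n - L)/L, None when |L| ~ 0
    final_abs_pct_error: float | None  # |E_last| * 100
    cost: float
    success: bool


def default_size_grid(n_samples: int, n_points: int = 10, smallest: int = 20) -> list[int]:
    """Log-spaced subsample sizes from ``smallest`` up to the cohort size."""
    if n_samples < smallest:
        raise ValueError(f"cohort of {n_samples} smaller than smallest grid size {smallest}")
    grid = np.unique(
        np.round(np.geomspace(smallest, n_samples, n_points)).astype(int)
    )
    return grid.tolist()


def subsample_splits(
    matrix,
    sizes,
    repeats: int = 25,
    seed: int = 0,
    unbiased: bool = False,
) -> ConvergenceSeries:
    """Gene-split fraction on ``repeats`` random sample subsets (drawn without
    replacement) at each size; the series records the mean and sd per size."""
    frame = matrix.data if hasattr(matrix, "data") else matrix
    sizes = sorted(int(s) for s in sizes)
    if not sizes:
        raise ValueError("empty size list")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    n = frame.shape[1]
    if sizes[0] < 3:
        raise ValueError("subsample sizes must be >= 3")
    if sizes[-1] > n:
        raise ValueError(f"size {sizes[-1]} exceeds cohort of {n} samples")
    rng = np.random.default_rng(seed)
    means, sds = [], []
    for size in sizes:
        vals = []
        for _ in range(repeats):
            idx = rng.choice(n, size=size, replace=False)
            sub = frame.iloc[:, np.sort(idx)]
            table = skewcore.compute_skewness(sub, unbiased=unbiased)
            vals.append(skewcore.gene_split(table).fraction_negative)
        means.append(float(np.mean(vals)))
        sds.append(float(np.std(vals, ddof=1)) if repeats > 1 else 0.0)
    return ConvergenceSeries(sizes=np.array(sizes, float), values=np.array(means), repeats=repeats, dispersion=np.array(sds))


def _initial_guess(n: np.ndarray, s: np.ndarray) -> tuple[float, float, float]:
    """L0 = last value; b0 from OLS of log|s - L0| on n; a0 from the intercept."""
    L0 = float(s[-1])
    resid = s - L0
    mask = np.abs(resid) > 1e-12
    if mask.sum() >= 2:
        y = np.log(np.abs(resid[mask]))
        slope, intercept = np.polyfit(n[mask], y, 1)
        b0 = max(-float(slope), 1e-4)
        a0 = float(np.sign(resid[mask][0]) * np.exp(intercept))
    else:
        b0, a0 = 0.1, 0.0
    return a0, b0, L0


def fit_convergence(series: ConvergenceSeries, n_starts: int = 5, seed: int = 0) -> ConvergenceFit:
    """Least-squares estimate of (a, b, L) with b constrained positive.

    Multi-start: the data-driven initial guess plus ``n_starts - 1`` jittered
    copies guard against local minima.  Points are sorted by n first, so a
    permuted copy of the same series yields the identical fit.  Requires at
    least 4 points.
    """
    order = np.argsort(series.sizes)
    n = series.sizes[order]
    s = series.values[order]
    if len(n) < 4:
        raise ValueError(f"fit_convergence needs >= 4 points, got {len(n)}")
    a0, b0, L0 = _initial_guess(n, s)
    rng = np.random.default_rng(seed)

    def residual(params):
        a, b, L = params
        return a * np.exp(-b * n) + L - s

    starts = [(a0, b0, L0)]
    for _ in range(n_starts - 1):
        starts.append(
            (
                a0 * rng.uniform(0.5, 2.0) if a0 != 0 else rng.normal(0, 0.1),
                b0 * rng.uniform(0.3, 3.0),
                L0 + rng.normal(0, max(abs(L0), 0.1) * 0.1),
            )
        )
    best = None
    for start in starts:
        try:
            res = least_squares(
                residual,
                x0=np.asarray(start, float),
                bounds=([-np.inf, 1e-12, -np.inf], [np.inf, np.inf, np.inf]),
                ftol=1e-14, xtol=1e-14, gtol=1e-14,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return ConvergenceFit(np.nan, np.nan, np.nan, np.nan, None, None, np.inf, False)
    a, b, L = (float(v) for v in best.x)
    if abs(L) < 1e-8:
        errors, final = None, None
    else:
        errors = (s - L) / L
        final = float(abs(errors[-1]) * 100.0)
    return ConvergenceFit(a=a, b=b, L=L, C=float(np.exp(-b)), errors=errors,
                          final_abs_pct_error=final, cost=float(best.cost), success=bool(best.success))
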