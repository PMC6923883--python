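"""Categorize genes by skew difference with a univariate Gaussian mixture.

Skew-difference distributions across cohort pairs are typically tri-modal:
a central mode of genes whose asymmetry barely changes, flanked by modes of
genes that became more negatively or more positively skewed.  A
variable-variance (each component has its own sigma) univariate Gaussian
mixture is fitted by EM for K = 1..10 and the number of components is chosen
by maximizing BIC = 2*logL - p*ln(n) with p = 3K - 1 free parameters
(K weights summing to one, K means, K variances).

EM details: k-means++ seeding refined by Lloyd iterations; 10 restarts run
as one vectorized batch on the emEM two-phase schedule (a short burn-in for
every restart, then the best-likelihood one continues to full convergence);
tolerance 1e-6 on the relative log-likelihood change, at most 500
iterations, and a variance floor of 1e-6 times the data variance to prevent
component collapse; restarts that collapse anyway are discarded and redrawn.

Components ordered by mean map to the three skew categories:
lowest -> "<" (shift toward negative skew), highest -> ">" (toward positive),
everything between -> "~" (negligible change).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass
class Mixture1D:
    """One fitted univariate Gaussian mixture (components sorted by mean)."""

    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    loglik: float
    n_iter: int
    loglik_path: np.ndarray  # per-iteration log-likelihood of the winning restart
    converged: bool

    @property
    def k(self) -> int:
        return len(self.weights)

    def log_component_density(self, x: np.ndarray) -> np.ndarray:
        """(n, k) array of log w_k + log N(x | mu_k, v_k)."""
        x = np.asarray(x, dtype=float)[:, None]
        return (
            np.log(self.weights)[None, :]
            - 0.5 * (_LOG_2PI + np.log(self.variances))[None, :]
            - 0.5 * (x - self.means[None, :]) ** 2 / self.variances[None, :]
        )

    def responsibilities(self, x: np.ndarray) -> np.ndarray:
        lw = self.log_component_density(x)
        m = lw.max(axis=1, keepdims=True)
        lse = m + np.log(np.exp(lw - m).sum(axis=1, keepdims=True))
        return np.exp(lw - lse)


@dataclass
class MixtureModelFit:
    """EM fits for every candidate K with their BIC, plus the winner."""

    table: pd.DataFrame  # columns: k, loglik, n_params, bic
    selected_k: int
    fits: dict[int, Mixture1D]
    gene_ids: pd.Index
    data: np.ndarray


def _kmeanspp_centers(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding on 1-D data."""
    centers = np.empty(k)
    centers[0] = x[rng.integers(len(x))]
    d2 = (x - centers[0]) ** 2
    for j in range(1, k):
        total = d2.sum()
        if total == 0:
            centers[j:] = centers[0]
            break
        centers[j] = x[rng.choice(len(x), p=d2 / total)]
        d2 = np.minimum(d2, (x - centers[j]) ** 2)
    return centers


def _lloyd_refine(x_sorted: np.ndarray, centers: np.ndarray, max_iter: int = 50) -> np.ndarray:
    """Lloyd (k-means) iterations on sorted 1-D data until the centers stop
    moving; turns raw k-means++ seeds into a good partition of the modes."""
    c = np.sort(centers)
    for _ in range(max_iter):
        mids = (c[1:] + c[:-1]) / 2
        idx = np.searchsorted(mids, x_sorted)
        new = c.copy()
        for j in range(len(c)):
            mask = idx == j
            if mask.any():
                new[j] = x_sorted[mask].mean()
        new = np.sort(new)
        if np.allclose(new, c, rtol=0, atol=1e-12):
            break
        c = new
    return c


def _init_params(
    x: np.ndarray, x_sorted: np.ndarray, k: int, rng: np.random.Generator, var_floor: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hard-assignment M-step from Lloyd-refined k-means++ centers."""
    centers = _lloyd_refine(x_sorted, _kmeanspp_centers(x, k, rng))
    mids = (centers[1:] + centers[:-1]) / 2
    assign = np.searchsorted(mids, x)
    n = len(x)
    weights = np.empty(k)
    means = centers.copy()
    variances = np.full(k, max(x.var(), var_floor))
    for j in range(k):
        mask = assign == j
        weights[j] = max(mask.sum(), 1) / n
        if mask.sum() >= 2:
            means[j] = x[mask].mean()
            variances[j] = max(x[mask].var(), var_floor)
    weights /= weights.sum()
    return weights, means, variances


def _em_batch(
    x: np.ndarray,
    weights: np.ndarray,  # (R, k)
    means: np.ndarray,
    variances: np.ndarray,
    tol: float,
    max_iter: int,
    var_floor: float,
    select_after: int | None = None,
) -> list[Mixture1D | None]:
    """Run EM for R restarts simultaneously; None marks a collapsed restart.

    With ``select_after`` the run follows the emEM two-phase schedule: after
    that many burn-in iterations only the highest-likelihood restart
    continues to full convergence (the others are frozen where they stand).
    """
    n = len(x)
    n_restarts, k = weights.shape
    xrow = x[None, :, None]  # (1, n, 1)
    xsq = x * x
    ll_prev = np.full(n_restarts, -np.inf)
    paths: list[list[float]] = [[] for _ in range(n_restarts)]
    status = np.zeros(n_restarts, dtype=int)  # 0 running, 1 converged, -1 collapsed
    n_iters = np.zeros(n_restarts, dtype=int)
    for it in range(max_iter):
        active = np.flatnonzero(status == 0)
        if active.size == 0:
            break
        w, mu, v = weights[active], means[active], variances[active]
        # log weighted densities, then a single exp for both the likelihood
        # and the responsibilities
        const = np.log(w) - 0.5 * (_LOG_2PI + np.log(v))  # (A, k)
        lw = const[:, None, :] - (xrow - mu[:, None, :]) ** 2 * (0.5 / v)[:, None, :]
        m = lw.max(axis=2, keepdims=True)
        q = np.exp(lw - m)  # (A, n, k)
        qsum = q.sum(axis=2, keepdims=True)
        ll = (m + np.log(qsum)).sum(axis=(1, 2))  # (A,)
        for a, r in enumerate(active):
            paths[r].append(float(ll[a]))
            n_iters[r] = it + 1
        done = (it > 0) & (ll - ll_prev[active] <= tol * np.abs(ll))
        status[active[done]] = 1
        ll_prev[active] = ll
        if select_after is not None and it == select_after:
            survivors = np.flatnonzero(status == 0)
            if survivors.size > 1:
                winner = survivors[np.argmax(ll_prev[survivors])]
                frozen = survivors[survivors != winner]
                status[frozen] = 2  # stopped after burn-in, not converged
                done = done | np.isin(active, frozen)
        keep = ~done
        if not keep.any():
            continue
        sub = active[keep]
        resp = q[keep] / qsum[keep]  # (S, n, k)
        nk = resp.sum(axis=1)  # (S, k)
        collapsed = (nk < 1e-10 * n).any(axis=1)
        if collapsed.any():
            status[sub[collapsed]] = -1
            ok = ~collapsed
            sub, resp, nk = sub[ok], resp[ok], nk[ok]
            if sub.size == 0:
                continue
        sx = np.einsum("snk,n->sk", resp, x)
        sxx = np.einsum("snk,n->sk", resp, xsq)
        new_means = sx / nk
        weights[sub] = nk / n
        means[sub] = new_means
        variances[sub] = np.maximum(sxx / nk - new_means**2, var_floor)
    out: list[Mixture1D | None] = []
    for r in range(n_restarts):
        if status[r] == -1:
            out.append(None)
            continue
        order = np.argsort(means[r])
        out.append(
            Mixture1D(
                weights=weights[r][order],
                means=means[r][order],
                variances=variances[r][order],
                loglik=paths[r][-1],
                n_iter=int(n_iters[r]),
                loglik_path=np.asarray(paths[r]),
                converged=status[r] == 1,
            )
        )
    return out


def fit_mixture_1d(
    x: np.ndarray,
    k: int,
    seed: int | np.random.Generator = 0,
    n_init: int = 10,
    tol: float = 1e-6,
    max_iter: int = 500,
    burn_in: int = 25,
) -> Mixture1D:
    """Best-of-``n_init`` EM fit of a k-component variable-variance Gaussian
    mixture to 1-D data.

    Restarts run as one vectorized batch on the emEM schedule: every restart
    gets ``burn_in`` iterations, then the best-likelihood one continues to
    full convergence (``burn_in=None`` runs all restarts to convergence).
    Collapsed restarts are redrawn (up to three extra rounds)."""
    x = np.asarray(x, dtype=float)
    if len(x) < k:
        raise ValueError(f"cannot fit {k} components to {len(x)} points")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    var_floor = max(1e-6 * x.var(), np.finfo(float).tiny)
    if k == 1:
        # closed form: single Gaussian at the MLE
        mu, v = x.mean(), max(x.var(), var_floor)
        ll = float((-0.5 * (_LOG_2PI + np.log(v)) - 0.5 * (x - mu) ** 2 / v).sum())
        return Mixture1D(
            weights=np.array([1.0]), means=np.array([mu]), variances=np.array([v]),
            loglik=ll, n_iter=1, loglik_path=np.array([ll]), converged=True,
        )
    x_sorted = np.sort(x)
    best: Mixture1D | None = None
    remaining = n_init
    for _round in range(4):
        if remaining <= 0:
            break
        weights = np.empty((remaining, k))
        means = np.empty((remaining, k))
        variances = np.empty((remaining, k))
        for r in range(remaining):
            weights[r], means[r], variances[r] = _init_params(x, x_sorted, k, rng, var_floor)
        fits = _em_batch(
            x, weights, means, variances, tol, max_iter, var_floor, select_after=burn_in
        )
        remaining = sum(f is None for f in fits)
        for f in fits:
            if f is not None and (best is None or f.loglik > best.loglik):
                best = f
    if best is None:
        raise RuntimeError(f"EM failed for k={k}: every restart collapsed")
    return best


def bic_score(loglik: float, k: int, n: int) -> float:
    """BIC on the maximize-me convention: 2*logL - p*ln(n), p = 3k - 1."""
    p = 3 * k - 1
    return 2.0 * loglik - p * np.log(n)


def fit_skew_mixture(
    diffs,
    k_min: int = 1,
    k_max: int = 10,
    seed: int = 0,
    n_init: int = 10,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> MixtureModelFit:
    """Fit mixtures for K = k_min..k_max to skew differences and select K by
    maximizing BIC.

    ``diffs`` is the skew-difference table (DataFrame with a ``delta``
    column), a Series, or a plain array.  Requires at least 20 values.
    """
    if isinstance(diffs, pd.DataFrame):
        values = diffs["delta"].to_numpy(dtype=float)
        index = diffs.index
    elif isinstance(diffs, pd.Series):
        values = diffs.to_numpy(dtype=float)
        index = diffs.index
    else:
        values = np.asarray(diffs, dtype=float)
        index = pd.RangeIndex(len(values))
    if len(values) < 20:
        raise ValueError(f"fit_skew_mixture needs >= 20 genes, got {len(values)}")
    rng = np.random.default_rng(seed)
    fits: dict[int, Mixture1D] = {}
    rows = []
    n = len(values)
    for k in range(k_min, k_max + 1):
        fit = fit_mixture_1d(values, k, seed=rng, n_init=n_init, tol=tol, max_iter=max_iter)
        fits[k] = fit
        rows.append({"k": k, "loglik": fit.loglik, "n_params": 3 * k - 1, "bic": bic_score(fit.loglik, k, n)})
    table = pd.DataFrame(rows)
    selected = int(table.loc[table["bic"].idxmax(), "k"])
    return MixtureModelFit(table=table, selected_k=selected, fits=fits, gene_ids=index, data=values)


CATEGORIES = ("<", "~", ">")


def assign_categories(fit: MixtureModelFit, force_k3: bool = True) -> pd.DataFrame:
    """Assign each gene to a skew category by maximum-posterior component.

    With ``force_k3`` the K=3 fit is used regardless of the BIC winner
    (the three-category reading: "<" more negative skew, "~" negligible
    change, ">" more positive skew).  Otherwise the selected K is used;
    K < 3 emits only the representable categories with a warning.

    Returns a DataFrame indexed by gene with columns ``category`` and
    ``component`` (mean-ordered component index); the component-to-category
    map is stored in ``attrs['component_map']``.
    """
    k = 3 if force_k3 else fit.selected_k
    if k not in fit.fits:
        raise ValueError(f"no K={k} fit available (candidates: {sorted(fit.fits)})")
    mix = fit.fits[k]
    if k == 1:
        comp_map = ["~"]
    elif k == 2:
        comp_map = ["<", ">"]
    else:
        comp_map = ["<"] + ["~"] * (k - 2) + [">"]
    if k < 3:
        warnings.warn(
            f"assign_categories: K={k} < 3; only categories {sorted(set(comp_map))} are representable",
            stacklevel=2,
        )
    resp = mix.responsibilities(fit.data)
    hard = resp.argmax(axis=1)
    out = pd.DataFrame(
        {"category": [comp_map[j] for j in hard], "component": hard},
        index=fit.gene_ids,
    )
    out.attrs["component_map"] = comp_map
    out.attrs["k"] = k
    return out
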