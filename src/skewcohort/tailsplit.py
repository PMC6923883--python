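"""Partition each gene's expression distribution into tail and non-tail patients.

Two methods:

* quantile splitting — the ceil(q*n) most extreme samples on the skew side;
  the tail *area* is constant across genes, so downstream two-group tests run
  on equal-sized groups.
* Gaussian splitting — the central mode is located by a robust fit (median
  and 1.4826*MAD); samples beyond a z threshold from it, on the skew side,
  form the tail.

The skew direction per gene is sign(S_g); genes with undefined or exactly
zero skewness are excluded from tail analysis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MAD_SCALE = 1.4826  # consistency factor: MAD * 1.4826 estimates a normal sd


@dataclass
class TailAssignment:
    """Tail / non-tail partition of one gene's samples."""

    gene: str
    direction: int  # +1 right tail, -1 left tail
    tail: list
    nontail: list
    method: str  # "quantile" | "gaussian"
    parameter: float  # q or z threshold
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.direction not in (+1, -1):
            raise ValueError(f"direction must be +1 or -1, got {self.direction}")
        if set(self.tail) & set(self.nontail):
            raise ValueError("tail and non-tail sets overlap")


def quantile_tail_split(values: pd.Series, direction: int, q: float = 0.1) -> TailAssignment:
    """Tail = the ceil(q*n) most extreme samples in the skew direction.

    Ties at the cut are broken by sample-id order, so the split is
    deterministic.  A constant vector still yields a tail of the required
    size (first ids) but is flagged degenerate.
    """
    if not 0 < q < 0.5:
        raise ValueError(f"q must lie in (0, 0.5), got {q}")
    if direction not in (+1, -1):
        raise ValueError(f"direction must be +1 or -1, got {direction}")
    n = len(values)
    t = math.ceil(q * n)
    frame = pd.DataFrame({"value": values.to_numpy(dtype=float), "sample": values.index})
    frame = frame.sort_values(
        ["value", "sample"], ascending=[direction < 0, True], kind="mergesort"
    )
    tail_ids = frame["sample"].iloc[:t].tolist()
    nontail_ids = frame["sample"].iloc[t:].tolist()
    degenerate = np.ptp(values.to_numpy(dtype=float)) == 0
    return TailAssignment(
        gene=str(values.name) if values.name is not None else "",
        direction=direction,
        tail=tail_ids,
        nontail=nontail_ids,
        method="quantile",
        parameter=q,
        degenerate=degenerate,
    )


def gaussian_tail_split(values: pd.Series, direction: int, z_threshold: float = 2.5) -> TailAssignment:
    """Tail = samples beyond ``z_threshold`` robust z-units from the central
    mode (median, MAD*1.4826 scale) on the skew side.

    A zero robust scale (constant or near-constant vector) yields an empty
    tail with a warning.  Requires at least 20 samples for the central-mode
    fit to be meaningful.
    """
    if direction not in (+1, -1):
        raise ValueError(f"direction must be +1 or -1, got {direction}")
    if len(values) < 20:
        raise ValueError(f"gaussian splitting needs >= 20 samples, got {len(values)}")
    x = values.to_numpy(dtype=float)
    center = float(np.median(x))
    scale = MAD_SCALE * float(np.median(np.abs(x - center)))
    name = str(values.name) if values.name is not None else ""
    if scale == 0:
        warnings.warn(f"gaussian_tail_split: zero robust scale for gene {name!r}; empty tail", stacklevel=2)
        return TailAssignment(
            gene=name, direction=direction, tail=[],
            nontail=list(values.index), method="gaussian",
            parameter=z_threshold, degenerate=True,
        )
    z = (x - center) / scale
    in_tail = direction * z > z_threshold
    return TailAssignment(
        gene=name,
        direction=direction,
        tail=list(values.index[in_tail]),
        nontail=list(values.index[~in_tail]),
        method="gaussian",
        parameter=z_threshold,
    )


def split_cohort(
    matrix,
    skew_table: pd.DataFrame,
    method: str = "quantile",
    q: float = 0.1,
    z_threshold: float = 2.5,
) -> dict[str, TailAssignment]:
    """Tail assignments for every gene with a defined, non-zero skewness.

    ``matrix`` is an ExpressionMatrix (or gene x sample DataFrame); the skew
    direction is sign(S_g) from ``skew_table``.  Returns gene -> assignment.
    """
    frame = matrix.data if hasattr(matrix, "data") else matrix
    out: dict[str, TailAssignment] = {}
    skipped = 0
    for gene in frame.index:
        if gene not in skew_table.index:
            skipped += 1
            continue
        s = skew_table.loc[gene, "skewness"]
        if not np.isfinite(s) or s == 0:
            skipped += 1
            continue
        direction = 1 if s > 0 else -1
        row = frame.loc[gene]
        if method == "quantile":
            out[gene] = quantile_tail_split(row, direction, q=q)
        elif method == "gaussian":
            out[gene] = gaussian_tail_split(row, direction, z_threshold=z_threshold)
        else:
            raise ValueError(f"unknown tail method {method!r}")
    if skipped:
        warnings.warn(f"split_cohort: {skipped} gene(s) skipped (undefined or zero skew)", stacklevel=2)
    return out


@dataclass
class TailOverlapReport:
    """Agreement between two tail-splitting methods on the same cohort."""

    per_gene_jaccard: pd.Series
    mean_jaccard: float
    significant_overlap: float | None = None  # |A n B| / |A u B| of significant genes


def _jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def compare_tail_methods(
    a: dict[str, TailAssignment],
    b: dict[str, TailAssignment],
    downstream_significant_a=None,
    downstream_significant_b=None,
) -> TailOverlapReport:
    """Per-gene Jaccard of tail sets between two assignment collections and,
    when downstream significant-gene lists are given, the Jaccard of those
    lists.  Both collections must cover the same genes."""
    if set(a) != set(b):
        raise ValueError("compare_tail_methods: mismatched gene sets")
    jac = pd.Series({g: _jaccard(set(a[g].tail), set(b[g].tail)) for g in a})
    sig_overlap = None
    if downstream_significant_a is not None and downstream_significant_b is not None:
        sa, sb = set(downstream_significant_a), set(downstream_significant_b)
        sig_overlap = _jaccard(sa, sb)
    return TailOverlapReport(
        per_gene_jaccard=jac,
        mean_jaccard=float(jac.mean()) if len(jac) else float("nan"),
        significant_overlap=sig_overlap,
    )
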