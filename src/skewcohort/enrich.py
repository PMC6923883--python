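"""Hypergeometric over-representation of gene sets within skew categories.

For a category of m genes drawn from a universe of N genes, a set with K
members in the universe and k members in the category has upper-tail
p = P(X >= k), X ~ Hypergeometric(N, K, m).  The universe is the genes with
a defined skew difference in the comparison — the sampling frame from which
the mixture categories were formed.  Benjamini-Hochberg correction is applied
within each (category, module) stratum; the per-category top-10 summary
counts how many of the ten most significant sets carry each module label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets with optional descriptions and module labels
    (e.g. Immune System, Metabolism, Translation)."""

    sets: dict[str, frozenset]
    descriptions: dict[str, str] = field(default_factory=dict)
    modules: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sets = {name: frozenset(members) for name, members in self.sets.items()}

    def __len__(self) -> int:
        return len(self.sets)

    def module_of(self, name: str) -> str:
        return self.modules.get(name, "")


def hypergeom_upper_tail(k: int, universe: int, set_size: int, category_size: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(universe, set_size, category_size)."""
    return float(stats.hypergeom.sf(k - 1, universe, set_size, category_size))


def overrepresentation_test(
    categories: pd.DataFrame,
    collection: GeneSetCollection,
    universe=None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric test of every gene set in every category.

    ``categories`` is the assignment table from ``mixcat.assign_categories``
    (indexed by gene, with a ``category`` column).  ``universe`` defaults to
    the genes carrying a category (the comparison's sampling frame) and must
    contain all of them.  Sets are intersected with the universe before
    testing; sets with no members in the universe are skipped.  BH runs
    within each (category, module) stratum; ``significant`` flags adjusted
    p < alpha.
    """
    cat_genes = categories.index
    if universe is None:
        universe_set = set(cat_genes)
    else:
        universe_set = set(universe)
        missing = set(cat_genes) - universe_set
        if missing:
            raise ValueError(f"universe missing {len(missing)} categorized gene(s)")
    if not universe_set:
        raise ValueError("empty universe")
    n_u = len(universe_set)
    rows = []
    for cat, sub in categories.groupby("category"):
        members_in_cat = set(sub.index) & universe_set
        m = len(members_in_cat)
        for name, genes in collection.sets.items():
            in_universe = genes & universe_set
            if not in_universe:
                log.info("overrepresentation_test: set %r has no members in universe; skipped", name)
                continue
            k = len(in_universe & members_in_cat)
            p = hypergeom_upper_tail(k, n_u, len(in_universe), m)
            rows.append(
                {
                    "set": name,
                    "category": cat,
                    "module": collection.module_of(name),
                    "overlap": k,
                    "set_size": len(in_universe),
                    "category_size": m,
                    "universe_size": n_u,
                    "p": p,
                }
            )
    results = pd.DataFrame(rows)
    if results.empty:
        return results.assign(p_adj=[], significant=[])
    results["p_adj"] = 1.0
    for _, idx in results.groupby(["category", "module"]).groups.items():
        results.loc[idx, "p_adj"] = multipletests(results.loc[idx, "p"], method="fdr_bh")[1]
    results["significant"] = results["p_adj"] < alpha
    return results


def summarize_top_pathways(results: pd.DataFrame, top_n: int = 10) -> pd.DataFrame:
    """Per category, rank sets by adjusted p (ties by raw p, then name), keep
    the ``top_n`` most significant, and count how many carry each module
    label.  When fewer than ``top_n`` sets are available the count runs over
    all of them and ``n_considered`` records how many."""
    rows = []
    for cat, sub in results.groupby("category"):
        ranked = sub.sort_values(["p_adj", "p", "set"], kind="mergesort").head(top_n)
        counts = ranked["module"].value_counts()
        for module, count in counts.items():
            rows.append(
                {"category": cat, "module": module, "count": int(count), "n_considered": len(ranked)}
            )
        if len(ranked) < top_n:
            log.info("summarize_top_pathways: category %r has only %d set(s)", cat, len(ranked))
    return pd.DataFrame(rows)
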