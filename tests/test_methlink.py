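import itertools
import math

import numpy as np
import pandas as pd
import pytest

from skewcohort import methlink
from skewcohort.methlink import (
    beta_to_mvalue,
    correlation_with_ci,
    intersect_and_unique,
    probe_dm_test,
    quadrant_analysis,
    rank_sum_test,
    robustness_sweep,
    select_top_genes,
    summarize_genes,
)
from skewcohort.tailsplit import TailAssignment


def rank_sum_oracle(x, y):
    """Exact two-sided rank-sum p by enumerating every assignment of the
    pooled values to the first group (tie-free data only)."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    us = []
    for combo in itertools.combinations(range(len(pooled)), n1):
        first = pooled[list(combo)]
        second = np.delete(pooled, list(combo))
        us.append(sum(1 for a in first for b in second if a > b))
    us = np.asarray(us)
    p_low = (us <= u_obs).mean()
    p_high = (us >= u_obs).mean()
    return min(1.0, 2 * min(p_low, p_high))


class TestRankSumTest:
    def test_separated_groups_worked_example(self):
        # tail {5,6,7} vs non-tail {1,2,3,4}: one-sided 1/35, two-sided 2/35
        p = rank_sum_test([5, 6, 7], [1, 2, 3, 4])
        assert p == pytest.approx(2 / 35, abs=1e-12)

    def test_matches_enumeration_all_small_group_sizes(self, rng):
        """Exact p equals exhaustive enumeration for every group-size pair
        with total <= 12."""
        for n1 in range(2, 11):
            for n2 in range(2, 13 - n1):
                x = rng.normal(size=n1)
                y = rng.normal(size=n2)
                assert rank_sum_test(x, y) == pytest.approx(rank_sum_oracle(x, y), abs=1e-12)

    def test_null_type_i_error_at_study_group_sizes(self, rng):
        """2,000 null probes with 50-vs-450 splits: rejection at 0.05 stays
        inside the binomial 95% interval around 0.05."""
        n_probes, alpha = 2000, 0.05
        rejections = 0
        x = rng.normal(size=(n_probes, 50))
        y = rng.normal(size=(n_probes, 450))
        from scipy import stats

        p = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic", axis=1).pvalue
        rejections = (p < alpha).sum()
        half = 1.96 * math.sqrt(alpha * (1 - alpha) / n_probes)
        assert alpha - half <= rejections / n_probes <= alpha + half


class TestBetaToM:
    def test_logit_reference_points(self):
        beta = pd.DataFrame({"s": [0.5, 0.8, 0.2]}, index=["p1", "p2", "p3"])
        m = beta_to_mvalue(beta).data["s"]
        assert m["p1"] == pytest.approx(0.0, abs=1e-12)
        assert m["p2"] == pytest.approx(2.0, abs=1e-9)
        assert m["p3"] == pytest.approx(-2.0, abs=1e-9)

    def test_extremes_clipped_not_infinite(self):
        beta = pd.DataFrame({"s": [0.0, 1.0]}, index=["p1", "p2"])
        m = beta_to_mvalue(beta, epsilon=1e-6).data["s"]
        assert np.isfinite(m).all()
        assert m["p1"] == pytest.approx(-m["p2"], rel=1e-9)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            beta_to_mvalue(pd.DataFrame({"s": [1.2]}, index=["p"]))


def _toy_cohort():
    """Two genes x 12 samples; gene gA's tail carries a +2 M shift on its
    first probe, gene gB is null."""
    samples = [f"s{i}" for i in range(12)]
    rng = np.random.default_rng(0)
    meth = pd.DataFrame(
        rng.normal(0, 0.3, size=(4, 12)),
        index=["pA1", "pA2", "pB1", "pB2"],
        columns=samples,
    )
    meth.loc["pA1", samples[:5]] += 2.0
    ann = pd.DataFrame(
        {"gene_id": ["gA", "gA", "gB", "gB"],
         "region": ["Promoter", "Body", "Promoter", "UTR"]},
        index=meth.index,
    )
    tails = {
        g: TailAssignment(g, 1, samples[:5], samples[5:], "quantile", 0.4)
        for g in ("gA", "gB")
    }
    return methlink.MethylationMatrix(data=meth), tails, ann


class TestProbeDmTest:
    def test_delta_m_is_group_mean_difference(self):
        meth, tails, ann = _toy_cohort()
        res = probe_dm_test(meth, tails, ann, min_tail=2).set_index("probe")
        x = meth.data.loc["pA1", tails["gA"].tail].mean()
        y = meth.data.loc["pA1", tails["gA"].nontail].mean()
        assert res.loc["pA1", "delta_m"] == pytest.approx(x - y, abs=1e-12)
        assert res.loc["pA1", "n_tail"] == 5 and res.loc["pA1", "n_nontail"] == 7

    def test_shifted_probe_significant_null_probe_not(self):
        meth, tails, ann = _toy_cohort()
        res = probe_dm_test(meth, tails, ann, min_tail=2).set_index("probe")
        assert res.loc["pA1", "p_adj"] < 0.05
        assert res.loc["pB1", "p"] > 0.05

    def test_small_tail_genes_skipped(self):
        meth, tails, ann = _toy_cohort()
        res = probe_dm_test(meth, tails, ann, min_tail=6)
        assert res.empty

    def test_bh_adjustment_joint_across_probes(self):
        meth, tails, ann = _toy_cohort()
        res = probe_dm_test(meth, tails, ann, min_tail=2)
        assert (res["p_adj"] >= res["p"] - 1e-12).all()
        sub = res.sort_values("p")
        assert sub["p_adj"].is_monotonic_increasing


class TestSummarizeAndSelect:
    @staticmethod
    def _probe_results():
        return pd.DataFrame(
            {
                "probe": ["p1", "p2", "p3", "q1", "q2"],
                "gene": ["gA", "gA", "gA", "gB", "gB"],
                "region": ["Promoter", "Body", "Promoter", "Promoter", "UTR"],
                "delta_m": [-1.0, 0.4, -0.8, 0.2, 0.1],
                "n_tail": 10, "n_nontail": 90,
                "p": [0.001, 0.15, 0.002, 0.3, 0.5],
                "p_adj": [0.005, 0.2, 0.008, 0.4, 0.6],
            }
        )

    @staticmethod
    def _skew():
        return pd.DataFrame({"skewness": [0.9, -0.4]}, index=["gA", "gB"])

    def test_min_p_and_fraction(self):
        out = summarize_genes(self._probe_results(), self._skew(), alpha=0.01)
        assert out.loc["gA", "min_p_adj"] == pytest.approx(0.005)
        assert out.loc["gA", "frac_significant"] == pytest.approx(2 / 3)

    def test_region_delta_m_over_significant_probes_only(self):
        out = summarize_genes(self._probe_results(), self._skew(), alpha=0.01)
        assert out.loc["gA", "delta_m_Promoter"] == pytest.approx(-0.9)  # p1, p3
        assert np.isnan(out.loc["gA", "delta_m_Body"])  # p2 not significant

    def test_gene_without_significant_probes_retained(self):
        out = summarize_genes(self._probe_results(), self._skew(), alpha=0.01)
        assert out.loc["gB", "frac_significant"] == 0.0
        assert np.isnan(out.loc["gB", "delta_m_All"])

    def test_ranking_ties_broken_by_fraction_then_id(self):
        res = self._probe_results()
        res.loc[res["gene"] == "gB", "p_adj"] = [0.005, 0.6]  # tie on min p
        out = summarize_genes(res, self._skew(), alpha=0.01)
        assert list(out.index) == ["gA", "gB"]  # gA has larger fraction

    def test_select_top_warns_when_short(self):
        out = summarize_genes(self._probe_results(), self._skew())
        assert len(select_top_genes(out, n=1)) == 1
        with pytest.warns(UserWarning, match="only 2"):
            assert len(select_top_genes(out, n=500)) == 2


class TestQuadrantAnalysis:
    @staticmethod
    def _top(points):
        s, dm = zip(*points)
        return pd.DataFrame(
            {"skewness": s, "delta_m_All": dm, "delta_m_Promoter": dm},
            index=[f"g{i}" for i in range(len(points))],
        )

    def test_sign_rule(self):
        rep = quadrant_analysis(self._top([(0.3, -0.5)]), regions=("All",))
        assert rep.counts.loc["All", "S>0,dM<0"] == 1
        assert rep.counts.loc["All", "n"] == 1

    def test_zeros_excluded_and_counted(self):
        rep = quadrant_analysis(self._top([(0.0, 1.0), (1.0, 0.0), (1.0, 1.0)]), regions=("All",))
        assert rep.counts.loc["All", "n"] == 1
        assert rep.counts.loc["All", "on_axis"] == 2

    def test_counts_sum_to_included_genes(self, rng):
        pts = list(zip(rng.normal(size=40), rng.normal(size=40)))
        rep = quadrant_analysis(self._top(pts), regions=("All", "Promoter"))
        quad_cols = [c for c in rep.counts.columns if "," in c]
        assert (rep.counts[quad_cols].sum(axis=1) == rep.counts["n"]).all()

    def test_fisher_worked_example(self):
        """A region pair whose quadrant-vs-rest table is [[3,1],[1,3]] gives
        the exact two-sided p of 34/70."""
        region_a = [(1, 1)] * 3 + [(1, -1)]
        region_b = [(1, 1)] * 1 + [(1, -1)] * 3
        s_a, dm_a = zip(*region_a)
        s_b, dm_b = zip(*region_b)
        top = pd.DataFrame(
            {
                "skewness": s_a + s_b,
                "delta_m_Promoter": list(dm_a) + [np.nan] * 4,
                "delta_m_Body": [np.nan] * 4 + list(dm_b),
            },
            index=[f"g{i}" for i in range(8)],
        )
        rep = quadrant_analysis(top, regions=("Promoter", "Body"))
        row = rep.fisher[(rep.fisher["quadrant"] == "S>0,dM>0")].iloc[0]
        assert row["p"] == pytest.approx(34 / 70, abs=1e-12)


class TestCorrelationWithCI:
    def test_fisher_z_interval_reference(self):
        """r = 0.8 at N = 500 gives the closed-form CI (0.766, 0.830)."""
        rng = np.random.default_rng(3)
        # construct data with exactly r = 0.8 via Gram-Schmidt
        x = rng.normal(size=500)
        e = rng.normal(size=500)
        x = (x - x.mean()) / x.std()
        e = e - e.mean()
        e -= x * (x @ e) / (x @ x)
        e /= e.std()
        y = 0.8 * x + np.sqrt(1 - 0.64) * e
        top = pd.DataFrame({"skewness": x, "delta_m_All": y})
        res = correlation_with_ci(top, "All")
        assert res.r == pytest.approx(0.8, abs=1e-9)
        assert res.ci_low == pytest.approx(0.766, abs=1e-3)
        assert res.ci_high == pytest.approx(0.830, abs=1e-3)

    def test_zero_correlation_symmetric_interval(self, rng):
        x = np.concatenate([np.arange(250.0), np.arange(250.0)])
        y = np.concatenate([np.arange(250.0), -np.arange(250.0)])
        top = pd.DataFrame({"skewness": x, "delta_m_All": y})
        res = correlation_with_ci(top, "All")
        assert res.r == pytest.approx(0.0, abs=1e-12)
        assert res.ci_low == pytest.approx(-res.ci_high, abs=1e-12)

    def test_perfect_correlation_flagged_degenerate(self):
        x = np.arange(10.0)
        top = pd.DataFrame({"skewness": x, "delta_m_All": 2 * x + 1})
        res = correlation_with_ci(top, "All")
        assert res.r == pytest.approx(1.0) and res.degenerate

    def test_preconditions(self):
        top = pd.DataFrame({"skewness": [1.0, 2, 3], "delta_m_All": [1.0, 2, 3]})
        with pytest.raises(ValueError, match=">= 4"):
            correlation_with_ci(top, "All")
        top = pd.DataFrame({"skewness": [1.0] * 5, "delta_m_All": np.arange(5.0)})
        with pytest.raises(ValueError, match="zero variance"):
            correlation_with_ci(top, "All")


class TestRobustnessSweep:
    @staticmethod
    def _summaries(rng, n=200):
        x = rng.normal(size=n)
        return pd.DataFrame(
            {
                "skewness": x,
                "delta_m_All": -0.7 * x + rng.normal(0, 0.4, n),
                "min_p_adj": np.sort(rng.uniform(size=n)),
            },
            index=[f"g{i}" for i in range(n)],
        )

    def test_single_point_grid(self, rng):
        out = robustness_sweep(self._summaries(rng), n_grid=[50], regions=("All",))
        assert len(out) == 1

    def test_window_one_identity(self, rng):
        out = robustness_sweep(
            self._summaries(rng), n_grid=[50, 100, 150], regions=("All",), smooth_window=1
        )
        assert np.allclose(out["r"], out["r_smooth"])

    def test_grid_truncated_to_available(self, rng):
        out = robustness_sweep(self._summaries(rng, 80), n_grid=[50, 500], regions=("All",))
        assert out["top_n"].max() == 80


class TestIntersectAndUnique:
    def test_set_algebra_example(self):
        shared, uniques = intersect_and_unique(
            {"c1": ["A", "B", "C"], "c2": ["B", "C", "D"]}, n_unique=5
        )
        assert shared == {"B", "C"}
        assert uniques == {"c1": ["A"], "c2": ["D"]}

    def test_identical_cohorts_no_uniques(self):
        shared, uniques = intersect_and_unique({"a": ["x", "y"], "b": ["x", "y"]}, n_unique=3)
        assert shared == {"x", "y"}
        assert uniques == {"a": [], "b": []}

    def test_top_one_unique_per_cohort(self):
        _, uniques = intersect_and_unique(
            {"a": ["s", "u1", "u2"], "b": ["s", "v1"]}, n_unique=1
        )
        assert uniques == {"a": ["u1"], "b": ["v1"]}

    def test_requires_two_cohorts(self):
        with pytest.raises(ValueError):
            intersect_and_unique({"a": ["x"]}, n_unique=1)
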