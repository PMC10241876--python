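"""stage_statistics: summaries, KW+DSCF, ANOVA+Tukey, headline ratios."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy import stats

from cohortlife.records import CohortStudy
from cohortlife.stage_stats import (
    GroupSummary,
    anova_tukey,
    headline_ratios,
    kruskal_wallis_dscf,
    oviposition_periods,
    reproductive_summary,
    stage_duration_summary,
)

from conftest import make_female, make_immature_death, make_male


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def exact_kw_pvalue(groups) -> float:
    """Exhaustive permutation p-value for the tie-corrected H statistic.

    Enumerates every distinct assignment of the pooled observations to the
    group sizes; ranks and the tie correction depend only on the pooled
    multiset, so they are computed once.
    """
    pooled = np.concatenate(groups)
    sizes = [len(g) for g in groups]
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_c = 1.0 - np.sum(counts**3 - counts) / (n_total**3 - n_total)

    def h_from_indices(index_groups) -> float:
        h = 12.0 / (n_total * (n_total + 1)) * sum(
            ranks[list(idx)].sum() ** 2 / len(idx) for idx in index_groups
        ) - 3 * (n_total + 1)
        return h / tie_c

    def assignments(remaining, sizes):
        if not sizes:
            yield []
            return
        head, *rest = sizes
        for combo in itertools.combinations(sorted(remaining), head):
            for tail in assignments(remaining - set(combo), rest):
                yield [combo] + tail

    observed = h_from_indices(
        np.split(np.arange(n_total), np.cumsum(sizes)[:-1]))
    count = total = 0
    for assignment in assignments(set(range(n_total)), sizes):
        total += 1
        if h_from_indices(assignment) >= observed - 1e-12:
            count += 1
    return count / total


def exact_ranksum_pvalue(x, y) -> float:
    """Exhaustive two-sided permutation test on the rank-sum statistic."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = stats.rankdata(pooled)
    obs = abs(ranks[:n1].sum() - n1 * (len(pooled) + 1) / 2)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        total += 1
        s = abs(ranks[list(idx)].sum() - n1 * (len(pooled) + 1) / 2)
        if s >= obs - 1e-12:
            count += 1
    return count / total


# ---------------------------------------------------------------------------
# kruskal_wallis_dscf
# ---------------------------------------------------------------------------

class TestKruskalWallisDscf:
    def test_hand_ranked_h(self):
        res = kruskal_wallis_dscf([[1, 2], [3, 4], [5, 6]])
        assert res.statistic == pytest.approx(4.571, abs=5e-4)
        assert res.df == (2,)

    def test_identical_groups(self):
        res = kruskal_wallis_dscf([[5, 5, 5], [5, 5, 5], [5, 5, 5]])
        assert res.statistic == 0.0
        assert res.pvalue == 1.0
        assert res.letters == ["a", "a", "a"]

    def test_monotone_transform_invariance(self):
        groups = [[1.0, 2.5, 4.0], [2.0, 3.0, 7.0], [5.0, 8.0, 9.0]]
        transformed = [list(np.exp(g)) for g in groups]
        a = kruskal_wallis_dscf(groups)
        b = kruskal_wallis_dscf(transformed)
        assert a.statistic == pytest.approx(b.statistic, abs=1e-12)
        assert np.allclose(a.pairwise_pvalues, b.pairwise_pvalues)

    def test_two_groups_matches_normal_rank_sum(self):
        """k=2 DSCF reduces to the two-sided normal rank-sum test."""
        rng = np.random.default_rng(3)
        for trial in range(20):
            x = rng.permutation(np.arange(1.0, 9.0))[: rng.integers(3, 6)]
            y = rng.uniform(0, 10, rng.integers(3, 6))
            res = kruskal_wallis_dscf([list(x), list(y)])
            z_p = stats.ranksums(x, y).pvalue
            assert res.pairwise_pvalues[0, 1] == pytest.approx(z_p, abs=1e-9)

    def test_kw_decision_matches_exhaustive_permutation(self):
        for groups in [
            [[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [7.0, 8.0, 9.0]],
            [[1.0, 5.0], [2.0, 6.0], [3.0, 4.0]],
            [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]],
        ]:
            res = kruskal_wallis_dscf(groups)
            exact = exact_kw_pvalue(groups)
            assert (res.pvalue < 0.05) == (exact < 0.05)

    def test_dscf_decision_matches_exhaustive_pairwise(self):
        # clearly separated and clearly null pairs: asymptotic DSCF must
        # agree in decision with the exact rank permutation test
        separated = [[1.0, 2.0, 3.0, 4.0, 5.0], [11.0, 12.0, 13.0, 14.0, 15.0]]
        null = [[1.0, 4.0, 7.0, 10.0], [2.0, 5.0, 8.0, 11.0]]
        for x, y in (separated, null):
            res = kruskal_wallis_dscf([x, y])
            exact = exact_ranksum_pvalue(np.asarray(x), np.asarray(y))
            assert (res.pairwise_pvalues[0, 1] < 0.05) == (exact < 0.05)

    def test_rejects_tiny_groups(self):
        with pytest.raises(ValueError):
            kruskal_wallis_dscf([[1.0], [2.0, 3.0]])


# ---------------------------------------------------------------------------
# anova_tukey
# ---------------------------------------------------------------------------

class TestAnovaTukey:
    def test_identical_groups(self):
        res = anova_tukey([[2.0, 2.0, 2.0], [2.0, 2.0, 2.0]])
        assert res.statistic == 0.0
        assert res.letters == ["a", "a"]

    def test_two_groups_f_is_t_squared(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, 8)
        b = rng.normal(1, 1, 6)
        res = anova_tukey([a, b])
        t = stats.ttest_ind(a, b, equal_var=True)
        assert res.statistic == pytest.approx(t.statistic**2, abs=1e-9)
        assert res.pvalue == pytest.approx(t.pvalue, abs=1e-9)

    def test_tukey_matches_two_sample_decision(self):
        rng = np.random.default_rng(5)
        for trial in range(20):
            a = rng.normal(0, 1, rng.integers(4, 10))
            b = rng.normal(rng.uniform(0, 2.5), 1, rng.integers(4, 10))
            res = anova_tukey([a, b])
            t_p = stats.ttest_ind(a, b, equal_var=True).pvalue
            assert (res.pairwise_pvalues[0, 1] < 0.05) == (t_p < 0.05)

    def test_three_calibrated_groups_distinct_letters(self):
        """Groups like the preoviposition means (13.0, 7.9, 4.4) separate."""
        rng = np.random.default_rng(6)
        groups = [
            rng.normal(13.0, 1.0, 12),
            rng.normal(7.9, 1.0, 12),
            rng.normal(4.4, 1.0, 12),
        ]
        res = anova_tukey(groups)
        assert res.letters == ["a", "b", "c"]

    def test_letters_transitive_consistent(self):
        rng = np.random.default_rng(7)
        groups = [rng.normal(m, 1.0, 8) for m in (0.0, 1.2, 2.4, 3.6)]
        res = anova_tukey(groups)
        k = len(groups)
        for i in range(k):
            for j in range(i + 1, k):
                shares = bool(set(res.letters[i]) & set(res.letters[j]))
                assert shares == (not res.significant[i, j])


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def _cohort_with_layers(treatment: str, n_layers: int, n_barren: int) -> CohortStudy:
    recs = []
    for i in range(n_layers):
        eggs = (0, 2, 3, 0, 0, 0)
        recs.append(make_female(f"{treatment}-l{i}", treatment, longevity=6,
                                daily_eggs=eggs))
    for i in range(n_barren):
        recs.append(make_female(f"{treatment}-b{i}", treatment, longevity=6))
    recs.append(make_male(f"{treatment}-m", treatment))
    return CohortStudy(treatment, recs, n_initial_eggs=len(recs))


class TestSummaries:
    def test_identical_duration_vectors_share_letters(self):
        cohorts = [
            CohortStudy(t, [make_female(f"{t}{i}", t, daily_eggs=(1,))
                            for i in range(5)], n_initial_eggs=5)
            for t in ("d1", "d2", "d3")
        ]
        for summary in stage_duration_summary(cohorts):
            assert summary.test is not None
            assert summary.test.letters == ["a", "a", "a"]
            assert summary.ns == [5, 5, 5]

    def test_stage_n_counts_completers_only(self):
        recs = [make_female(f"f{i}", "d") for i in range(4)]
        recs.append(make_immature_death("dead", "d"))  # finished egg + n1 only
        cohorts = [
            CohortStudy("d", recs, n_initial_eggs=5),
            CohortStudy("e", [make_female(f"e{i}", "e") for i in range(5)],
                        n_initial_eggs=5),
        ]
        summaries = {s.variable: s for s in stage_duration_summary(cohorts)}
        assert summaries["egg"].ns == [5, 5]
        assert summaries["n2"].ns == [4, 5]
        assert summaries["total_immature"].ns == [4, 5]

    def test_layers_vs_all_female_counts(self):
        """fecundity n counts all adult females, oviposition n only layers."""
        cohorts = [_cohort_with_layers("aphidlike", 3, 4),
                   _cohort_with_layers("other", 5, 0)]
        summaries = {s.variable: s for s in reproductive_summary(cohorts)}
        assert summaries["fecundity"].ns == [7, 5]
        assert summaries["oviposition"].ns == [3, 5]
        assert summaries["longevity"].ns == [7, 5]
        # non-layers' zeros pull the fecundity mean down
        assert summaries["fecundity"].means[0] == pytest.approx(5 * 3 / 7)

    def test_all_layers_equal_counts(self):
        cohorts = [_cohort_with_layers("a", 4, 0), _cohort_with_layers("b", 4, 0)]
        summaries = {s.variable: s for s in reproductive_summary(cohorts)}
        assert summaries["fecundity"].ns == summaries["oviposition"].ns

    def test_zero_fecundity_treatment_periods_empty(self):
        cohorts = [_cohort_with_layers("none", 0, 3), _cohort_with_layers("b", 4, 0)]
        with pytest.warns(UserWarning):
            summaries = {s.variable: s for s in reproductive_summary(cohorts)}
        assert summaries["fecundity"].means[0] == 0.0
        assert np.isnan(summaries["oviposition"].means[0])
        assert summaries["oviposition"].ns[0] == 0

    def test_se_is_sd_over_sqrt_n(self):
        cohorts = [_cohort_with_layers("a", 4, 0), _cohort_with_layers("b", 3, 2)]
        summaries = {s.variable: s for s in reproductive_summary(cohorts)}
        fec = summaries["fecundity"]
        values = [5.0, 5.0, 5.0, 0.0, 0.0]
        assert fec.ses[1] == pytest.approx(np.std(values, ddof=1) / np.sqrt(5))


class TestOvipositionPeriods:
    def test_hand_example(self):
        f = make_female("f", longevity=10, daily_eggs=(0, 0, 4, 0, 5, 0, 0, 0, 0, 0))
        pre, ovi, post = oviposition_periods(f)
        assert (pre, ovi, post) == (2, 3, 5)
        assert pre + ovi + post == f.adult_longevity

    def test_non_layer_is_none(self):
        assert oviposition_periods(make_female("f")) is None


class TestHeadlineRatios:
    @staticmethod
    def summary(variable, means):
        treatments = list(means)
        return GroupSummary(
            variable=variable, treatments=treatments,
            means=[means[t] for t in treatments],
            ses=[0.0] * len(means), ns=[1] * len(means), test=None)

    def test_published_style_values(self):
        fec = self.summary("fecundity", {"mixed": 497.7, "aphids": 5.7})
        imm = self.summary("total_immature", {"mixed": 21.6, "aphids": 24.8})
        out = headline_ratios(fec, imm, focal="mixed", baseline="aphids")
        assert out["fold_change"] == 87.3
        assert out["percent_reduction"] == 13

    def test_identical_inputs(self):
        fec = self.summary("fecundity", {"a": 10.0, "b": 10.0})
        imm = self.summary("total_immature", {"a": 20.0, "b": 20.0})
        out = headline_ratios(fec, imm, focal="a", baseline="b")
        assert out["fold_change"] == 1.0
        assert out["percent_reduction"] == 0

    def test_zero_denominator_warns(self):
        fec = self.summary("fecundity", {"a": 10.0, "b": 0.0})
        imm = self.summary("total_immature", {"a": 20.0, "b": 20.0})
        with pytest.warns(UserWarning, match="fold change undefined"):
            out = headline_ratios(fec, imm, focal="a", baseline="b")
        assert np.isnan(out["fold_change"])
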