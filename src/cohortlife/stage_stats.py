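"""Stage-level descriptive statistics and hypothesis tests.

Stage-duration and reproductive-period summaries (mean, SE, n per
treatment) with the tests used in the source analyses:

* Kruskal-Wallis (tie corrected, chi-square reference) with
  Dwass-Steel-Critchlow-Fligner (DSCF) pairwise comparisons — stage
  durations, oviposition and postoviposition periods;
* one-way ANOVA with Tukey-Kramer pairwise comparisons — preoviposition
  period, female adult longevity and total fecundity.

The DSCF procedure re-ranks each pair of groups separately, standardises
the pairwise rank sum with a tie-corrected variance and refers
``sqrt(2) * |z|`` to the studentized range distribution with the *total*
number of groups and infinite df (the asymptotic reference).

Variable rules: oviposition-cycle periods are computed over ovipositing
females only, while longevity and total fecundity cover all adult females
(non-layers contribute zero fecundity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .letters import compact_letters
from .records import STAGES, CohortStudy, Fate

__all__ = [
    "GroupSummary",
    "TestResult",
    "kruskal_wallis_dscf",
    "anova_tukey",
    "stage_duration_summary",
    "reproductive_summary",
    "oviposition_periods",
    "headline_ratios",
]


@dataclass
class TestResult:
    """Omnibus test plus pairwise decisions for one variable."""

    method: str                # "kruskal_wallis_dscf" | "anova_tukey"
    statistic: float           # H or F
    df: tuple                  # (k-1,) for KW, (k-1, N-k) for ANOVA
    pvalue: float
    pairwise_pvalues: np.ndarray
    significant: np.ndarray
    letters: list[str]
    alpha: float


@dataclass
class GroupSummary:
    variable: str
    treatments: list[str]
    means: list[float]         # nan for empty cells
    ses: list[float]
    ns: list[int]
    test: TestResult | None
    tested_treatments: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def letter_for(self, treatment: str) -> str:
        if self.test is None or treatment not in self.tested_treatments:
            return ""
        return self.test.letters[self.tested_treatments.index(treatment)]


def _mean_se_n(values: Sequence[float]) -> tuple[float, float, int]:
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n == 0:
        return float("nan"), float("nan"), 0
    se = float(np.std(x, ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return float(x.mean()), se, n


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

def _dscf_pair(x: np.ndarray, y: np.ndarray, k: int) -> float:
    """Two-sided DSCF p-value for one pair out of k groups."""
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w = float(ranks[n1:].sum())            # rank sum of the second group
    n = n1 + n2
    expected = n2 * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0.0:
        return 1.0
    z = (w - expected) / np.sqrt(var)
    return float(stats.studentized_range.sf(np.sqrt(2.0) * abs(z), k, np.inf))


def kruskal_wallis_dscf(groups: Sequence[Sequence[float]], alpha: float = 0.05) -> TestResult:
    """Tie-corrected Kruskal-Wallis H with DSCF pairwise letters."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs n >= 2")

    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*groups)

    pvalues = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            pv = _dscf_pair(groups[i], groups[j], k)
            pvalues[i, j] = pvalues[j, i] = pv
    significant = pvalues < alpha
    np.fill_diagonal(significant, False)
    means = [float(g.mean()) for g in groups]
    return TestResult(
        method="kruskal_wallis_dscf", statistic=float(h), df=(k - 1,),
        pvalue=float(p), pairwise_pvalues=pvalues, significant=significant,
        letters=compact_letters(means, significant), alpha=alpha,
    )


def anova_tukey(groups: Sequence[Sequence[float]], alpha: float = 0.05) -> TestResult:
    """One-way fixed-effects ANOVA with Tukey-Kramer letters."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs n >= 2")

    n_total = sum(len(g) for g in groups)
    sse = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    grand = float(np.concatenate(groups).mean())
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    df_b, df_w = k - 1, n_total - k
    if sse == 0.0:
        f = 0.0 if ssb == 0.0 else float("inf")
        p = 1.0 if ssb == 0.0 else 0.0
        pvalues = np.where(
            np.abs(np.subtract.outer([g.mean() for g in groups],
                                     [g.mean() for g in groups])) > 0, 0.0, 1.0)
    else:
        f, p = stats.f_oneway(*groups)
        pvalues = stats.tukey_hsd(*groups).pvalue
    pvalues = np.asarray(pvalues, dtype=float)
    significant = pvalues < alpha
    np.fill_diagonal(significant, False)
    means = [float(g.mean()) for g in groups]
    return TestResult(
        method="anova_tukey", statistic=float(f), df=(df_b, df_w),
        pvalue=float(p), pairwise_pvalues=pvalues, significant=significant,
        letters=compact_letters(means, significant), alpha=alpha,
    )


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def _summarise(
    variable: str,
    treatments: list[str],
    values: list[list[float]],
    method: str,
    alpha: float,
    min_n: int = 2,
) -> GroupSummary:
    means, ses, ns = [], [], []
    for v in values:
        m, s, n = _mean_se_n(v)
        means.append(m)
        ses.append(s)
        ns.append(n)

    notes: list[str] = []
    testable = [i for i, v in enumerate(values) if len(v) >= min_n]
    dropped = [treatments[i] for i in range(len(values)) if i not in testable]
    for t in dropped:
        notes.append(f"{variable}: treatment {t!r} dropped from test (n < {min_n})")
        warnings.warn(notes[-1], stacklevel=3)

    test = None
    tested: list[str] = []
    if len(testable) >= 2:
        groups = [values[i] for i in testable]
        tested = [treatments[i] for i in testable]
        if method == "kruskal_wallis_dscf":
            test = kruskal_wallis_dscf(groups, alpha=alpha)
        else:
            test = anova_tukey(groups, alpha=alpha)
    return GroupSummary(
        variable=variable, treatments=treatments, means=means, ses=ses, ns=ns,
        test=test, tested_treatments=tested, warnings=notes,
    )


def stage_duration_summary(
    cohorts: Sequence[CohortStudy], alpha: float = 0.05
) -> list[GroupSummary]:
    """Per-stage development summaries plus the total immature period.

    Stage means include every individual that completed the stage (so
    immature deaths contribute to the stages they finished); the total
    immature period covers individuals reaching adulthood only.  Each
    variable is compared across treatments by Kruskal-Wallis with DSCF.
    """
    treatments = [c.treatment for c in cohorts]
    out: list[GroupSummary] = []
    for stage in STAGES:
        values = [
            [float(r.stage_durations[stage])
             for r in c.individuals if stage in r.stage_durations]
            for c in cohorts
        ]
        out.append(_summarise(stage, treatments, values, "kruskal_wallis_dscf", alpha))
    totals = [
        [float(r.immature_duration) for r in c.individuals if r.fate is Fate.ADULT]
        for c in cohorts
    ]
    out.append(_summarise("total_immature", treatments, totals, "kruskal_wallis_dscf", alpha))
    return out


def oviposition_periods(record) -> tuple[int, int, int] | None:
    """(preoviposition, oviposition, postoviposition) days for a layer.

    Days from emergence to first egg, first to last egg inclusive, and last
    egg to death; ``None`` for females that never laid.
    """
    if not record.oviposited:
        return None
    eggs = record.daily_eggs
    laying_days = [k for k, e in enumerate(eggs, start=1) if e > 0]
    first, last = laying_days[0], laying_days[-1]
    longevity = record.adult_longevity if record.adult_longevity is not None else len(eggs)
    return first - 1, last - first + 1, longevity - last


_REPRO_TESTS = {
    "preoviposition": "anova_tukey",
    "oviposition": "kruskal_wallis_dscf",
    "postoviposition": "kruskal_wallis_dscf",
    "longevity": "anova_tukey",
    "fecundity": "anova_tukey",
}


def reproductive_summary(
    cohorts: Sequence[CohortStudy], alpha: float = 0.05
) -> list[GroupSummary]:
    """Reproductive-period, longevity and fecundity summaries per treatment."""
    treatments = [c.treatment for c in cohorts]
    per_var: dict[str, list[list[float]]] = {v: [] for v in _REPRO_TESTS}
    for c in cohorts:
        pre, ovi, post, lon, fec = [], [], [], [], []
        for f in c.females:
            if f.adult_longevity is not None:
                lon.append(float(f.adult_longevity))
            fec.append(float(f.total_eggs))
            periods = oviposition_periods(f)
            if periods is not None:
                pre.append(float(periods[0]))
                ovi.append(float(periods[1]))
                post.append(float(periods[2]))
        per_var["preoviposition"].append(pre)
        per_var["oviposition"].append(ovi)
        per_var["postoviposition"].append(post)
        per_var["longevity"].append(lon)
        per_var["fecundity"].append(fec)
    return [
        _summarise(var, treatments, per_var[var], method, alpha)
        for var, method in _REPRO_TESTS.items()
    ]


def headline_ratios(
    fecundity: GroupSummary,
    total_immature: GroupSummary,
    focal: str,
    baseline: str,
) -> dict[str, float]:
    """Fold change in fecundity and percent reduction in immature duration.

    ``fold_change`` = focal fecundity mean / baseline mean, 1 d.p.;
    ``percent_reduction`` = 100 * (1 - focal immature mean / baseline mean),
    nearest integer.
    """
    def cell(summary: GroupSummary, treatment: str) -> float:
        if treatment not in summary.treatments:
            raise KeyError(f"treatment {treatment!r} not in {summary.variable} summary")
        return summary.means[summary.treatments.index(treatment)]

    fec_f, fec_b = cell(fecundity, focal), cell(fecundity, baseline)
    imm_f, imm_b = cell(total_immature, focal), cell(total_immature, baseline)
    out: dict[str, float] = {}
    if fec_b == 0 or not np.isfinite(fec_b):
        warnings.warn("fold change undefined: zero/missing baseline fecundity", stacklevel=2)
        out["fold_change"] = float("nan")
    else:
        out["fold_change"] = round(fec_f / fec_b, 1)
    if imm_b == 0 or not np.isfinite(imm_b):
        warnings.warn("percent reduction undefined: zero/missing baseline duration", stacklevel=2)
        out["percent_reduction"] = float("nan")
    else:
        out["percent_reduction"] = float(round(100.0 * (1.0 - imm_f / imm_b)))
    return out
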