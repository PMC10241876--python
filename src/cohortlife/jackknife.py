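"""Leave-one-out jackknife estimation of demographic parameters.

For a cohort of ``n`` deletion units the whole pipeline (census ->
schedules -> parameters) is rerun with each unit omitted, giving the
leave-one-out estimates ``theta_(-i)``.  The pseudo-value for unit ``i`` is

    pv_i = n * theta_all - (n - 1) * theta_(-i)

and the jackknife estimate and standard error are the mean of the
pseudo-values and ``sqrt(sum((pv - mean(pv))^2) / (n (n - 1)))``.

Treatments are compared parameter by parameter with Tukey's studentized
range test on the pseudo-values (Tukey-Kramer for unequal n).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
from scipy.stats import studentized_range

from .demography import UndefinedParameterError, compute_params
from .letters import compact_letters
from .records import CohortStudy, Fate
from .schedules import AgeOrigin, build_schedule, census_quantities

__all__ = [
    "PARAMETERS",
    "JackknifeEstimate",
    "TukeyComparison",
    "jackknife_parameters",
    "jackknife_statistic",
    "compare_treatments",
]

#: The four parameters reported per treatment, in display order.
PARAMETERS = ("R0", "T", "rm", "lam")

JackknifeUnit = Literal["individual", "female"]


@dataclass
class JackknifeEstimate:
    parameter: str
    treatment: str
    theta_all: float
    pseudo_values: np.ndarray
    n_units: int
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pseudo_values = np.asarray(self.pseudo_values, dtype=float)
        if len(self.pseudo_values) != self.n_units:
            raise ValueError("pseudo_values length must equal n_units")

    @property
    def theta_jack(self) -> float:
        return float(np.mean(self.pseudo_values))

    @property
    def se(self) -> float:
        n = self.n_units
        if n < 2:
            return float("nan")
        dev = self.pseudo_values - self.theta_jack
        return float(np.sqrt(np.sum(dev * dev) / (n * (n - 1))))


def _params_or_zero(cohort: CohortStudy, age_origin: str, tol: float) -> dict[str, float | None]:
    """Pipeline run for one (sub)cohort.

    Returns a value per parameter; ``R0`` is always defined (0 for a cohort
    with no reproduction), the other three are ``None`` when undefined.
    """
    schedule = build_schedule(cohort, age_origin)
    try:
        p = compute_params(schedule, tol=tol)
        return {"R0": p.r0, "T": p.t, "rm": p.rm, "lam": p.lam}
    except UndefinedParameterError:
        r0 = float(np.sum(schedule.lx * schedule.mx))
        return {"R0": r0, "T": None, "rm": None, "lam": None}


def _deletion_units(cohort: CohortStudy, unit: JackknifeUnit) -> list[int]:
    if unit == "individual":
        return list(range(len(cohort.individuals)))
    if unit == "female":
        return [i for i, r in enumerate(cohort.individuals) if r.is_adult_female]
    raise ValueError(f"unknown jackknife unit {unit!r}")


def _drop(cohort: CohortStudy, index: int) -> CohortStudy:
    kept = [r for i, r in enumerate(cohort.individuals) if i != index]
    return CohortStudy(
        treatment=cohort.treatment, individuals=kept,
        n_initial_eggs=cohort.n_initial_eggs - 1,
    )


def jackknife_parameters(
    cohort: CohortStudy,
    unit: JackknifeUnit = "individual",
    age_origin: AgeOrigin = "egg",
    tol: float = 1e-10,
) -> dict[str, JackknifeEstimate]:
    """Jackknife all four parameters for one treatment cohort.

    ``unit="individual"`` deletes every post-exclusion record (immature
    deaths and males included, so that SURV and SR vary across replicates);
    ``unit="female"`` deletes adult females only.  A replicate whose reduced
    cohort has no reproduction contributes ``theta = 0`` to the R0
    pseudo-values (flagged) while its T/rm/lam pseudo-values are dropped,
    shrinking those parameters' n.
    """
    if any(r.fate is Fate.LOST for r in cohort.individuals):
        raise ValueError("cohort contains lost records; run apply_exclusions first")
    units = _deletion_units(cohort, unit)
    n = len(units)
    if n < 2:
        raise ValueError(f"jackknife needs >= 2 deletion units, found {n}")

    theta_all = _params_or_zero(cohort, age_origin, tol)
    if theta_all["rm"] is None:
        warnings.warn(
            f"{cohort.treatment}: full-sample rm/T/lam undefined (R0 = 0 or no "
            "reproduction past age 0); only R0 will be jackknifed",
            stacklevel=2,
        )

    loo: dict[str, list[float]] = {p: [] for p in PARAMETERS}
    notes: dict[str, list[str]] = {p: [] for p in PARAMETERS}
    for i in units:
        theta_i = _params_or_zero(_drop(cohort, i), age_origin, tol)
        rid = cohort.individuals[i].id
        for p in PARAMETERS:
            if theta_all[p] is None:
                continue
            if theta_i[p] is None:
                if p == "R0":  # cannot happen: R0 always defined
                    raise AssertionError
                notes[p].append(
                    f"replicate without {rid} has no reproduction: {p} pseudo-value dropped"
                )
                continue
            loo[p].append(n * theta_all[p] - (n - 1) * theta_i[p])
        if theta_i["R0"] == 0.0:
            notes["R0"].append(
                f"replicate without {rid} has R0 = 0 (last reproducing female removed)"
            )

    out: dict[str, JackknifeEstimate] = {}
    for p in PARAMETERS:
        if theta_all[p] is None:
            continue
        pv = np.asarray(loo[p], dtype=float)
        if len(pv) < len(units):
            notes[p].append(f"n reduced from {len(units)} to {len(pv)}")
        out[p] = JackknifeEstimate(
            parameter=p, treatment=cohort.treatment, theta_all=theta_all[p],
            pseudo_values=pv, n_units=len(pv), warnings=notes[p],
        )
        for msg in notes[p]:
            warnings.warn(f"{cohort.treatment}/{p}: {msg}", stacklevel=2)
    return out


def jackknife_statistic(
    values: Sequence[float],
    stat: Callable[[np.ndarray], float] = np.mean,
    label: str = "stat",
    treatment: str = "",
) -> JackknifeEstimate:
    """Jackknife an arbitrary statistic of a 1-D sample.

    Used as an internal oracle: for a linear statistic (the mean) the
    jackknife SE equals the classical SE of the mean exactly.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 observations")
    theta_all = float(stat(x))
    pv = np.empty(n)
    for i in range(n):
        theta_i = float(stat(np.delete(x, i)))
        pv[i] = n * theta_all - (n - 1) * theta_i
    return JackknifeEstimate(
        parameter=label, treatment=treatment, theta_all=theta_all,
        pseudo_values=pv, n_units=n,
    )


@dataclass
class TukeyComparison:
    """Tukey's studentized range test across treatments on pseudo-values."""

    parameter: str
    treatments: list[str]
    means: np.ndarray
    ns: np.ndarray
    mse: float
    df: int
    pvalues: np.ndarray        # (k, k), 1.0 on the diagonal
    significant: np.ndarray    # (k, k) bool at alpha
    letters: list[str]
    alpha: float
    warnings: list[str] = field(default_factory=list)


def compare_treatments(
    estimates: Sequence[JackknifeEstimate], alpha: float = 0.05
) -> TukeyComparison:
    """One-way Tukey-Kramer comparison of one parameter across treatments.

    Operates on the jackknife pseudo-values: group means are the jackknife
    estimates, the pooled error variance comes from the within-treatment
    pseudo-value scatter, and the studentized range reference uses
    ``df = sum(n_i - 1)``.
    """
    params = {e.parameter for e in estimates}
    if len(params) != 1:
        raise ValueError(f"estimates mix parameters: {sorted(params)}")
    parameter = params.pop()

    notes: list[str] = []
    kept: list[JackknifeEstimate] = []
    for e in estimates:
        if e.n_units < 2:
            notes.append(f"{e.treatment}: excluded ({e.n_units} pseudo-value(s))")
            warnings.warn(f"{parameter}: {notes[-1]}", stacklevel=2)
        else:
            kept.append(e)
    if len(kept) < 2:
        raise ValueError("need >= 2 treatments with >= 2 pseudo-values each")

    groups = [e.pseudo_values for e in kept]
    names = [e.treatment for e in kept]
    ns = np.array([len(g) for g in groups])
    means = np.array([g.mean() for g in groups])
    df = int(np.sum(ns - 1))
    sse = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    mse = sse / df if df > 0 else 0.0

    k = len(groups)
    pvalues = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            denom = np.sqrt(mse / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            if denom == 0.0:
                p = 1.0 if means[i] == means[j] else 0.0
            else:
                q = abs(means[i] - means[j]) / denom
                p = float(studentized_range.sf(q, k, df))
            pvalues[i, j] = pvalues[j, i] = p
    significant = pvalues < alpha
    np.fill_diagonal(significant, False)
    letters = compact_letters(means, significant)

    return TukeyComparison(
        parameter=parameter, treatments=names, means=means, ns=ns,
        mse=mse, df=df, pvalues=pvalues, significant=significant,
        letters=letters, alpha=alpha, warnings=notes,
    )
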