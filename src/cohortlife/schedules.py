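"""Age-specific survival (l_x) and fecundity (m_x) schedules.

The female-based bookkeeping:

* ``SURV``  — egg-to-adult survival fraction of the cohort,
* ``SR``    — proportion female among emerged adults,
* ``NF``    — initial number of adult females,
* ``NSF_x`` — number of those females still alive at age ``x``,
* ``l_x  = SURV * NSF_x / NF``,
* ``m_x  = NEGG_x * SR`` with ``NEGG_x`` the mean eggs laid per *living*
  female at age ``x``.

Using living females as the ``NEGG_x`` denominator makes the conservation
identity exact:  ``sum_x l_x m_x = SURV * SR * (total eggs) / NF``.

Age conventions
---------------
``age_origin="egg"``: day 0 is deposition of the focal egg; an eventual
female counts as alive throughout her immature period, so ``l_x = SURV``
before the first emergence.  ``age_origin="adult_emergence"``: day 0 is each
female's own emergence day.  Either way a female dying on day ``d`` is alive
at ages ``< d`` and dead at ``d``, and the schedule is truncated at the last
age with any female alive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .records import CohortStudy, Fate

__all__ = [
    "AgeOrigin",
    "Schedule",
    "census_quantities",
    "build_lx",
    "build_mx",
    "build_schedule",
    "export_schedule",
    "schedule_from_rows",
    "reproductive_sum",
]

AgeOrigin = Literal["egg", "adult_emergence"]

_VALID_ORIGINS = ("egg", "adult_emergence")


class DegenerateCohortError(ValueError):
    """No adult females: l_x/m_x schedules cannot be built the normal way."""


@dataclass
class Schedule:
    """Paired age-indexed survival and fecundity vectors."""

    ages: np.ndarray          # contiguous integer days 0..X
    lx: np.ndarray            # fraction alive, in [0, 1], non-increasing
    mx: np.ndarray            # expected daughters per female per day, >= 0
    age_origin: str = "egg"
    surv: float = float("nan")
    sr: float = float("nan")
    nf: int = 0
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=int)
        self.lx = np.asarray(self.lx, dtype=float)
        self.mx = np.asarray(self.mx, dtype=float)
        if not (len(self.ages) == len(self.lx) == len(self.mx)):
            raise ValueError("ages, lx, mx must have equal length")
        if len(self.ages) and np.any(np.diff(self.ages) != 1):
            raise ValueError("ages must be contiguous integers")
        if self.age_origin not in _VALID_ORIGINS:
            raise ValueError(f"age_origin must be one of {_VALID_ORIGINS}")

    def __len__(self) -> int:
        return len(self.ages)


def census_quantities(cohort: CohortStudy) -> tuple[float, float, int]:
    """Return ``(SURV, SR, NF)`` for a post-exclusion cohort."""
    if any(r.fate is Fate.LOST for r in cohort.individuals):
        raise ValueError("cohort contains lost records; run apply_exclusions first")
    return cohort.surv, cohort.sr, cohort.nf


def _female_spans(cohort: CohortStudy, age_origin: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-female (emergence_age, death_age) under the chosen origin.

    A female is alive at ages in ``[0, death_age)`` and lays her adult-day-k
    eggs at age ``emergence_age + k - 1``.
    """
    emergence = []
    death = []
    for f in cohort.females:
        if f.adult_longevity is None:
            raise ValueError(f"{f.id}: adult female without longevity")
        if age_origin == "egg":
            e = f.immature_duration
        else:
            e = 0
        emergence.append(e)
        death.append(e + f.adult_longevity)
    return np.asarray(emergence, dtype=int), np.asarray(death, dtype=int)


def _nsf(cohort: CohortStudy, age_origin: str) -> np.ndarray:
    """Number of surviving females at each age 0..last-alive-age."""
    _, death = _female_spans(cohort, age_origin)
    if len(death) == 0:
        raise DegenerateCohortError("no adult females in cohort")
    max_age = int(death.max())  # last alive age is max_age - 1
    ages = np.arange(max_age)
    return (death[None, :] > ages[:, None]).sum(axis=1)


def build_lx(cohort: CohortStudy, age_origin: AgeOrigin = "egg") -> np.ndarray:
    """Age-specific survival: ``SURV * NSF_x / NF`` per age."""
    if age_origin not in _VALID_ORIGINS:
        raise ValueError(f"age_origin must be one of {_VALID_ORIGINS}")
    surv, _, nf = census_quantities(cohort)
    if nf == 0:
        raise DegenerateCohortError(
            "NF = 0: no adult females; use build_schedule for the degenerate path"
        )
    return surv * _nsf(cohort, age_origin) / nf


def build_mx(cohort: CohortStudy, age_origin: AgeOrigin = "egg") -> np.ndarray:
    """Age-specific fecundity: mean eggs per living female times sex ratio."""
    if age_origin not in _VALID_ORIGINS:
        raise ValueError(f"age_origin must be one of {_VALID_ORIGINS}")
    _, sr, nf = census_quantities(cohort)
    if nf == 0:
        raise DegenerateCohortError("NF = 0: no adult females")
    nsf = _nsf(cohort, age_origin)
    total_eggs = np.zeros(len(nsf), dtype=float)
    emergence, _ = _female_spans(cohort, age_origin)
    for f, e in zip(cohort.females, emergence):
        if f.daily_eggs is None:
            continue
        if any(n < 0 for n in f.daily_eggs):
            raise ValueError(f"{f.id}: negative daily egg count")
        for k, eggs in enumerate(f.daily_eggs, start=1):
            total_eggs[e + k - 1] += eggs
    with np.errstate(invalid="ignore", divide="ignore"):
        negg = np.where(nsf > 0, total_eggs / np.maximum(nsf, 1), 0.0)
    return negg * sr


def build_schedule(cohort: CohortStudy, age_origin: AgeOrigin = "egg") -> Schedule:
    """Full l_x/m_x schedule for a post-exclusion cohort.

    A cohort with no adult females yields a flagged degenerate single-age
    schedule with ``m_x = 0`` everywhere rather than an error, so that
    downstream code can still report ``R0 = 0``.
    """
    surv, sr, nf = census_quantities(cohort)
    if nf == 0:
        return Schedule(
            ages=np.array([0]), lx=np.array([surv]), mx=np.array([0.0]),
            age_origin=age_origin, surv=surv, sr=sr, nf=0, degenerate=True,
        )
    lx = build_lx(cohort, age_origin)
    mx = build_mx(cohort, age_origin)
    return Schedule(
        ages=np.arange(len(lx)), lx=lx, mx=mx,
        age_origin=age_origin, surv=surv, sr=sr, nf=nf,
    )


def reproductive_sum(cohort: CohortStudy) -> float:
    """Right-hand side of the conservation identity.

    ``SURV * SR * (total eggs laid by all NF females) / NF`` — must equal
    ``sum_x l_x m_x`` to machine precision for any cohort.
    """
    surv, sr, nf = census_quantities(cohort)
    if nf == 0:
        return 0.0
    total = sum(f.total_eggs for f in cohort.females)
    return surv * sr * total / nf


def export_schedule(schedule: Schedule) -> list[tuple[int, float, float]]:
    """One ``(x, lx, mx)`` row per age, full precision."""
    return [
        (int(x), float(l), float(m))
        for x, l, m in zip(schedule.ages, schedule.lx, schedule.mx)
    ]


def schedule_from_rows(
    rows, age_origin: AgeOrigin = "egg", surv: float = float("nan"),
    sr: float = float("nan"), nf: int = 0,
) -> Schedule:
    """Inverse of :func:`export_schedule`."""
    rows = list(rows)
    return Schedule(
        ages=np.array([r[0] for r in rows], dtype=int),
        lx=np.array([r[1] for r in rows], dtype=float),
        mx=np.array([r[2] for r in rows], dtype=float),
        age_origin=age_origin, surv=surv, sr=sr, nf=nf,
    )
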