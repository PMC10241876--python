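"""Individual rearing records and treatment cohorts.

Data model for daily-census rearing studies: one :class:`IndividualRecord`
per reared individual (stage durations, fate, sex, adult longevity, daily
egg counts) grouped into treatment-level :class:`CohortStudy` objects, with
CSV readers/writers, validation, and the lost-individual exclusion rule.

Conventions
-----------
* Stage durations are integer days (>= 1); the census is daily, so sub-daily
  resolution is rejected at parse time.
* A duration is *absent* for the stage in which an individual died, and for
  all later stages.
* ``daily_eggs`` is indexed by adult age: element ``i`` is the number of
  eggs laid on the ``i+1``-th day of adult life.  In the fecundity CSV this
  index appears as ``age_day`` (1-based).
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "STAGES",
    "Fate",
    "Sex",
    "IndividualRecord",
    "CohortStudy",
    "ValidationReport",
    "CohortDataError",
    "read_cohort_csv",
    "write_cohort_csv",
    "apply_exclusions",
    "validate_cohort",
]

#: Immature life stages, in developmental order.
STAGES = ("egg", "n1", "n2", "n3", "n4", "n5")


class CohortDataError(ValueError):
    """Raised on malformed or referentially inconsistent cohort input."""


class Fate(str, Enum):
    ADULT = "adult"
    DIED_IMMATURE = "died_immature"
    LOST = "lost"


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class IndividualRecord:
    """One reared individual.

    Parameters
    ----------
    id : str
        Unique identifier within the study.
    treatment : str
        Treatment (diet) label.
    fate : Fate
        ``adult`` if the individual emerged, ``died_immature`` if it died
        during an immature stage, ``lost`` if it was lost from the census
        (lost records are discarded before analysis).
    sex : Sex
        Known only for emerged adults; ``unknown`` is allowed (and typical)
        for immature deaths.
    stage_durations : dict
        Map stage name -> integer days spent in that stage.  Stages after
        (and including) the stage of death are absent.
    adult_longevity : int or None
        Days of adult life (females only).
    daily_eggs : tuple of int or None
        Egg count per adult day, element ``i`` = adult day ``i+1``.  Only
        present for adult females; ``None`` means no fecundity record (an
        adult female with ``None`` contributes zero fecundity).
    """

    id: str
    treatment: str
    fate: Fate
    sex: Sex = Sex.UNKNOWN
    stage_durations: dict[str, int] = field(default_factory=dict)
    adult_longevity: int | None = None
    daily_eggs: tuple[int, ...] | None = None

    @property
    def oviposited(self) -> bool:
        """True if any daily egg count is positive."""
        return self.daily_eggs is not None and sum(self.daily_eggs) > 0

    @property
    def total_eggs(self) -> int:
        return 0 if self.daily_eggs is None else int(sum(self.daily_eggs))

    @property
    def is_adult_female(self) -> bool:
        return self.fate is Fate.ADULT and self.sex is Sex.FEMALE

    @property
    def immature_duration(self) -> int:
        """Total days from egg to adult emergence.

        Only defined for individuals that completed every immature stage.
        """
        if self.fate is not Fate.ADULT:
            raise ValueError(f"{self.id}: immature duration undefined for fate={self.fate.value}")
        return sum(self.stage_durations[s] for s in STAGES)

    def death_age(self) -> int:
        """Age (days since egg deposition) at which the female is first dead.

        A female dying on day ``d`` counts as alive at ages ``< d`` and dead
        at ``d`` (death-day exclusive).
        """
        if not self.is_adult_female or self.adult_longevity is None:
            raise ValueError(f"{self.id}: death age defined only for adult females with longevity")
        return self.immature_duration + self.adult_longevity


@dataclass
class CohortStudy:
    """A treatment-labelled collection of individuals plus census metadata."""

    treatment: str
    individuals: list[IndividualRecord]
    n_initial_eggs: int

    # --- census quantities (derived; cheap enough to recompute on access) ---

    @property
    def adults(self) -> list[IndividualRecord]:
        return [r for r in self.individuals if r.fate is Fate.ADULT]

    @property
    def females(self) -> list[IndividualRecord]:
        return [r for r in self.adults if r.sex is Sex.FEMALE]

    @property
    def nf(self) -> int:
        """Initial number of adult females."""
        return len(self.females)

    @property
    def surv(self) -> float:
        """Egg-to-adult survival fraction."""
        if self.n_initial_eggs == 0:
            return 0.0
        return len(self.adults) / self.n_initial_eggs

    @property
    def sr(self) -> float:
        """Sex ratio: proportion female among emerged adults."""
        adults = self.adults
        if not adults:
            return 0.0
        return len(self.females) / len(adults)

    @property
    def degenerate(self) -> bool:
        """True when no adults (or no females) emerged: fecundity undefined."""
        return self.nf == 0

    def __len__(self) -> int:
        return len(self.individuals)


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __bool__(self) -> bool:  # truthy == valid
        return self.ok


# ---------------------------------------------------------------------------
# exclusion rule
# ---------------------------------------------------------------------------

def apply_exclusions(cohort: CohortStudy) -> CohortStudy:
    """Discard records lost during the experiment.

    Returns a new cohort with all ``fate=lost`` records removed and
    ``n_initial_eggs`` reduced by the number removed, so that lost
    individuals never enter the survival denominator.  Idempotent.
    """
    kept = [r for r in cohort.individuals if r.fate is not Fate.LOST]
    n_lost = len(cohort.individuals) - len(kept)
    return CohortStudy(
        treatment=cohort.treatment,
        individuals=kept,
        n_initial_eggs=cohort.n_initial_eggs - n_lost,
    )


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def _validate_record(r: IndividualRecord) -> Iterable[str]:
    known = set(r.stage_durations)
    unknown = known - set(STAGES)
    if unknown:
        yield f"{r.id}: unknown stage names {sorted(unknown)}"
    for s, d in r.stage_durations.items():
        if not isinstance(d, int) or d < 1:
            yield f"{r.id}: stage {s} duration {d!r} is not an integer >= 1"
    # durations must be a prefix of the stage sequence
    present = [s in known for s in STAGES]
    if any(present) and not all(present):
        first_absent = present.index(False)
        if any(present[first_absent:]):
            yield f"{r.id}: stage durations are not a contiguous prefix of {STAGES}"
    if r.fate is Fate.ADULT and not all(present):
        yield f"{r.id}: fate=adult but not all six stage durations present"
    if r.fate is not Fate.ADULT and all(present):
        yield f"{r.id}: all stage durations present but fate={r.fate.value}"
    if r.fate is Fate.ADULT and r.sex is Sex.UNKNOWN:
        yield f"{r.id}: emerged adult with unknown sex"
    if r.daily_eggs is not None:
        if r.sex is not Sex.FEMALE or r.fate is not Fate.ADULT:
            yield f"{r.id}: daily egg record on a non-(adult female) individual"
        if any((not isinstance(e, int)) or e < 0 for e in r.daily_eggs):
            yield f"{r.id}: daily egg counts must be non-negative integers"
    if r.adult_longevity is not None:
        if r.adult_longevity < 1:
            yield f"{r.id}: adult longevity {r.adult_longevity} < 1"
        if r.sex is not Sex.FEMALE:
            yield f"{r.id}: adult longevity recorded for a non-female"
    if r.is_adult_female and r.adult_longevity is None:
        yield f"{r.id}: adult female without adult longevity"
    if (
        r.daily_eggs is not None
        and r.adult_longevity is not None
        and len(r.daily_eggs) > r.adult_longevity
    ):
        yield (
            f"{r.id}: egg-laying record spans {len(r.daily_eggs)} adult days "
            f"but adult longevity is {r.adult_longevity}"
        )


def validate_cohort(cohort: CohortStudy) -> ValidationReport:
    """Check every type invariant; reports violations, never raises."""
    out: list[str] = []
    seen: set[str] = set()
    for r in cohort.individuals:
        if r.id in seen:
            out.append(f"{r.id}: duplicate individual id")
        seen.add(r.id)
        if r.treatment != cohort.treatment:
            out.append(f"{r.id}: treatment {r.treatment!r} != cohort {cohort.treatment!r}")
        out.extend(_validate_record(r))
    if len(cohort.individuals) > cohort.n_initial_eggs:
        out.append(
            f"cohort {cohort.treatment!r}: {len(cohort.individuals)} records exceed "
            f"n_initial_eggs={cohort.n_initial_eggs}"
        )
    if not cohort.individuals:
        out.append(f"cohort {cohort.treatment!r}: no usable records")
    return ValidationReport(out)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

INDIVIDUALS_HEADER = [
    "id", "treatment", "fate", "sex",
    "dur_egg", "dur_n1", "dur_n2", "dur_n3", "dur_n4", "dur_n5",
    "adult_longevity",
]
FECUNDITY_HEADER = ["id", "age_day", "eggs"]


def _parse_int(value: str, what: str, line: int, minimum: int = 0) -> int | None:
    if value == "":
        return None
    try:
        n = int(value)
    except ValueError:
        raise CohortDataError(f"line {line}: {what} {value!r} is not an integer") from None
    if n < minimum:
        raise CohortDataError(f"line {line}: {what} {n} < {minimum}")
    return n


def read_cohort_csv(individuals_path: str | Path, fecundity_path: str | Path) -> list[CohortStudy]:
    """Read the two-file CSV representation into one cohort per treatment.

    Daily egg counts from the long-format fecundity file are joined onto
    female records by ``id``.  Referential or schema problems raise
    :class:`CohortDataError` naming the offending line.
    """
    individuals_path = Path(individuals_path)
    fecundity_path = Path(fecundity_path)

    raw: dict[str, dict] = {}
    order: list[str] = []
    with individuals_path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != INDIVIDUALS_HEADER:
            raise CohortDataError(
                f"{individuals_path}: bad header {header!r}, expected {INDIVIDUALS_HEADER!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(INDIVIDUALS_HEADER):
                raise CohortDataError(
                    f"line {lineno}: expected {len(INDIVIDUALS_HEADER)} fields, got {len(row)}"
                )
            rid, treatment, fate_s, sex_s, *durs, longevity_s = row
            if rid == "":
                raise CohortDataError(f"line {lineno}: empty id")
            if rid in raw:
                raise CohortDataError(f"line {lineno}: duplicate id {rid!r}")
            try:
                fate = Fate(fate_s)
            except ValueError:
                raise CohortDataError(f"line {lineno}: unknown fate {fate_s!r}") from None
            try:
                sex = Sex(sex_s) if sex_s else Sex.UNKNOWN
            except ValueError:
                raise CohortDataError(f"line {lineno}: unknown sex {sex_s!r}") from None
            durations: dict[str, int] = {}
            for stage, cell in zip(STAGES, durs):
                d = _parse_int(cell, f"duration of stage {stage}", lineno, minimum=1)
                if d is not None:
                    durations[stage] = d
            longevity = _parse_int(longevity_s, "adult_longevity", lineno, minimum=1)
            raw[rid] = dict(
                treatment=treatment, fate=fate, sex=sex,
                stage_durations=durations, adult_longevity=longevity,
            )
            order.append(rid)

    eggs_by_id: dict[str, dict[int, int]] = {}
    with fecundity_path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != FECUNDITY_HEADER:
            raise CohortDataError(
                f"{fecundity_path}: bad header {header!r}, expected {FECUNDITY_HEADER!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 3:
                raise CohortDataError(f"line {lineno}: expected 3 fields, got {len(row)}")
            rid, day_s, eggs_s = row
            if rid not in raw:
                raise CohortDataError(f"line {lineno}: fecundity row for unknown id {rid!r}")
            info = raw[rid]
            if info["fate"] is not Fate.ADULT or info["sex"] is not Sex.FEMALE:
                raise CohortDataError(
                    f"line {lineno}: fecundity row for id {rid!r}, which is not an adult female"
                )
            day = _parse_int(day_s, "age_day", lineno, minimum=1)
            eggs = _parse_int(eggs_s, "eggs", lineno, minimum=0)
            if day is None or eggs is None:
                raise CohortDataError(f"line {lineno}: empty age_day or eggs field")
            per = eggs_by_id.setdefault(rid, {})
            if day in per:
                raise CohortDataError(f"line {lineno}: duplicate age_day {day} for id {rid!r}")
            per[day] = eggs

    records: dict[str, list[IndividualRecord]] = {}
    treatment_order: list[str] = []
    for rid in order:
        info = raw[rid]
        daily: tuple[int, ...] | None = None
        if rid in eggs_by_id:
            per = eggs_by_id[rid]
            last = max(per)
            daily = tuple(per.get(day, 0) for day in range(1, last + 1))
        rec = IndividualRecord(
            id=rid,
            treatment=info["treatment"],
            fate=info["fate"],
            sex=info["sex"],
            stage_durations=info["stage_durations"],
            adult_longevity=info["adult_longevity"],
            daily_eggs=daily,
        )
        if rec.treatment not in records:
            records[rec.treatment] = []
            treatment_order.append(rec.treatment)
        records[rec.treatment].append(rec)

    return [
        CohortStudy(treatment=t, individuals=records[t], n_initial_eggs=len(records[t]))
        for t in treatment_order
    ]


def write_cohort_csv(
    cohorts: Sequence[CohortStudy],
    individuals_path: str | Path,
    fecundity_path: str | Path,
) -> None:
    """Write cohorts using the same dialect the reader accepts.

    Every day of each present egg-laying record is written, including zero
    days, so a write/read round trip reproduces ``daily_eggs`` exactly.
    """

    def fmt(v: int | None) -> str:
        return "" if v is None else str(v)

    ind_buf = io.StringIO()
    fec_buf = io.StringIO()
    iw = csv.writer(ind_buf, lineterminator="\n")
    fw = csv.writer(fec_buf, lineterminator="\n")
    iw.writerow(INDIVIDUALS_HEADER)
    fw.writerow(FECUNDITY_HEADER)
    for cohort in cohorts:
        for r in cohort.individuals:
            iw.writerow(
                [r.id, r.treatment, r.fate.value, r.sex.value]
                + [fmt(r.stage_durations.get(s)) for s in STAGES]
                + [fmt(r.adult_longevity)]
            )
            if r.daily_eggs is not None:
                for i, eggs in enumerate(r.daily_eggs, start=1):
                    fw.writerow([r.id, i, eggs])
    Path(individuals_path).write_text(ind_buf.getvalue(), encoding="utf-8")
    Path(fecundity_path).write_text(fec_buf.getvalue(), encoding="utf-8")


def relabel(record: IndividualRecord, **changes) -> IndividualRecord:
    """Return a copy of *record* with the given fields replaced."""
    return replace(record, **changes)
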