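"""Shared fixtures: hand-built toy cohorts and simulated ones."""

from __future__ import annotations

import pytest

from cohortlife.records import CohortStudy, Fate, IndividualRecord, Sex
from cohortlife.simulate import preset_configs, simulate_cohort


def make_female(
    rid: str,
    treatment: str = "t",
    immature: dict[str, int] | None = None,
    longevity: int = 10,
    daily_eggs: tuple[int, ...] | None = None,
) -> IndividualRecord:
    durations = immature or {"egg": 8, "n1": 3, "n2": 2, "n3": 2, "n4": 3, "n5": 5}
    return IndividualRecord(
        id=rid, treatment=treatment, fate=Fate.ADULT, sex=Sex.FEMALE,
        stage_durations=durations, adult_longevity=longevity, daily_eggs=daily_eggs,
    )


def make_male(rid: str, treatment: str = "t") -> IndividualRecord:
    return IndividualRecord(
        id=rid, treatment=treatment, fate=Fate.ADULT, sex=Sex.MALE,
        stage_durations={"egg": 8, "n1": 3, "n2": 2, "n3": 2, "n4": 3, "n5": 5},
    )


def make_immature_death(rid: str, treatment: str = "t") -> IndividualRecord:
    return IndividualRecord(
        id=rid, treatment=treatment, fate=Fate.DIED_IMMATURE, sex=Sex.UNKNOWN,
        stage_durations={"egg": 8, "n1": 3},
    )


def make_lost(rid: str, treatment: str = "t") -> IndividualRecord:
    return IndividualRecord(
        id=rid, treatment=treatment, fate=Fate.LOST, sex=Sex.UNKNOWN,
        stage_durations={"egg": 8},
    )


@pytest.fixture
def single_female_cohort() -> CohortStudy:
    """One female laying 4 eggs/day for 5 days; SURV = 1, SR = 1."""
    eggs = (0, 0, 4, 4, 4, 4, 4, 0, 0, 0)
    female = make_female("f1", longevity=10, daily_eggs=eggs)
    return CohortStudy(treatment="t", individuals=[female], n_initial_eggs=1)


@pytest.fixture
def identical_females_cohort() -> CohortStudy:
    """Five byte-identical females: every jackknife SE must be zero."""
    eggs = (0, 4, 4, 4, 4, 4, 0, 0)
    females = [make_female(f"f{i}", longevity=8, daily_eggs=eggs) for i in range(5)]
    return CohortStudy(treatment="t", individuals=females, n_initial_eggs=5)


@pytest.fixture(scope="session")
def preset_cohorts():
    """One simulated post-exclusion cohort per diet preset (fixed seed)."""
    from cohortlife.records import apply_exclusions

    return [
        apply_exclusions(simulate_cohort(cfg))
        for cfg in preset_configs(seed=42).values()
    ]
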