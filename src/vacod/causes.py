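"""Cause-of-death vocabularies and age stratification.

Verbal-autopsy analyses for under-five mortality are run separately for
neonates (first four weeks of life) and older children, each age group with
its own closed list of common causes plus a residual OTHER category that
absorbs everything the cause list does not cover.
"""

from __future__ import annotations

from enum import Enum

from .errors import OutOfRangeError, VocabularyError

# Upper age limit of the study population: 59 completed months.
MAX_AGE_DAYS = 1825
# Last day of the neonatal period (0-27 days).
NEONATE_MAX_DAYS = 27


class AgeGroup(str, Enum):
    NEONATE = "neonate"
    CHILD = "child"


class Cause(str, Enum):
    """Closed cause-of-death vocabulary across both age groups."""

    MALARIA = "malaria"
    PNEUMONIA = "pneumonia"
    MENINGITIS = "meningitis"
    DIARRHEA = "diarrhea"
    MALNUTRITION = "malnutrition"
    HIV_AIDS = "hiv_aids"
    SEPTICEMIA = "septicemia"
    CONGENITAL_MALFORMATION = "congenital_malformation"
    OTHER = "other"


CHILD_CAUSES: tuple[Cause, ...] = (
    Cause.MALARIA,
    Cause.PNEUMONIA,
    Cause.MENINGITIS,
    Cause.DIARRHEA,
    Cause.MALNUTRITION,
    Cause.HIV_AIDS,
    Cause.OTHER,
)

NEONATE_CAUSES: tuple[Cause, ...] = (
    Cause.SEPTICEMIA,
    Cause.MENINGITIS,
    Cause.PNEUMONIA,
    Cause.CONGENITAL_MALFORMATION,
    Cause.OTHER,
)


def vocabulary(age_group: AgeGroup) -> tuple[Cause, ...]:
    """The closed cause vocabulary (including OTHER) for an age group."""
    return NEONATE_CAUSES if age_group is AgeGroup.NEONATE else CHILD_CAUSES


def check_vocabulary(cause: Cause, age_group: AgeGroup) -> None:
    if cause not in vocabulary(age_group):
        raise VocabularyError(
            f"cause {cause.value!r} is not in the {age_group.value} vocabulary"
        )


def derive_age_group(age_days: int, *, neonate_max_days: int = NEONATE_MAX_DAYS) -> AgeGroup:
    """Stratify a death by age at death in days.

    NEONATE covers 0..``neonate_max_days`` days (default 27); CHILD covers the
    rest of the under-five range up to 59 months (1825 days).
    """
    if not isinstance(age_days, (int,)) or isinstance(age_days, bool):
        raise OutOfRangeError(f"age_days must be an integer, got {age_days!r}")
    if age_days < 0 or age_days > MAX_AGE_DAYS:
        raise OutOfRangeError(
            f"age_days must be in [0, {MAX_AGE_DAYS}], got {age_days}"
        )
    return AgeGroup.NEONATE if age_days <= neonate_max_days else AgeGroup.CHILD
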