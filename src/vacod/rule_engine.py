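"""Expert symptom algorithms for assigning cause of death.

Two classification modes are provided over the same per-cause diagnostic
criteria:

* **non-hierarchical** (:func:`classify_multi`) — every criterion is applied
  independently, so one death may satisfy several causes at once;
* **hierarchical** (:func:`classify_single`) — the criteria are tried in a
  fixed precedence order and the first one that fires gives the single
  assigned cause (OTHER if none fires).

Criteria are evaluated with three-valued (Kleene) logic so the three possible
responses — yes, no, unknown — are handled explicitly; the
:class:`EvaluationPolicy` decides how unknowns resolve. Under the default
``unknown-as-absent`` policy a criterion fires only on affirmative evidence:
an unknown flag behaves like "no" and an unknown duration fails its threshold
clause.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from itertools import product

import yaml

from .causes import AgeGroup, Cause, check_vocabulary, vocabulary
from .errors import ConfigError, OutOfRangeError, VocabularyError
from .va_data import COUNT_FIELDS, FLAG_FIELDS, NO, YES, SymptomProfile, VARecord

__all__ = [
    "UnknownHandling",
    "EvaluationPolicy",
    "Hierarchy",
    "DEFAULT_CHILD_ORDER",
    "DEFAULT_NEONATE_ORDER",
    "default_hierarchy",
    "evaluate_criterion",
    "classify_multi",
    "classify_single",
    "enumerate_truth_table",
    "load_hierarchy",
    "load_policy",
]


class UnknownHandling(str, Enum):
    #: unknown flags behave as "no"; unknown durations fail their clause
    AS_ABSENT = "unknown-as-absent"
    #: the criterion fails unless it is true under every resolution of unknowns
    FAILS_CRITERION = "unknown-fails-criterion"
    #: return the three-valued result (None = indeterminate)
    PROPAGATE = "propagate-indeterminate"


@dataclass(frozen=True)
class EvaluationPolicy:
    """Unknown handling plus the duration/frequency thresholds of the criteria."""

    unknown_handling: UnknownHandling = UnknownHandling.AS_ABSENT
    cough_max_days: int = 22          # pneumonia: cough for *less than* this many days
    weight_loss_min_days: int = 14    # malnutrition: weight loss for at least this long
    stools_min_per_day: int = 3       # diarrhea: more than 2 loose watery stools

    def __post_init__(self):
        object.__setattr__(
            self, "unknown_handling", UnknownHandling(self.unknown_handling)
        )
        for name in ("cough_max_days", "weight_loss_min_days", "stools_min_per_day"):
            v = getattr(self, name)
            if not isinstance(v, int) or isinstance(v, bool) or v <= 0:
                raise ConfigError(f"{name} must be a positive integer, got {v!r}")


DEFAULT_POLICY = EvaluationPolicy()

# Precedence orders for single-cause assignment, most specific criterion first.
DEFAULT_CHILD_ORDER: tuple[Cause, ...] = (
    Cause.MENINGITIS,
    Cause.PNEUMONIA,
    Cause.MALNUTRITION,
    Cause.DIARRHEA,
    Cause.HIV_AIDS,
    Cause.MALARIA,
)
DEFAULT_NEONATE_ORDER: tuple[Cause, ...] = (
    Cause.SEPTICEMIA,
    Cause.MENINGITIS,
    Cause.PNEUMONIA,
    Cause.CONGENITAL_MALFORMATION,
)


@dataclass(frozen=True)
class Hierarchy:
    """An ordered cause precedence list for one age group (no OTHER, no repeats)."""

    age_group: AgeGroup
    ordered_causes: tuple[Cause, ...]

    def __post_init__(self):
        object.__setattr__(self, "age_group", AgeGroup(self.age_group))
        causes = tuple(Cause(c) for c in self.ordered_causes)
        object.__setattr__(self, "ordered_causes", causes)
        if Cause.OTHER in causes:
            raise ConfigError("OTHER cannot appear in a hierarchy")
        if len(set(causes)) != len(causes):
            raise ConfigError("hierarchy contains duplicate causes")
        vocab = set(vocabulary(self.age_group)) - {Cause.OTHER}
        bad = set(causes) - vocab
        if bad:
            raise VocabularyError(
                f"hierarchy causes {sorted(c.value for c in bad)} outside the "
                f"{self.age_group.value} vocabulary"
            )


def default_hierarchy(age_group: AgeGroup) -> Hierarchy:
    order = (
        DEFAULT_NEONATE_ORDER if AgeGroup(age_group) is AgeGroup.NEONATE else DEFAULT_CHILD_ORDER
    )
    return Hierarchy(AgeGroup(age_group), order)


# ---------------------------------------------------------------------------
# Three-valued logic (None = unknown)

def _t_not(x):
    return None if x is None else (not x)


def _t_and(*xs):
    if any(x is False for x in xs):
        return False
    if any(x is None for x in xs):
        return None
    return True


def _t_or(*xs):
    if any(x is True for x in xs):
        return True
    if any(x is None for x in xs):
        return None
    return False


def _t_at_least(k, xs):
    true = sum(1 for x in xs if x is True)
    if true >= k:
        return True
    unknown = sum(1 for x in xs if x is None)
    if true + unknown < k:
        return False
    return None


class _Leaves:
    """Symptom lookups resolved according to the unknown-handling policy."""

    def __init__(self, profile: SymptomProfile, policy: EvaluationPolicy):
        self._p = profile
        self._absent = policy.unknown_handling is UnknownHandling.AS_ABSENT

    def flag(self, name: str):
        v = self._p.flag(name)
        if v == YES:
            return True
        if v == NO:
            return False
        return False if self._absent else None

    def _count(self, name: str):
        v = getattr(self._p, name)
        if v is None and not self._absent:
            return None
        return v

    def lt(self, name: str, bound: int):
        v = self._count(name)
        if v is None:
            return False if self._absent else None
        return v < bound

    def ge(self, name: str, bound: int):
        v = self._count(name)
        if v is None:
            return False if self._absent else None
        return v >= bound


# ---------------------------------------------------------------------------
# Diagnostic criteria

def _child_malaria(g: _Leaves, p: EvaluationPolicy):
    # Fever with cerebral signs but no meningeal signs, OR fever with one of
    # the other malaria-compatible presentations.
    cerebral = _t_and(
        g.flag("fever"),
        _t_or(g.flag("convulsions"), g.flag("unconscious")),
        _t_not(g.flag("stiff_neck")),
        _t_not(g.flag("bulging_fontanelle")),
    )
    febrile_other = _t_and(
        g.flag("fever"),
        _t_or(
            _t_and(g.flag("convulsions"), _t_not(g.flag("unconscious"))),
            g.flag("difficulty_breathing"),
            g.flag("blood_in_urine"),
            g.flag("pale_body"),
            g.flag("lack_of_blood"),
        ),
    )
    return _t_or(cerebral, febrile_other)


def _child_hiv(g: _Leaves, p: EvaluationPolicy):
    return _t_or(g.flag("mouth_sore"), g.flag("yellow_eyes"), g.flag("wasting"))


def _child_pneumonia(g: _Leaves, p: EvaluationPolicy):
    return _t_and(
        g.flag("cough"),
        g.lt("cough_duration_days", p.cough_max_days),
        g.flag("fever"),
        g.flag("difficulty_breathing"),
    )


def _child_meningitis(g: _Leaves, p: EvaluationPolicy):
    return _t_and(
        _t_or(g.flag("stiff_neck"), g.flag("bulging_fontanelle")),
        _t_or(g.flag("fever"), g.flag("convulsions"), g.flag("unconscious")),
    )


def _child_diarrhea(g: _Leaves, p: EvaluationPolicy):
    return g.ge("stools_per_day", p.stools_min_per_day)


def _child_malnutrition(g: _Leaves, p: EvaluationPolicy):
    return _t_or(
        g.flag("wasting"),
        _t_and(g.flag("weight_loss"), g.ge("weight_loss_duration_days", p.weight_loss_min_days)),
        _t_and(g.flag("swelling"), _t_or(g.flag("rash"), g.flag("hair_color_change"))),
    )


def _neonate_septicemia(g: _Leaves, p: EvaluationPolicy):
    # "any two" over grouped items; each printed item counts once
    items = [
        g.flag("stopped_suckling"),
        _t_or(g.flag("fever"), g.flag("cold_to_touch")),
        _t_or(g.flag("lethargic_or_unresponsive"), g.flag("unconscious")),
        g.flag("convulsions"),
        g.flag("vomiting"),
        g.flag("skin_pustules"),
    ]
    return _t_at_least(2, items)


def _neonate_meningitis(g: _Leaves, p: EvaluationPolicy):
    return _t_and(g.flag("fever"), g.flag("convulsions"))


def _neonate_pneumonia(g: _Leaves, p: EvaluationPolicy):
    return _t_and(g.flag("cough"), g.flag("difficulty_breathing"))


def _neonate_congenital(g: _Leaves, p: EvaluationPolicy):
    return g.flag("deformity")


CRITERIA = {
    (AgeGroup.CHILD, Cause.MALARIA): _child_malaria,
    (AgeGroup.CHILD, Cause.HIV_AIDS): _child_hiv,
    (AgeGroup.CHILD, Cause.PNEUMONIA): _child_pneumonia,
    (AgeGroup.CHILD, Cause.MENINGITIS): _child_meningitis,
    (AgeGroup.CHILD, Cause.DIARRHEA): _child_diarrhea,
    (AgeGroup.CHILD, Cause.MALNUTRITION): _child_malnutrition,
    (AgeGroup.NEONATE, Cause.SEPTICEMIA): _neonate_septicemia,
    (AgeGroup.NEONATE, Cause.MENINGITIS): _neonate_meningitis,
    (AgeGroup.NEONATE, Cause.PNEUMONIA): _neonate_pneumonia,
    (AgeGroup.NEONATE, Cause.CONGENITAL_MALFORMATION): _neonate_congenital,
}


def evaluate_criterion(
    profile: SymptomProfile,
    cause: Cause,
    age_group: AgeGroup,
    policy: EvaluationPolicy = DEFAULT_POLICY,
):
    """Does ``cause``'s diagnostic criterion fire on this profile?

    Returns a bool under the ``unknown-as-absent`` and
    ``unknown-fails-criterion`` policies, and bool-or-None (None =
    indeterminate) under ``propagate-indeterminate``.
    """
    cause = Cause(cause)
    age_group = AgeGroup(age_group)
    check_vocabulary(cause, age_group)
    if cause is Cause.OTHER:
        raise VocabularyError("OTHER has no diagnostic criterion")
    result = CRITERIA[(age_group, cause)](_Leaves(profile, policy), policy)
    if policy.unknown_handling is UnknownHandling.PROPAGATE:
        return result
    if policy.unknown_handling is UnknownHandling.FAILS_CRITERION:
        return result is True
    return bool(result)


def classify_multi(
    record: VARecord, policy: EvaluationPolicy = DEFAULT_POLICY
) -> frozenset[Cause]:
    """All causes whose criteria fire (may be several; empty if none).

    An empty set is reported as OTHER in downstream mortality-fraction
    accounting — see :func:`vacod.evaluation.as_cause_set`.
    """
    group = record.age_group
    fired = [
        cause
        for cause in vocabulary(group)
        if cause is not Cause.OTHER
        and evaluate_criterion(record.profile, cause, group, policy) is True
    ]
    return frozenset(fired)


def classify_single(
    record: VARecord,
    hierarchy: Hierarchy | None = None,
    policy: EvaluationPolicy = DEFAULT_POLICY,
) -> Cause:
    """First cause in precedence order whose criterion fires; OTHER if none."""
    group = record.age_group
    if hierarchy is None:
        hierarchy = default_hierarchy(group)
    if hierarchy.age_group is not group:
        raise VocabularyError(
            f"hierarchy is for {hierarchy.age_group.value} but record "
            f"{record.record_id!r} is {group.value}"
        )
    for cause in hierarchy.ordered_causes:
        if evaluate_criterion(record.profile, cause, group, policy) is True:
            return cause
    return Cause.OTHER


def enumerate_truth_table(
    age_group: AgeGroup,
    flag_subset: tuple[str, ...],
    duration_grid: dict[str, tuple[int, ...]] | None = None,
    policy: EvaluationPolicy = DEFAULT_POLICY,
    hierarchy: Hierarchy | None = None,
):
    """Exhaustively classify every yes/no combination of a flag subset.

    Flags outside the subset are "no"; integer fields take every value in
    ``duration_grid`` (default 0). Yields
    ``(assignment, multi_set, single_label)`` where ``assignment`` maps field
    name to value. Intended as scaffolding for comparing the engine against
    independent brute-force evaluators.
    """
    age_group = AgeGroup(age_group)
    flag_subset = tuple(flag_subset)
    for name in flag_subset:
        if name not in FLAG_FIELDS:
            raise KeyError(name)
    if len(flag_subset) > 20:
        raise OutOfRangeError(f"flag subset too large: {len(flag_subset)} > 20")
    duration_grid = duration_grid or {}
    for name in duration_grid:
        if name not in COUNT_FIELDS:
            raise KeyError(name)
    count_names = tuple(duration_grid)
    count_values = [tuple(duration_grid[n]) for n in count_names]
    age_days = 0 if age_group is AgeGroup.NEONATE else 365
    for flag_bits in product((NO, YES), repeat=len(flag_subset)):
        for counts in product(*count_values) if count_names else ((),):
            assignment = dict(zip(flag_subset, flag_bits))
            assignment.update(dict(zip(count_names, counts)))
            profile = SymptomProfile.all_no(**assignment)
            record = VARecord("tt", "enum", age_days, profile)
            multi = classify_multi(record, policy)
            single = classify_single(record, hierarchy, policy)
            yield assignment, multi, single


# ---------------------------------------------------------------------------
# Configuration files

def load_hierarchy(path) -> Hierarchy:
    """Read a hierarchy from YAML/JSON: ``{age_group: ..., order: [...]}``."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    try:
        return Hierarchy(AgeGroup(raw["age_group"]), tuple(Cause(c) for c in raw["order"]))
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: invalid hierarchy config: {exc}") from exc


def load_policy(path) -> EvaluationPolicy:
    """Read an evaluation policy from YAML/JSON."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        return EvaluationPolicy(**raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: invalid policy config: {exc}") from exc
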