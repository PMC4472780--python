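"""Diagnostic criteria, multi- vs single-cause assignment, unknown handling."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import brute_oracle
from vacod.causes import AgeGroup, Cause
from vacod.errors import ConfigError, VocabularyError
from vacod.rule_engine import (
    DEFAULT_CHILD_ORDER,
    DEFAULT_NEONATE_ORDER,
    EvaluationPolicy,
    Hierarchy,
    UnknownHandling,
    classify_multi,
    classify_single,
    default_hierarchy,
    enumerate_truth_table,
    evaluate_criterion,
)
from vacod.va_data import FLAG_FIELDS, SymptomProfile, VARecord

from conftest import child_record, neonate_record


# ---------------------------------------------------------------------------
# criterion examples

@pytest.mark.parametrize(
    "kwargs,cause,expected",
    [
        # fever + convulsions without meningeal signs
        (dict(fever="yes", convulsions="yes"), Cause.MALARIA, True),
        # cough duration bound is strict: 22 days fails "less than 22"
        (
            dict(cough="yes", cough_duration_days=22, fever="yes", difficulty_breathing="yes"),
            Cause.PNEUMONIA,
            False,
        ),
        (
            dict(cough="yes", cough_duration_days=21, fever="yes", difficulty_breathing="yes"),
            Cause.PNEUMONIA,
            True,
        ),
        (dict(stools_per_day=3), Cause.DIARRHEA, True),
        (dict(stools_per_day=2), Cause.DIARRHEA, False),
        (dict(weight_loss="yes", weight_loss_duration_days=14), Cause.MALNUTRITION, True),
        (dict(weight_loss="yes", weight_loss_duration_days=13), Cause.MALNUTRITION, False),
        # the rash/hair-change qualifier attaches to swelling, not weight loss
        (dict(swelling="yes", hair_color_change="yes"), Cause.MALNUTRITION, True),
        (dict(swelling="yes"), Cause.MALNUTRITION, False),
        (dict(yellow_eyes="yes"), Cause.HIV_AIDS, True),
        # meningeal sign alone is not meningitis: needs fever/convulsions/coma
        (dict(stiff_neck="yes"), Cause.MENINGITIS, False),
        (dict(stiff_neck="yes", unconscious="yes"), Cause.MENINGITIS, True),
    ],
)
def test_child_criterion_examples(kwargs, cause, expected):
    r = child_record(**kwargs)
    assert evaluate_criterion(r.profile, cause, AgeGroup.CHILD) is expected


@pytest.mark.parametrize(
    "kwargs,cause,expected",
    [
        # "any two of" the septicemia items
        (dict(stopped_suckling="yes", vomiting="yes"), Cause.SEPTICEMIA, True),
        (dict(stopped_suckling="yes"), Cause.SEPTICEMIA, False),
        # fever and cold-to-touch are one grouped item, not two
        (dict(fever="yes", cold_to_touch="yes"), Cause.SEPTICEMIA, False),
        (dict(lethargic_or_unresponsive="yes", unconscious="yes"), Cause.SEPTICEMIA, False),
        (dict(fever="yes", convulsions="yes"), Cause.MENINGITIS, True),
        (dict(cough="yes", difficulty_breathing="yes"), Cause.PNEUMONIA, True),
        (dict(deformity="yes"), Cause.CONGENITAL_MALFORMATION, True),
    ],
)
def test_neonate_criterion_examples(kwargs, cause, expected):
    r = neonate_record(**kwargs)
    assert evaluate_criterion(r.profile, cause, AgeGroup.NEONATE) is expected


def test_all_absent_profile_fires_nothing():
    for record in (child_record(), neonate_record()):
        assert classify_multi(record) == frozenset()
        assert classify_single(record) is Cause.OTHER


def test_vocabulary_mismatch_raises():
    with pytest.raises(VocabularyError):
        evaluate_criterion(SymptomProfile(), Cause.SEPTICEMIA, AgeGroup.CHILD)
    with pytest.raises(VocabularyError):
        evaluate_criterion(SymptomProfile(), Cause.OTHER, AgeGroup.CHILD)
    with pytest.raises(VocabularyError):
        classify_single(child_record(), default_hierarchy(AgeGroup.NEONATE))


# ---------------------------------------------------------------------------
# multi vs single assignment

def test_multi_cause_assignment_may_return_several():
    r = child_record(fever="yes", convulsions="yes", stiff_neck="yes")
    assert classify_multi(r) == {Cause.MENINGITIS, Cause.MALARIA}
    # meningitis outranks malaria in the precedence order
    assert classify_single(r) is Cause.MENINGITIS


def test_neonate_fever_convulsions_ranks_as_septicemia():
    r = neonate_record(fever="yes", convulsions="yes")
    assert classify_multi(r) == {Cause.SEPTICEMIA, Cause.MENINGITIS}
    assert classify_single(r) is Cause.SEPTICEMIA


def test_custom_hierarchy_changes_the_single_assignment():
    r = neonate_record(fever="yes", convulsions="yes")
    flipped = Hierarchy(AgeGroup.NEONATE, tuple(reversed(DEFAULT_NEONATE_ORDER)))
    assert classify_single(r, flipped) is Cause.MENINGITIS


def test_hierarchy_validation():
    with pytest.raises(ConfigError):
        Hierarchy(AgeGroup.CHILD, (Cause.MALARIA, Cause.OTHER))
    with pytest.raises(ConfigError):
        Hierarchy(AgeGroup.CHILD, (Cause.MALARIA, Cause.MALARIA))
    with pytest.raises(VocabularyError):
        Hierarchy(AgeGroup.NEONATE, (Cause.MALARIA,))


# ---------------------------------------------------------------------------
# properties

profiles = st.builds(
    SymptomProfile.all_no,
    **{f: st.sampled_from(["yes", "no", "unknown"]) for f in FLAG_FIELDS},
    cough_duration_days=st.integers(min_value=0, max_value=40),
    weight_loss_duration_days=st.integers(min_value=0, max_value=40),
    stools_per_day=st.integers(min_value=0, max_value=10),
)


@settings(max_examples=200, deadline=None)
@given(profiles, st.sampled_from([5, 365]))
def test_single_assignment_contained_in_multi_set(profile, age_days):
    r = VARecord("p", "s", age_days, profile)
    assert classify_single(r) in classify_multi(r) | {Cause.OTHER}


@settings(max_examples=150, deadline=None)
@given(profiles, st.sampled_from([5, 365]), st.data())
def test_unknown_to_no_is_inert_under_default_policy(profile, age_days, data):
    """unknown-as-absent: turning any unknown flag into an explicit 'no' changes nothing."""
    unknown_flags = [f for f in FLAG_FIELDS if profile.flag(f) == "unknown"]
    if not unknown_flags:
        return
    flag = data.draw(st.sampled_from(unknown_flags))
    resolved = SymptomProfile(
        **{f: ("no" if f == flag else profile.flag(f)) for f in FLAG_FIELDS},
        cough_duration_days=profile.cough_duration_days,
        weight_loss_duration_days=profile.weight_loss_duration_days,
        stools_per_day=profile.stools_per_day,
    )
    r1 = VARecord("a", "s", age_days, profile)
    r2 = VARecord("a", "s", age_days, resolved)
    assert classify_multi(r1) == classify_multi(r2)
    assert classify_single(r1) == classify_single(r2)


def test_unknown_handling_policies_differ_on_negated_clauses():
    # malaria needs NOT(stiff neck): an unknown stiff neck passes under
    # unknown-as-absent but blocks the criterion when unknowns must not matter
    profile = SymptomProfile.all_no(fever="yes", unconscious="yes", stiff_neck="unknown")
    absent = EvaluationPolicy(unknown_handling=UnknownHandling.AS_ABSENT)
    strict = EvaluationPolicy(unknown_handling=UnknownHandling.FAILS_CRITERION)
    propagate = EvaluationPolicy(unknown_handling=UnknownHandling.PROPAGATE)
    assert evaluate_criterion(profile, Cause.MALARIA, AgeGroup.CHILD, absent) is True
    assert evaluate_criterion(profile, Cause.MALARIA, AgeGroup.CHILD, strict) is False
    assert evaluate_criterion(profile, Cause.MALARIA, AgeGroup.CHILD, propagate) is None


def test_policy_thresholds_are_validated():
    with pytest.raises(ConfigError):
        EvaluationPolicy(cough_max_days=0)


# ---------------------------------------------------------------------------
# truth-table scaffolding

def test_truth_table_shape_and_oracle_agreement_small():
    flags = ("fever", "convulsions", "stiff_neck", "bulging_fontanelle", "unconscious")
    rows = list(enumerate_truth_table(AgeGroup.CHILD, flags))
    assert len(rows) == 32
    for assignment, multi, single in rows:
        s = {f: False for f in FLAG_FIELDS}
        s.update({k: v == "yes" for k, v in assignment.items()})
        s.update(cough_duration_days=0, weight_loss_duration_days=0, stools_per_day=0)
        assert {c.value for c in multi} == brute_oracle.multi("child", s)
        assert single.value == brute_oracle.single("child", s)
        assert single in multi | {Cause.OTHER}


def test_single_flag_enumeration_never_fires_malaria():
    rows = list(enumerate_truth_table(AgeGroup.CHILD, ("fever",)))
    assert len(rows) == 2
    assert all(Cause.MALARIA not in multi for _, multi, _ in rows)


def test_truth_table_rejects_oversized_subsets():
    from vacod.errors import OutOfRangeError

    with pytest.raises(OutOfRangeError):
        next(enumerate_truth_table(AgeGroup.CHILD, FLAG_FIELDS[:21]))
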