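"""Percent agreement, Cohen's kappa, Landis-Koch bands, CSMF shift tables."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vacod.causes import Cause
from vacod.errors import DegenerateMarginalsError, OutOfRangeError, UniverseMismatchError, VacodError
from vacod.reliability import (
    POOLED,
    cohen_kappa,
    csmf_shift,
    landis_koch_band,
    percent_agreement,
    reliability_report,
)


def pairs_from_table(table):
    """Expand a contingency table {(a,b): count} into a pair list."""
    out = []
    for (a, b), count in table.items():
        out.extend([(a, b)] * count)
    return out


# ---------------------------------------------------------------------------
# percent agreement

def test_percent_agreement_examples():
    assert percent_agreement([("a", "a")] * 4) == 1.0
    assert percent_agreement([("a", "b"), ("b", "a")]) == 0.0
    pairs = [("a", "a")] * 5 + [("a", "b")]
    assert percent_agreement(pairs) == pytest.approx(5 / 6)
    with pytest.raises(VacodError):
        percent_agreement([])


# ---------------------------------------------------------------------------
# kappa

def test_kappa_hand_computed_two_by_two():
    pairs = pairs_from_table({("x", "x"): 20, ("x", "y"): 5, ("y", "x"): 10, ("y", "y"): 15})
    result = cohen_kappa(pairs)
    assert result.percent_agreement == pytest.approx(0.7)
    assert result.kappa == pytest.approx(0.4)
    assert result.band == "fair"
    assert result.ci95[0] <= result.kappa <= result.ci95[1]
    # z = 0.4 / sqrt(0.5 / (50 * 0.5)) = 2.828..., two-sided p ~ 0.0047
    assert result.p_value == pytest.approx(0.00468, abs=1e-4)


def test_kappa_is_one_iff_perfect_nondegenerate_agreement():
    result = cohen_kappa([("a", "a"), ("b", "b"), ("a", "a")])
    assert result.kappa == pytest.approx(1.0)
    assert result.percent_agreement == 1.0


def test_kappa_zero_when_observed_equals_chance():
    # uniform independent marginals: p_o = p_e = 0.5
    pairs = pairs_from_table({("a", "a"): 5, ("a", "b"): 5, ("b", "a"): 5, ("b", "b"): 5})
    assert cohen_kappa(pairs).kappa == pytest.approx(0.0)


def test_degenerate_marginals_raise_rather_than_nan():
    with pytest.raises(DegenerateMarginalsError):
        cohen_kappa([("a", "a"), ("a", "a")])


@settings(max_examples=50, deadline=None)
@given(st.data())
def test_kappa_invariant_under_relabeling(data):
    labels = ["a", "b", "c", "d"]
    n = data.draw(st.integers(min_value=5, max_value=60))
    pairs = [
        (data.draw(st.sampled_from(labels)), data.draw(st.sampled_from(labels)))
        for _ in range(n)
    ]
    try:
        base = cohen_kappa(pairs)
    except DegenerateMarginalsError:
        return
    perm = dict(zip(labels, data.draw(st.permutations(labels))))
    relabeled = cohen_kappa([(perm[a], perm[b]) for a, b in pairs])
    assert relabeled.kappa == pytest.approx(base.kappa, abs=1e-12)
    assert relabeled.se == pytest.approx(base.se, abs=1e-12)


def test_kappa_matches_independent_implementation_on_random_tables():
    from statsmodels.stats.inter_rater import cohens_kappa as sm_kappa

    rng = np.random.default_rng(42)
    for _ in range(50):
        k = int(rng.integers(2, 8))
        table = rng.multinomial(int(rng.integers(10, 200)), np.full(k * k, 1 / (k * k))).reshape(k, k)
        pairs = pairs_from_table(
            {(i, j): int(table[i, j]) for i in range(k) for j in range(k)}
        )
        try:
            ours = cohen_kappa(pairs)
        except DegenerateMarginalsError:
            continue
        theirs = float(sm_kappa(table, return_results=True).kappa)
        assert ours.kappa == pytest.approx(theirs, abs=1e-12)


def test_bootstrap_ci_contains_kappa_and_shrinks_with_n():
    rng = np.random.default_rng(3)
    labels = ["a", "b", "c"]

    def noisy_pairs(n):
        out = []
        for _ in range(n):
            a = labels[int(rng.integers(3))]
            b = a if rng.random() < 0.8 else labels[int(rng.integers(3))]
            out.append((a, b))
        return out

    small = cohen_kappa(noisy_pairs(60), ci_method="bootstrap", n_boot=400, seed=1)
    large = cohen_kappa(noisy_pairs(1500), ci_method="bootstrap", n_boot=400, seed=1)
    for result in (small, large):
        assert result.ci95[0] <= result.kappa <= result.ci95[1]
    assert (large.ci95[1] - large.ci95[0]) < (small.ci95[1] - small.ci95[0])


# ---------------------------------------------------------------------------
# Landis-Koch bands

@pytest.mark.parametrize(
    "kappa,band",
    [
        (0.87, "almost perfect"),
        (0.79, "substantial"),
        (0.77, "substantial"),
        (0.8, "substantial"),     # upper-inclusive boundary
        (0.52, "moderate"),
        (0.31, "fair"),
        (0.1, "slight"),
        (0.0, "poor"),
        (-0.4, "poor"),
        (1.0, "almost perfect"),
    ],
)
def test_landis_koch_bands(kappa, band):
    assert landis_koch_band(kappa) == band


def test_landis_koch_rejects_out_of_range():
    with pytest.raises(OutOfRangeError):
        landis_koch_band(1.2)


# ---------------------------------------------------------------------------
# CSMF shift

def test_csmf_shift_matches_hand_values():
    # 100 paired records: malnutrition 19% -> 12% is a -7 pp shift
    original = {f"r{i}": (Cause.MALNUTRITION if i < 19 else Cause.OTHER) for i in range(100)}
    repeat = {f"r{i}": (Cause.MALNUTRITION if i < 12 else Cause.OTHER) for i in range(100)}
    table = csmf_shift(original, repeat)
    row = table[(table.group == POOLED) & (table.cause == "malnutrition")].iloc[0]
    assert row.csmf_original == pytest.approx(0.19)
    assert row.csmf_repeat == pytest.approx(0.12)
    assert row.shift_pp == pytest.approx(-7.0)


def test_csmf_shift_identical_labelings_and_universe_check():
    labels = {f"r{i}": Cause.MALARIA if i % 2 else Cause.OTHER for i in range(10)}
    table = csmf_shift(labels, labels)
    assert (table.shift_pp == 0).all()
    with pytest.raises(UniverseMismatchError):
        csmf_shift(labels, {**labels, "extra": Cause.OTHER})


def test_csmf_shift_reports_per_reviewer_groups():
    original = {f"r{i}": Cause.MALARIA if i < 9 else Cause.OTHER for i in range(20)}
    repeat = {f"r{i}": Cause.MALARIA if i < 6 else Cause.OTHER for i in range(20)}
    reviewers = {f"r{i}": ("1" if i < 10 else "2") for i in range(20)}
    table = csmf_shift(original, repeat, reviewers)
    assert set(table.group) == {POOLED, "1", "2"}
    r1 = table[(table.group == "1") & (table.cause == "malaria")].iloc[0]
    assert r1.shift_pp == pytest.approx(-30.0)  # 9/10 -> 6/10


# ---------------------------------------------------------------------------
# reliability report

def test_report_single_reviewer_equals_pooled():
    pairs = pairs_from_table({("a", "a"): 12, ("a", "b"): 3, ("b", "b"): 10, ("b", "a"): 2})
    report = reliability_report({"1": pairs})
    assert report["1"] == report[POOLED]


def test_report_pools_pairs_not_kappas():
    pairs = pairs_from_table({("a", "a"): 12, ("a", "b"): 3, ("b", "b"): 10, ("b", "a"): 2})
    report = reliability_report({"1": pairs, "2": pairs})
    # identical pair multisets: marginals scale linearly, pooled kappa unchanged
    assert report[POOLED].kappa == pytest.approx(report["1"].kappa)
    assert report[POOLED].n_pairs == 2 * report["1"].n_pairs


def test_report_flags_degenerate_reviewer():
    good = pairs_from_table({("a", "a"): 5, ("b", "b"): 5, ("a", "b"): 2})
    degenerate = [("a", "a")] * 4
    report = reliability_report({"1": good, "2": degenerate})
    assert report["2"] is None
    assert report[POOLED].n_pairs == len(good) + 4
    dropped = reliability_report(
        {"1": good, "2": degenerate}, drop_degenerate_from_pooled=True
    )
    assert dropped[POOLED].n_pairs == len(good)
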