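"""Validation of cause-of-death assignments against a reference standard.

For each cause a record is "positive" if the cause belongs to the record's
assigned cause set (single-cause assignments are singleton sets), which gives
per-cause confusion counts and the usual diagnostic metrics — sensitivity,
specificity, positive predictive value. Population-level accuracy is measured
through cause-specific mortality fractions (CSMF): the fraction of deaths in a
stratum attributed to each cause, and the signed difference in percentage
points between a method's CSMF and the reference standard's.

Metrics with a zero denominator are undefined and reported as NaN/null,
never coerced to 0.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .causes import Cause, vocabulary
from .errors import UniverseMismatchError, VacodError
from .va_data import RecordSet, stratify

__all__ = [
    "ConfusionCounts",
    "BinaryMetrics",
    "as_cause_set",
    "confusion",
    "binary_metrics",
    "csmf",
    "csmf_difference",
    "evaluate_methods",
    "ALL_SITES",
]

ALL_SITES = "ALL"


@dataclass(frozen=True)
class ConfusionCounts:
    cause: Cause
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise VacodError(f"{name} must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


class BinaryMetrics(NamedTuple):
    sensitivity: float | None
    specificity: float | None
    ppv: float | None


def as_cause_set(assignment) -> frozenset[Cause]:
    """Normalise an assignment to a cause set; empty sets mean OTHER.

    Accepts a single :class:`Cause`, an iterable of causes, or None/empty
    (no named cause fired), which is accounted as the residual OTHER category.
    """
    if assignment is None:
        return frozenset({Cause.OTHER})
    if isinstance(assignment, Cause):
        return frozenset({assignment})
    if isinstance(assignment, str):
        return frozenset({Cause(assignment)})
    causes = frozenset(Cause(c) for c in assignment)
    return causes if causes else frozenset({Cause.OTHER})


def _check_universe(predicted: Mapping, reference: Mapping) -> None:
    missing_pred = sorted(set(reference) - set(predicted))
    missing_ref = sorted(set(predicted) - set(reference))
    if missing_pred or missing_ref:
        raise UniverseMismatchError(
            "predicted and reference cover different records "
            f"(missing from predicted: {missing_pred[:10]}, "
            f"missing from reference: {missing_ref[:10]})",
            missing=tuple(missing_pred + missing_ref),
        )


def confusion(predicted: Mapping, reference: Mapping, cause: Cause) -> ConfusionCounts:
    """Per-cause TP/FP/TN/FN over a shared record universe."""
    cause = Cause(cause)
    _check_universe(predicted, reference)
    tp = fp = tn = fn = 0
    for rid, ref in reference.items():
        ref_pos = cause in as_cause_set(ref)
        pred_pos = cause in as_cause_set(predicted[rid])
        if pred_pos and ref_pos:
            tp += 1
        elif pred_pos:
            fp += 1
        elif ref_pos:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(cause, tp, fp, tn, fn)


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def binary_metrics(c: ConfusionCounts) -> BinaryMetrics:
    """Sensitivity, specificity and PPV; None where the denominator is zero."""
    return BinaryMetrics(
        sensitivity=_ratio(c.tp, c.tp + c.fn),
        specificity=_ratio(c.tn, c.tn + c.fp),
        ppv=_ratio(c.tp, c.tp + c.fp),
    )


def csmf(assignments: Mapping, cause: Cause, n: int | None = None) -> float:
    """Fraction of deaths attributed to ``cause``.

    For multi-cause assignments the fractions may sum to more than 1 across
    causes; for single-cause assignments they partition and sum to 1
    (including OTHER).
    """
    cause = Cause(cause)
    if n is None:
        n = len(assignments)
    if n == 0:
        raise VacodError("CSMF undefined on an empty stratum")
    if len(assignments) > n:
        raise VacodError(f"{len(assignments)} assignments exceed stratum size {n}")
    positive = sum(1 for a in assignments.values() if cause in as_cause_set(a))
    return positive / n


def csmf_difference(csmf_method: float, csmf_reference: float) -> float:
    """Signed method-minus-reference CSMF difference in percentage points."""
    for v in (csmf_method, csmf_reference):
        if not (0.0 <= v <= 1.0):
            raise VacodError(f"CSMF must be in [0, 1], got {v}")
    return (csmf_method - csmf_reference) * 100.0


def evaluate_methods(
    records: RecordSet,
    methods: Mapping[str, Mapping],
    by_site: bool = True,
) -> pd.DataFrame:
    """Full validation table: one row per (method, site stratum, age group, cause).

    ``methods`` maps a method name to a per-record-id assignment (a cause, a
    cause set, or None). Strata are each site plus a pooled ``ALL`` stratum,
    crossed with age group. Sensitivity/specificity/PPV rows are produced for
    the named causes; the residual OTHER category appears with CSMF columns
    only, since it has no diagnostic criterion of its own.
    """
    universe = set(records.ids())
    reference = {}
    for r in records:
        if r.reference_causes is None:
            raise VacodError(f"record {r.record_id!r} has no reference cause")
        reference[r.record_id] = r.reference_causes
    for name, assignment in methods.items():
        missing = sorted(universe - set(assignment))
        if missing:
            raise UniverseMismatchError(
                f"method {name!r} is missing assignments for {missing[:10]}",
                missing=tuple(missing),
            )

    strata: list[tuple[str, RecordSet]] = [(ALL_SITES, records)]
    if by_site:
        strata += list(stratify(records, "site").items())

    rows = []
    for site_label, site_records in strata:
        for age_group, group_records in stratify(site_records, "age_group").items():
            ids = group_records.ids()
            ref = {rid: reference[rid] for rid in ids}
            n = len(ids)
            for method, assignment in methods.items():
                pred = {rid: assignment[rid] for rid in ids}
                for cause in vocabulary(age_group):
                    row = {
                        "method": method,
                        "site": site_label,
                        "age_group": age_group.value,
                        "cause": cause.value,
                        "n": n,
                        "csmf_method": csmf(pred, cause),
                        "csmf_reference": csmf(ref, cause),
                    }
                    row["csmf_difference_pp"] = csmf_difference(
                        row["csmf_method"], row["csmf_reference"]
                    )
                    if cause is Cause.OTHER:
                        row.update(
                            tp=np.nan, fp=np.nan, tn=np.nan, fn=np.nan,
                            sensitivity=np.nan, specificity=np.nan, ppv=np.nan,
                        )
                    else:
                        counts = confusion(pred, ref, cause)
                        metrics = binary_metrics(counts)
                        row.update(
                            tp=counts.tp, fp=counts.fp, tn=counts.tn, fn=counts.fn,
                            sensitivity=np.nan if metrics.sensitivity is None else metrics.sensitivity,
                            specificity=np.nan if metrics.specificity is None else metrics.specificity,
                            ppv=np.nan if metrics.ppv is None else metrics.ppv,
                        )
                    rows.append(row)
    columns = [
        "method", "site", "age_group", "cause", "n",
        "tp", "fp", "tn", "fn",
        "sensitivity", "specificity", "ppv",
        "csmf_method", "csmf_reference", "csmf_difference_pp",
    ]
    return pd.DataFrame(rows, columns=columns)
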