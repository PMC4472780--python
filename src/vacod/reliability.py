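"""Intra-rater reliability of repeated cause-of-death certification.

When the same physician re-reviews a questionnaire months later, agreement
between the original and repeat cause is summarised by the raw percent
agreement and by Cohen's kappa, which corrects for the agreement expected by
chance from the two labelings' marginal distributions:

    kappa = (p_o - p_e) / (1 - p_e)

with p_o the observed agreement fraction and p_e = sum_k r_k * c_k / n^2 over
the row/column marginals of the contingency table. The large-sample standard
error sqrt(p_o (1 - p_o) / (n (1 - p_e)^2)) gives a normal 95% CI, and the
null hypothesis kappa = 0 is tested with z = kappa / sqrt(p_e / (n (1 - p_e)))
(two-sided). A seeded pair-resampling bootstrap CI is available as an
alternative. Kappa values are interpreted on the conventional Landis-Koch
verbal scale.

Population-level stability is summarised separately: the cause-specific
mortality fraction computed from the original labels versus the repeat labels
(per reviewer and pooled), with the signed shift in percentage points.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .causes import Cause
from .errors import DegenerateMarginalsError, OutOfRangeError, UniverseMismatchError, VacodError
from .evaluation import csmf, csmf_difference

__all__ = [
    "KappaResult",
    "percent_agreement",
    "cohen_kappa",
    "landis_koch_band",
    "csmf_shift",
    "reliability_report",
    "POOLED",
]

POOLED = "ALL"

# Landis-Koch verbal bands, upper-inclusive so that e.g. 0.79 is 'substantial'
# and exactly 0.8 is still 'substantial', not 'almost perfect'.
_BANDS = (
    (0.8, "almost perfect"),
    (0.6, "substantial"),
    (0.4, "moderate"),
    (0.2, "fair"),
    (0.0, "slight"),
)


def landis_koch_band(kappa: float) -> str:
    """Conventional verbal interpretation of a kappa value."""
    if not (-1.0 <= kappa <= 1.0):
        raise OutOfRangeError(f"kappa must be in [-1, 1], got {kappa}")
    for lower, label in _BANDS:
        if kappa > lower:
            return label
    return "poor"


@dataclass(frozen=True)
class KappaResult:
    n_pairs: int
    percent_agreement: float
    kappa: float
    se: float
    ci95: tuple[float, float]
    p_value: float
    band: str


def percent_agreement(pairs: Sequence[tuple]) -> float:
    """Fraction of (original, repeat) pairs with identical labels."""
    pairs = list(pairs)
    if not pairs:
        raise VacodError("percent agreement undefined on an empty pair sequence")
    return sum(1 for a, b in pairs if a == b) / len(pairs)


def _marginal_chance_agreement(pairs: list[tuple]) -> float:
    n = len(pairs)
    a_counts: dict = {}
    b_counts: dict = {}
    for a, b in pairs:
        a_counts[a] = a_counts.get(a, 0) + 1
        b_counts[b] = b_counts.get(b, 0) + 1
    labels = set(a_counts) | set(b_counts)
    return sum(a_counts.get(k, 0) * b_counts.get(k, 0) for k in labels) / (n * n)


def cohen_kappa(
    pairs: Sequence[tuple],
    ci_method: str = "normal",
    n_boot: int = 2000,
    seed: int | None = None,
) -> KappaResult:
    """Cohen's kappa for paired single labels, with SE, CI, p-value and band.

    ``ci_method='bootstrap'`` replaces the normal-approximation CI by a seeded
    percentile bootstrap over pairs (``n_boot`` resamples); the point
    estimate, SE and p-value are unchanged.
    """
    pairs = [(a, b) for a, b in pairs]
    n = len(pairs)
    if n < 2:
        raise VacodError(f"kappa needs at least 2 pairs, got {n}")
    p_o = percent_agreement(pairs)
    p_e = _marginal_chance_agreement(pairs)
    if p_e >= 1.0 - 1e-15:
        raise DegenerateMarginalsError(
            "both labelings are constant on a single label; chance agreement "
            "is 1 and kappa is undefined"
        )
    kappa = (p_o - p_e) / (1.0 - p_e)
    se = float(np.sqrt(p_o * (1.0 - p_o) / (n * (1.0 - p_e) ** 2)))
    if ci_method == "normal":
        ci = (max(-1.0, kappa - 1.96 * se), min(1.0, kappa + 1.96 * se))
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        idx = np.arange(n)
        boots = []
        for _ in range(n_boot):
            sample = [pairs[i] for i in rng.choice(idx, size=n, replace=True)]
            pe_b = _marginal_chance_agreement(sample)
            if pe_b >= 1.0 - 1e-15:
                continue  # degenerate resample carries no information on kappa
            boots.append((percent_agreement(sample) - pe_b) / (1.0 - pe_b))
        ci = tuple(np.percentile(boots, [2.5, 97.5]))
        ci = (min(ci[0], kappa), max(ci[1], kappa))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    z = kappa / float(np.sqrt(p_e / (n * (1.0 - p_e))))
    p_value = float(2.0 * stats.norm.sf(abs(z)))
    return KappaResult(
        n_pairs=n,
        percent_agreement=p_o,
        kappa=kappa,
        se=se,
        ci95=ci,
        p_value=p_value,
        band=landis_koch_band(kappa),
    )


def csmf_shift(
    original: Mapping,
    repeat: Mapping,
    reviewers: Mapping | None = None,
    causes: Sequence[Cause] | None = None,
) -> pd.DataFrame:
    """Original-vs-repeat CSMF per cause, per reviewer plus a pooled ALL row group.

    ``original`` and ``repeat`` map record id to a single cause label;
    ``reviewers`` (optional) maps record id to a reviewer id. The shift column
    is (repeat - original) in percentage points.
    """
    missing = sorted(set(original) ^ set(repeat))
    if missing:
        raise UniverseMismatchError(
            f"original and repeat labelings cover different records: {missing[:10]}",
            missing=tuple(missing),
        )
    if reviewers is not None:
        missing_rev = sorted(set(original) - set(reviewers))
        if missing_rev:
            raise UniverseMismatchError(
                f"records without a reviewer: {missing_rev[:10]}", missing=tuple(missing_rev)
            )
    if causes is None:
        seen = {Cause(v) for v in original.values()} | {Cause(v) for v in repeat.values()}
        causes = sorted(seen, key=lambda c: c.value)

    groups: dict[str, list] = {POOLED: list(original)}
    if reviewers is not None:
        for rid in original:
            groups.setdefault(str(reviewers[rid]), []).append(rid)

    rows = []
    for group, ids in groups.items():
        orig = {rid: original[rid] for rid in ids}
        rept = {rid: repeat[rid] for rid in ids}
        for cause in causes:
            c_orig = csmf(orig, cause)
            c_rept = csmf(rept, cause)
            rows.append(
                {
                    "group": group,
                    "cause": Cause(cause).value,
                    "n": len(ids),
                    "csmf_original": c_orig,
                    "csmf_repeat": c_rept,
                    "shift_pp": csmf_difference(c_rept, c_orig),
                }
            )
    return pd.DataFrame(rows)


def reliability_report(
    pairs_by_reviewer: Mapping[str, Sequence[tuple]],
    drop_degenerate_from_pooled: bool = False,
    **kappa_kwargs,
) -> dict[str, KappaResult | None]:
    """Per-reviewer kappa plus a pooled result on the concatenated pairs.

    The pooled entry (key ``'ALL'``) is computed on all pairs together, not as
    an average of per-reviewer kappas. A reviewer whose labelings are
    degenerate (constant on one label for both reviews) is reported as None;
    their pairs still enter the pooled computation unless
    ``drop_degenerate_from_pooled`` is set.
    """
    results: dict[str, KappaResult | None] = {}
    pooled_pairs: list[tuple] = []
    for reviewer, pairs in pairs_by_reviewer.items():
        pairs = list(pairs)
        if len(pairs) < 2:
            raise VacodError(f"reviewer {reviewer!r} has fewer than 2 pairs")
        try:
            results[str(reviewer)] = cohen_kappa(pairs, **kappa_kwargs)
            pooled_pairs.extend(pairs)
        except DegenerateMarginalsError:
            results[str(reviewer)] = None
            if not drop_degenerate_from_pooled:
                pooled_pairs.extend(pairs)
    results[POOLED] = cohen_kappa(pooled_pairs, **kappa_kwargs)
    return results
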