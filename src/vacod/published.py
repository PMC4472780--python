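"""Published summary tables from the Ugandan VA validation study.

The study's questionnaire-level data were never deposited, but its printed
summary tables are enough to check the package's CSMF arithmetic and kappa
interpretation against the source: the method-vs-reference CSMF table (with
its signed difference columns), the original-vs-repeat CSMF table from the
intra-rater substudy, and the per-reviewer reliability coefficients.

All CSMF columns are in percent, as printed. ``recompute_*`` functions rerun
the package's own difference operations on the printed CSMF columns and
return them side by side with the printed differences.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .evaluation import csmf_difference
from .reliability import landis_koch_band

__all__ = [
    "load_method_csmf",
    "load_repeat_csmf",
    "load_reliability_summary",
    "recompute_method_differences",
    "recompute_repeat_shifts",
    "band_reliability_summary",
]


def _load(name: str) -> pd.DataFrame:
    with resources.files("vacod.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


def load_method_csmf() -> pd.DataFrame:
    """Reference vs PCVA/non-hierarchical/hierarchical CSMF by site and age group."""
    return _load("published_method_csmf.csv")


def load_repeat_csmf() -> pd.DataFrame:
    """Original vs repeat-review CSMF by physician reviewer (pooled row = 'ALL')."""
    return _load("published_repeat_csmf.csv")


def load_reliability_summary() -> pd.DataFrame:
    """Per-reviewer percent agreement and kappa with the printed 95% CI."""
    return _load("published_reliability.csv")


def recompute_method_differences() -> pd.DataFrame:
    """Recompute the signed CSMF-difference columns from the printed CSMFs.

    Adds ``diff_<method>`` columns (method minus reference, percentage points)
    computed by :func:`vacod.evaluation.csmf_difference` next to the printed
    ``printed_diff_<method>`` columns.
    """
    table = load_method_csmf()
    for method in ("pcva", "nha", "ha"):
        table[f"diff_{method}"] = [
            csmf_difference(m / 100.0, r / 100.0)
            for m, r in zip(table[f"csmf_{method}"], table["csmf_mr"])
        ]
    return table


def recompute_repeat_shifts() -> pd.DataFrame:
    """Recompute the repeat-minus-original shift column from the printed CSMFs."""
    table = load_repeat_csmf()
    table["shift_pp"] = [
        csmf_difference(rep / 100.0, orig / 100.0)
        for rep, orig in zip(table["csmf_repeat"], table["csmf_original"])
    ]
    return table


def band_reliability_summary() -> pd.DataFrame:
    """Attach the Landis-Koch verbal band to each printed kappa."""
    table = load_reliability_summary()
    table["band"] = [landis_koch_band(k) for k in table["kappa"]]
    return table
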