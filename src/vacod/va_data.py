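"""Domain types and tabular I/O for verbal-autopsy records.

A record is one death: identifiers, age at death, the closed-ended
sign/symptom responses collected at interview, and optional cause labels
(reference standard from medical-record review, physician-certified VA, and
a repeat physician review used for intra-rater reliability).

Symptom responses are ternary — yes / no / unknown — and the unknown state is
preserved verbatim at parse time; how unknowns influence a diagnostic
criterion is decided by the rule engine's evaluation policy, never here.
"""

from __future__ import annotations

import csv
import json
from collections.abc import Iterable, Iterator, Sequence
from dataclasses import dataclass

from .causes import (
    AgeGroup,
    Cause,
    derive_age_group,
    vocabulary,
)
from .errors import FormatError, OutOfRangeError, VocabularyError

__all__ = [
    "YES",
    "NO",
    "UNKNOWN",
    "SymptomProfile",
    "VARecord",
    "RecordSet",
    "FLAG_FIELDS",
    "COUNT_FIELDS",
    "read_records",
    "write_records",
    "column_schema",
    "write_schema",
    "systematic_sample",
    "stratify",
    "derive_age_group",
]


# Plain string sentinels keep CSV round-trips and YAML configs trivial.
YES = "yes"
NO = "no"
UNKNOWN = "unknown"
_TERNARY = (YES, NO, UNKNOWN)

FLAG_FIELDS: tuple[str, ...] = (
    "fever",
    "convulsions",
    "stiff_neck",
    "bulging_fontanelle",
    "unconscious",
    "difficulty_breathing",
    "blood_in_urine",
    "pale_body",
    "lack_of_blood",
    "mouth_sore",
    "yellow_eyes",
    "wasting",
    "cough",
    "weight_loss",
    "swelling",
    "rash",
    "hair_color_change",
    "stopped_suckling",
    "cold_to_touch",
    "lethargic_or_unresponsive",
    "vomiting",
    "skin_pustules",
    "deformity",
)

COUNT_FIELDS: tuple[str, ...] = (
    "cough_duration_days",
    "weight_loss_duration_days",
    "stools_per_day",
)


def _coerce_flag(value) -> str:
    if value is True:
        return YES
    if value is False:
        return NO
    if value is None:
        return UNKNOWN
    if isinstance(value, str):
        v = value.strip().lower()
        if v in ("", "unknown", "unk", "dk", "nan"):
            return UNKNOWN
        if v in ("yes", "y", "1", "true"):
            return YES
        if v in ("no", "n", "0", "false"):
            return NO
    raise FormatError(f"cannot interpret {value!r} as a yes/no/unknown response")


@dataclass(frozen=True)
class SymptomProfile:
    """Closed-ended responses: ternary flags plus integer durations/frequencies.

    Flags default to ``unknown``; integer fields default to ``None`` (unknown).
    """

    fever: str = UNKNOWN
    convulsions: str = UNKNOWN
    stiff_neck: str = UNKNOWN
    bulging_fontanelle: str = UNKNOWN
    unconscious: str = UNKNOWN
    difficulty_breathing: str = UNKNOWN
    blood_in_urine: str = UNKNOWN
    pale_body: str = UNKNOWN
    lack_of_blood: str = UNKNOWN
    mouth_sore: str = UNKNOWN
    yellow_eyes: str = UNKNOWN
    wasting: str = UNKNOWN
    cough: str = UNKNOWN
    weight_loss: str = UNKNOWN
    swelling: str = UNKNOWN
    rash: str = UNKNOWN
    hair_color_change: str = UNKNOWN
    stopped_suckling: str = UNKNOWN
    cold_to_touch: str = UNKNOWN
    lethargic_or_unresponsive: str = UNKNOWN
    vomiting: str = UNKNOWN
    skin_pustules: str = UNKNOWN
    deformity: str = UNKNOWN
    cough_duration_days: int | None = None
    weight_loss_duration_days: int | None = None
    stools_per_day: int | None = None

    def __post_init__(self):
        for name in FLAG_FIELDS:
            object.__setattr__(self, name, _coerce_flag(getattr(self, name)))
        for name in COUNT_FIELDS:
            value = getattr(self, name)
            if value is None:
                continue
            if isinstance(value, bool) or not isinstance(value, int):
                raise FormatError(f"{name} must be a non-negative integer or None, got {value!r}")
            if value < 0:
                raise FormatError(f"{name} must be non-negative, got {value}")

    @classmethod
    def all_no(cls, **overrides) -> "SymptomProfile":
        """A profile with every flag 'no' and counts 0, overridden by keywords."""
        base = {name: NO for name in FLAG_FIELDS}
        base.update({name: 0 for name in COUNT_FIELDS})
        base.update(overrides)
        return cls(**base)

    def flag(self, name: str) -> str:
        if name not in FLAG_FIELDS:
            raise KeyError(name)
        return getattr(self, name)


def _check_causes(causes, age_group: AgeGroup, what: str):
    if causes is None:
        return None
    out = frozenset(Cause(c) for c in causes)
    vocab = set(vocabulary(age_group))
    bad = out - vocab
    if bad:
        raise VocabularyError(
            f"{what} contains {sorted(c.value for c in bad)} outside the "
            f"{age_group.value} vocabulary"
        )
    return out


@dataclass(frozen=True)
class VARecord:
    """One death with its interview responses and optional cause labels."""

    record_id: str
    site: str
    age_days: int
    profile: SymptomProfile
    reviewer_id: str | None = None
    reference_causes: frozenset[Cause] | None = None
    pcva_causes: frozenset[Cause] | None = None
    pcva_repeat_cause: Cause | None = None

    def __post_init__(self):
        group = derive_age_group(self.age_days)  # validates range
        object.__setattr__(
            self, "reference_causes", _check_causes(self.reference_causes, group, "reference_causes")
        )
        object.__setattr__(
            self, "pcva_causes", _check_causes(self.pcva_causes, group, "pcva_causes")
        )
        if self.pcva_repeat_cause is not None:
            cause = Cause(self.pcva_repeat_cause)
            if cause not in vocabulary(group):
                raise VocabularyError(
                    f"pcva_repeat_cause {cause.value!r} outside the {group.value} vocabulary"
                )
            object.__setattr__(self, "pcva_repeat_cause", cause)

    @property
    def age_group(self) -> AgeGroup:
        return derive_age_group(self.age_days)


class RecordSet:
    """An ordered collection of records with unique ids."""

    def __init__(self, records: Iterable[VARecord]):
        self._records = list(records)
        seen: set[str] = set()
        dups: list[str] = []
        for r in self._records:
            if r.record_id in seen:
                dups.append(r.record_id)
            seen.add(r.record_id)
        if dups:
            raise FormatError(f"duplicate record ids: {sorted(set(dups))}")

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[VARecord]:
        return iter(self._records)

    def __getitem__(self, i):
        return self._records[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, RecordSet) and self._records == other._records

    def ids(self) -> list[str]:
        return [r.record_id for r in self._records]

    def subset(self, ids: Sequence[str]) -> "RecordSet":
        wanted = set(ids)
        return RecordSet(r for r in self._records if r.record_id in wanted)


# ---------------------------------------------------------------------------
# CSV I/O

_META_COLUMNS = ("record_id", "site", "reviewer_id", "age_days")
_LABEL_COLUMNS = ("reference_causes", "pcva_causes", "pcva_repeat_cause")
REQUIRED_COLUMNS = ("record_id", "site", "age_days") + FLAG_FIELDS + COUNT_FIELDS
ALL_COLUMNS = _META_COLUMNS + FLAG_FIELDS + COUNT_FIELDS + _LABEL_COLUMNS


def column_schema() -> dict:
    """JSON-serialisable description of the record CSV layout."""
    cols = {}
    for name in _META_COLUMNS:
        cols[name] = {
            "record_id": "unique string identifier",
            "site": "study site label",
            "reviewer_id": "optional physician reviewer id",
            "age_days": "integer age at death in days (0-1825)",
        }[name]
    for name in FLAG_FIELDS:
        cols[name] = "yes/no response; empty or 'unknown' = unknown"
    for name in COUNT_FIELDS:
        cols[name] = "non-negative integer; empty = unknown"
    for name in _LABEL_COLUMNS:
        cols[name] = "cause label(s); multiple causes joined with ';'; empty = absent"
    return {
        "format": "CSV, UTF-8, comma separated, header required",
        "columns": cols,
        "required": list(REQUIRED_COLUMNS),
    }


def write_schema(path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(column_schema(), fh, indent=2)
        fh.write("\n")


def _cell_to_int(value: str, column: str, record_id: str) -> int | None:
    v = value.strip()
    if v == "" or v.lower() in ("unknown", "nan"):
        return None
    try:
        return int(v)
    except ValueError:
        raise FormatError(
            f"record {record_id!r}: column {column!r} must be an integer, got {value!r}"
        ) from None


def _cell_to_causes(value: str) -> frozenset[Cause] | None:
    v = value.strip()
    if not v:
        return None
    return frozenset(Cause(part.strip().lower()) for part in v.split(";") if part.strip())


def read_records(path) -> RecordSet:
    """Parse a record CSV; empty cells become the unknown state.

    Raises :class:`FormatError` for a missing required column, a non-integer
    age/duration cell (naming the record), or duplicated record ids.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file, header row required")
        missing = [c for c in REQUIRED_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise FormatError(f"{path}: missing required column(s): {missing}")
        records = []
        for row in reader:
            rid = (row.get("record_id") or "").strip()
            if not rid:
                raise FormatError(f"{path}: row {reader.line_num}: empty record_id")
            age = _cell_to_int(row["age_days"], "age_days", rid)
            if age is None:
                raise FormatError(f"record {rid!r}: age_days may not be unknown")
            profile_kwargs = {name: row[name] for name in FLAG_FIELDS}
            for name in COUNT_FIELDS:
                profile_kwargs[name] = _cell_to_int(row[name], name, rid)
            try:
                profile = SymptomProfile(**profile_kwargs)
                record = VARecord(
                    record_id=rid,
                    site=(row["site"] or "").strip(),
                    age_days=age,
                    profile=profile,
                    reviewer_id=(row.get("reviewer_id") or "").strip() or None,
                    reference_causes=_cell_to_causes(row.get("reference_causes", "") or ""),
                    pcva_causes=_cell_to_causes(row.get("pcva_causes", "") or ""),
                    pcva_repeat_cause=(
                        Cause((row.get("pcva_repeat_cause") or "").strip().lower())
                        if (row.get("pcva_repeat_cause") or "").strip()
                        else None
                    ),
                )
            except (OutOfRangeError, VocabularyError, ValueError) as exc:
                raise FormatError(f"record {rid!r}: {exc}") from exc
            records.append(record)
    return RecordSet(records)


def _causes_to_cell(causes) -> str:
    if causes is None:
        return ""
    return ";".join(sorted(c.value for c in causes))


def write_records(records: RecordSet, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=ALL_COLUMNS)
        writer.writeheader()
        for r in records:
            row = {
                "record_id": r.record_id,
                "site": r.site,
                "reviewer_id": r.reviewer_id or "",
                "age_days": r.age_days,
            }
            for name in FLAG_FIELDS:
                value = r.profile.flag(name)
                row[name] = "" if value == UNKNOWN else value
            for name in COUNT_FIELDS:
                value = getattr(r.profile, name)
                row[name] = "" if value is None else value
            row["reference_causes"] = _causes_to_cell(r.reference_causes)
            row["pcva_causes"] = _causes_to_cell(r.pcva_causes)
            row["pcva_repeat_cause"] = (
                r.pcva_repeat_cause.value if r.pcva_repeat_cause else ""
            )
            writer.writerow(row)


# ---------------------------------------------------------------------------
# Sampling and stratification

def systematic_sample(ordered_ids: Sequence, interval: int, offset: int | None = None) -> list:
    """Every ``interval``-th element starting at 1-based position ``offset``.

    With the default ``offset = interval`` this takes the 5th, 10th, 15th, ...
    element when ``interval`` is 5 — a fixed-interval systematic sample of
    roughly 1/interval of the list, preserving input order.
    """
    if interval < 1:
        raise OutOfRangeError(f"interval must be >= 1, got {interval}")
    if offset is None:
        offset = interval
    if not (1 <= offset <= interval):
        raise OutOfRangeError(f"offset must be in [1, {interval}], got {offset}")
    return list(ordered_ids[offset - 1 :: interval])


def stratify(records: RecordSet, key: str) -> dict:
    """Partition records by ``site`` or ``age_group``; order preserving."""
    if key not in ("site", "age_group"):
        raise ValueError(f"key must be 'site' or 'age_group', got {key!r}")
    buckets: dict = {}
    for r in records:
        k = r.site if key == "site" else r.age_group
        buckets.setdefault(k, []).append(r)
    return {k: RecordSet(v) for k, v in buckets.items()}
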