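"""Daily-diary data model, CSV IO, validation and sample exclusions.

The canonical on-disk form is a long-format CSV: one row per person-day
with ``dyad_id``, ``role`` (adolescent/caregiver), ``day`` and one column
per emotion item.  A companion baseline CSV carries the one-time symptom
means (anxious/depressive item means on a 0-3 instrument scale) and the
adolescent gender group used for multigroup analysis.

Inclusion follows the diary-study convention: a dyad enters analysis only
if both members provided diary (Part 2) data and both have at least
``min_days`` days with at least one non-missing emotion rating — the
minimum needed for a stable emodiversity score.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field

from .items import ITEM_NAMES, RATING_MAX, RATING_MIN

logger = logging.getLogger(__name__)

ADOLESCENT = "adolescent"
CAREGIVER = "caregiver"
ROLES = (ADOLESCENT, CAREGIVER)

GENDER_GROUPS = ("boy", "girl", "other", "unreported")

SYMPTOM_MIN = 0.0
SYMPTOM_MAX = 3.0

# exclusion reason codes
NO_PARTNER_PART2 = "no-partner-part2"
FEWER_THAN_MIN_DAYS = "fewer-than-6-days"
PARTNER_INSUFFICIENT = "partner-insufficient"


class SchemaError(ValueError):
    """A mandatory column is absent from an input table."""


class ValidationError(ValueError):
    """A field value violates its declared bounds or uniqueness."""


@dataclass
class DailyReport:
    """One person-day of emotion ratings (missing items simply absent)."""

    dyad_id: str
    role: str
    day: int
    ratings: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(f"unknown role {self.role!r}")
        if self.day < 1:
            raise ValidationError(f"day must be >= 1, got {self.day}")
        for name, value in self.ratings.items():
            if name not in ITEM_NAMES:
                raise ValidationError(f"unknown emotion item {name!r}")
            if not (RATING_MIN <= value <= RATING_MAX):
                raise ValidationError(
                    f"rating {value} for {name!r} outside {RATING_MIN}..{RATING_MAX}"
                )

    @property
    def n_rated(self) -> int:
        return len(self.ratings)


@dataclass
class BaselineRecord:
    """Per-person baseline symptom means and demographic group."""

    dyad_id: str
    role: str
    anxious_mean: float | None = None
    depressive_mean: float | None = None
    gender_group: str = "unreported"

    def bounds_violations(self) -> list[str]:
        bad = []
        for label, v in (("anxious_mean", self.anxious_mean),
                         ("depressive_mean", self.depressive_mean)):
            if v is not None and not (SYMPTOM_MIN <= v <= SYMPTOM_MAX):
                bad.append(f"{label}={v}")
        return bad


@dataclass
class DyadRecord:
    """Both members' diaries and baselines for one dyad."""

    dyad_id: str
    adolescent_diary: list[DailyReport] = field(default_factory=list)
    caregiver_diary: list[DailyReport] = field(default_factory=list)
    adolescent_baseline: BaselineRecord | None = None
    caregiver_baseline: BaselineRecord | None = None

    def diary(self, role: str) -> list[DailyReport]:
        return self.adolescent_diary if role == ADOLESCENT else self.caregiver_diary

    def baseline(self, role: str) -> BaselineRecord | None:
        return self.adolescent_baseline if role == ADOLESCENT else self.caregiver_baseline


@dataclass
class ExclusionReport:
    n_input_dyads: int
    n_retained_dyads: int
    reasons: dict[str, tuple[str, ...]] = field(default_factory=dict)


DEFAULT_DIARY_SCHEMA = {"dyad_id": "dyad_id", "role": "role", "day": "day",
                        **{name: name for name in ITEM_NAMES}}
DEFAULT_BASELINE_SCHEMA = {
    "dyad_id": "dyad_id", "role": "role", "anxious_mean": "anxious_mean",
    "depressive_mean": "depressive_mean", "gender_group": "gender_group",
}


def _parse_rating(raw: str) -> int | None:
    """Integer 0-4, None for blank, ValueError-ish sentinel for garbage."""
    raw = raw.strip()
    if raw == "" or raw.upper() in ("NA", "NAN"):
        return None
    value = float(raw)  # may raise ValueError -> handled by caller
    if not value.is_integer():
        raise ValueError(raw)
    return int(value)


def read_diary_table(path, schema: dict[str, str] | None = None) -> list[DailyReport]:
    """Read a long-format diary CSV into typed reports.

    Unparseable ratings become missing with a logged warning; ratings
    outside 0-4 and duplicate (dyad, role, day) keys raise
    :class:`ValidationError` naming the offending row numbers.
    """
    schema = dict(DEFAULT_DIARY_SCHEMA if schema is None else schema)
    reports: list[DailyReport] = []
    out_of_range: list[int] = []
    seen: set[tuple[str, str, int]] = set()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for key in ("dyad_id", "role", "day"):
            if schema[key] not in header:
                raise SchemaError(f"missing mandatory column {schema[key]!r} in {path}")
        item_cols = {name: schema.get(name, name) for name in ITEM_NAMES
                     if schema.get(name, name) in header}
        if not item_cols:
            raise SchemaError(f"no emotion item columns found in {path}")
        for rownum, row in enumerate(reader, start=2):
            dyad_id = row[schema["dyad_id"]].strip()
            role = row[schema["role"]].strip()
            day = int(row[schema["day"]])
            key = (dyad_id, role, day)
            if key in seen:
                raise ValidationError(
                    f"duplicate (dyad, role, day) {key} at row {rownum} of {path}")
            seen.add(key)
            ratings: dict[str, int] = {}
            for name, col in item_cols.items():
                try:
                    value = _parse_rating(row[col])
                except ValueError:
                    logger.warning("row %d: unparseable rating %r for %s; treated as missing",
                                   rownum, row[col], name)
                    continue
                if value is None:
                    continue
                if not (RATING_MIN <= value <= RATING_MAX):
                    out_of_range.append(rownum)
                    continue
                ratings[name] = value
            reports.append(DailyReport(dyad_id, role, day, ratings))
    if out_of_range:
        raise ValidationError(
            f"ratings outside {RATING_MIN}..{RATING_MAX} at rows {sorted(set(out_of_range))} of {path}")
    return reports


def write_diary_table(reports: list[DailyReport], path, schema: dict[str, str] | None = None) -> None:
    """Write reports in the same CSV dialect :func:`read_diary_table` reads."""
    schema = dict(DEFAULT_DIARY_SCHEMA if schema is None else schema)
    cols = [schema["dyad_id"], schema["role"], schema["day"]] + \
        [schema.get(name, name) for name in ITEM_NAMES]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(cols)
        for rep in reports:
            row = [rep.dyad_id, rep.role, rep.day]
            row += ["" if name not in rep.ratings else rep.ratings[name]
                    for name in ITEM_NAMES]
            writer.writerow(row)


def read_baseline_table(path, schema: dict[str, str] | None = None,
                        strict_bounds: bool = False) -> list[BaselineRecord]:
    """Read the per-person baseline CSV.

    Symptom means outside the 0-3 instrument range raise in strict mode
    and are kept with a logged warning otherwise (synthetic cohorts with
    Gaussian outcome tails can graze the bound).
    """
    schema = dict(DEFAULT_BASELINE_SCHEMA if schema is None else schema)
    records: list[BaselineRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for key in ("dyad_id", "role"):
            if schema[key] not in header:
                raise SchemaError(f"missing mandatory column {schema[key]!r} in {path}")
        for rownum, row in enumerate(reader, start=2):
            def _num(colkey: str) -> float | None:
                col = schema.get(colkey)
                if col is None or col not in row or row[col].strip() in ("", "NA", "NaN", "nan"):
                    return None
                v = float(row[col])
                return None if math.isnan(v) else v

            gender_col = schema.get("gender_group")
            gender = (row.get(gender_col, "") or "").strip() if gender_col else ""
            rec = BaselineRecord(
                dyad_id=row[schema["dyad_id"]].strip(),
                role=row[schema["role"]].strip(),
                anxious_mean=_num("anxious_mean"),
                depressive_mean=_num("depressive_mean"),
                gender_group=gender if gender in GENDER_GROUPS else "unreported",
            )
            bad = rec.bounds_violations()
            if bad:
                msg = f"row {rownum}: symptom mean outside instrument bounds ({', '.join(bad)})"
                if strict_bounds:
                    raise ValidationError(msg)
                logger.warning("%s; kept", msg)
            records.append(rec)
    return records


def write_baseline_table(records: list[BaselineRecord], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["dyad_id", "role", "anxious_mean", "depressive_mean", "gender_group"])
        for rec in records:
            writer.writerow([
                rec.dyad_id, rec.role,
                "" if rec.anxious_mean is None else repr(rec.anxious_mean),
                "" if rec.depressive_mean is None else repr(rec.depressive_mean),
                rec.gender_group,
            ])


def build_dyads(reports: list[DailyReport],
                baselines: list[BaselineRecord] | None = None) -> list[DyadRecord]:
    """Group person-level reports and baselines into DyadRecords.

    Dyads appear in first-encounter order; a member with no diary rows
    simply has an empty diary (picked up by the exclusion rules).
    """
    dyads: dict[str, DyadRecord] = {}
    for rep in reports:
        rec = dyads.setdefault(rep.dyad_id, DyadRecord(rep.dyad_id))
        rec.diary(rep.role).append(rep)
    for base in baselines or []:
        rec = dyads.setdefault(base.dyad_id, DyadRecord(base.dyad_id))
        if base.role == ADOLESCENT:
            rec.adolescent_baseline = base
        else:
            rec.caregiver_baseline = base
    for rec in dyads.values():
        rec.adolescent_diary.sort(key=lambda r: r.day)
        rec.caregiver_diary.sort(key=lambda r: r.day)
    return list(dyads.values())


def n_diary_days(diary: list[DailyReport]) -> int:
    """Days that count toward inclusion: >=1 non-missing emotion rating."""
    return sum(1 for rep in diary if rep.n_rated > 0)


def apply_exclusions(dyads: list[DyadRecord], min_days: int = 6
                     ) -> tuple[list[DyadRecord], ExclusionReport]:
    """Apply the three inclusion rules symmetrically to each dyad.

    A dyad is retained only if both members participated in the diary
    phase and both contributed at least ``min_days`` countable days.
    Excluded dyads carry every reason code that applies.
    """
    if min_days < 1:
        raise ValueError("min_days must be >= 1")
    retained: list[DyadRecord] = []
    reasons: dict[str, tuple[str, ...]] = {}
    for dyad in dyads:
        d_a = n_diary_days(dyad.adolescent_diary)
        d_c = n_diary_days(dyad.caregiver_diary)
        codes: list[str] = []
        if d_a == 0 or d_c == 0:
            codes.append(NO_PARTNER_PART2)
        if 0 < d_a < min_days or 0 < d_c < min_days:
            codes.append(FEWER_THAN_MIN_DAYS)
            codes.append(PARTNER_INSUFFICIENT)
        if codes:
            reasons[dyad.dyad_id] = tuple(dict.fromkeys(codes))
            logger.info("excluding dyad %s: %s", dyad.dyad_id, ", ".join(codes))
        else:
            retained.append(dyad)
    return retained, ExclusionReport(len(dyads), len(retained), reasons)
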