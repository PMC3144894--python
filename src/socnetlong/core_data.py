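"""Data model, readers/writers, age estimation and age-class assignment.

Field studies of marked social mammals produce two long-format tables:
daily observation records (one row per individual per interaction event)
and individual capture records.  This module parses both, estimates the
age of animals not captured as pups from a log-log body-weight
regression, and assigns the three age classes (pup / juvenile / adult)
used throughout the analysis.
"""

from __future__ import annotations

import datetime as _dt
import enum
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import DomainError, NotApplicableError, RecordError, SchemaError

__all__ = [
    "Sex",
    "InteractionType",
    "AgeClass",
    "Individual",
    "ObservationRecord",
    "NetworkPeriod",
    "AgeModel",
    "MALE_AGE_MODEL",
    "FEMALE_AGE_MODEL",
    "read_observations",
    "write_observations",
    "read_individuals",
    "write_individuals",
    "estimate_age",
    "assign_age_class",
    "reference_birthdate",
]


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"
    UNKNOWN = "unknown"


class InteractionType(str, enum.Enum):
    AFFILIATIVE_CONTACT = "affiliative_contact"   # huddle / shared sleeping burrow
    COORDINATED_ACTIVITY = "coordinated_activity"  # move or sit together
    AGONISTIC = "agonistic"
    TREE_FORAGING = "tree_foraging"


class AgeClass(str, enum.Enum):
    PUP = "pup"          # <= 1 year
    JUVENILE = "juvenile"  # (1, 2) years
    ADULT = "adult"      # >= 2 years


@dataclass(frozen=True)
class Individual:
    id: str
    sex: Sex = Sex.UNKNOWN
    first_capture_date: _dt.date | None = None
    birth_reference_date: _dt.date | None = None
    body_weight_kg: float | None = None
    known_age: bool = False

    def __post_init__(self):
        if self.body_weight_kg is not None and self.body_weight_kg <= 0:
            raise DomainError(f"body_weight_kg must be positive, got {self.body_weight_kg}")


@dataclass(frozen=True)
class ObservationRecord:
    date: _dt.date
    site: str
    event_id: str
    individual_id: str
    interaction_type: InteractionType
    marked: bool = True


@dataclass(frozen=True)
class NetworkPeriod:
    """A site-by-season window over which one association network is built."""

    site: str
    label: str
    days: tuple[_dt.date, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "days", tuple(sorted(set(self.days))))

    def contains(self, record: ObservationRecord) -> bool:
        return record.site == self.site and (not self.days or record.date in set(self.days))


@dataclass(frozen=True)
class AgeModel:
    """log(age) = intercept + slope * log(body weight), logs in ``log_base``.

    The default male/female models (``MALE_AGE_MODEL``, ``FEMALE_AGE_MODEL``)
    use base-10 logs with age in days — the only base/unit combination that
    yields plausible adult ages for a 3–4 kg animal.  Both are configurable.
    """

    intercept: float
    slope: float
    log_base: float = 10.0
    age_unit: str = "days"  # "days" or "years"

    def __post_init__(self):
        if self.slope <= 0:
            raise DomainError("age-model slope must be positive")
        if self.log_base <= 0 or self.log_base == 1.0:
            raise DomainError("log_base must be positive and != 1")
        if self.age_unit not in ("days", "years"):
            raise DomainError(f"age_unit must be 'days' or 'years', got {self.age_unit!r}")


MALE_AGE_MODEL = AgeModel(intercept=2.3250903, slope=1.3498142)
FEMALE_AGE_MODEL = AgeModel(intercept=2.3711934, slope=1.4997657)

DAYS_PER_YEAR = 365.25

_OBS_COLUMNS = ("date", "site", "event_id", "individual_id", "interaction_type", "marked")


def _parse_date(value, row: int) -> _dt.date:
    try:
        return pd.Timestamp(value).date()
    except (ValueError, TypeError) as exc:
        raise RecordError(f"unparseable date {value!r}", row=row) from exc


def read_observations(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
) -> list[ObservationRecord]:
    """Read a long-format observation CSV (one row per individual per event).

    Parameters
    ----------
    path:
        CSV file with columns date (ISO-8601), site, event_id,
        individual_id, interaction_type, marked (0/1).
    schema:
        Optional mapping from the canonical column names above to the
        names actually used in the file.

    Raises
    ------
    SchemaError
        If a required column is missing (the message names it).
    RecordError
        For an unparseable date, an unknown interaction type, or a
        duplicated (event_id, individual_id) pair; the message carries
        the 1-based data row number.
    """
    schema = dict(schema or {})
    frame = pd.read_csv(path, dtype=str)
    colmap = {canon: schema.get(canon, canon) for canon in _OBS_COLUMNS}
    for canon, actual in colmap.items():
        if actual not in frame.columns:
            raise SchemaError(f"missing required column {actual!r} (for {canon!r})")

    records: list[ObservationRecord] = []
    seen: set[tuple[str, str]] = set()
    for i, row in enumerate(frame.to_dict("records"), start=1):
        raw = {canon: row[actual] for canon, actual in colmap.items()}
        date = _parse_date(raw["date"], i)
        try:
            itype = InteractionType(str(raw["interaction_type"]))
        except ValueError:
            raise RecordError(
                f"unknown interaction_type {raw['interaction_type']!r}", row=i
            ) from None
        key = (str(raw["event_id"]), str(raw["individual_id"]))
        if key in seen:
            raise RecordError(f"duplicate (event_id, individual_id) pair {key}", row=i)
        seen.add(key)
        marked = str(raw["marked"]).strip().lower() not in ("0", "false", "no")
        records.append(
            ObservationRecord(
                date=date,
                site=str(raw["site"]),
                event_id=str(raw["event_id"]),
                individual_id=str(raw["individual_id"]),
                interaction_type=itype,
                marked=marked,
            )
        )
    return records


def write_observations(records: Iterable[ObservationRecord], path: str | Path) -> None:
    rows = [
        {
            "date": r.date.isoformat(),
            "site": r.site,
            "event_id": r.event_id,
            "individual_id": r.individual_id,
            "interaction_type": r.interaction_type.value,
            "marked": int(r.marked),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(_OBS_COLUMNS)).to_csv(path, index=False)


def read_individuals(path: str | Path) -> list[Individual]:
    """Read the individuals CSV: id, sex, first_capture_date, body_weight_kg, known_age."""
    frame = pd.read_csv(path, dtype=str)
    required = ("id", "sex")
    for col in required:
        if col not in frame.columns:
            raise SchemaError(f"missing required column {col!r}")
    out: list[Individual] = []
    ids: set[str] = set()
    for i, row in enumerate(frame.to_dict("records"), start=1):
        rid = str(row["id"])
        if rid in ids:
            raise RecordError(f"duplicate individual id {rid!r}", row=i)
        ids.add(rid)
        weight = row.get("body_weight_kg")
        weight = float(weight) if weight not in (None, "") and not pd.isna(weight) else None
        fcd = row.get("first_capture_date")
        fcd = _parse_date(fcd, i) if fcd not in (None, "") and not pd.isna(fcd) else None
        known = str(row.get("known_age", "0")).strip().lower() in ("1", "true", "yes")
        try:
            sex = Sex(str(row["sex"]))
        except ValueError:
            raise RecordError(f"unknown sex {row['sex']!r}", row=i) from None
        out.append(
            Individual(
                id=rid, sex=sex, first_capture_date=fcd,
                body_weight_kg=weight, known_age=known,
            )
        )
    return out


def write_individuals(individuals: Iterable[Individual], path: str | Path) -> None:
    rows = [
        {
            "id": ind.id,
            "sex": ind.sex.value,
            "first_capture_date": ind.first_capture_date.isoformat()
            if ind.first_capture_date else "",
            "body_weight_kg": ind.body_weight_kg if ind.body_weight_kg is not None else "",
            "known_age": int(ind.known_age),
        }
        for ind in individuals
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def estimate_age(
    body_weight_kg: float,
    sex: Sex | str = Sex.UNKNOWN,
    model: AgeModel | None = None,
) -> float:
    """Estimate age from body weight via the log-log regression.

    age = base ** (intercept + slope * log_base(weight)), in the model's
    ``age_unit``.  When ``model`` is omitted the sex-specific default
    model is used; for unknown sex an explicit model is required.
    """
    if body_weight_kg <= 0:
        raise DomainError(f"body weight must be positive, got {body_weight_kg}")
    if model is None:
        sex = Sex(sex)
        if sex is Sex.MALE:
            model = MALE_AGE_MODEL
        elif sex is Sex.FEMALE:
            model = FEMALE_AGE_MODEL
        else:
            raise DomainError("no default age model for unknown sex; pass model=")
    log_w = math.log(body_weight_kg, model.log_base)
    return model.log_base ** (model.intercept + model.slope * log_w)


def age_in_years(age: float, model: AgeModel) -> float:
    """Convert an ``estimate_age`` output to years."""
    return age / DAYS_PER_YEAR if model.age_unit == "days" else age


def assign_age_class(age_years: float) -> AgeClass:
    """Pups are <=1 year, juveniles in (1, 2) years, adults >=2 years."""
    if age_years < 0:
        raise DomainError(f"age must be non-negative, got {age_years}")
    if age_years <= 1.0:
        return AgeClass.PUP
    if age_years < 2.0:
        return AgeClass.JUVENILE
    return AgeClass.ADULT


def reference_birthdate(capture_year: int, age_class_at_capture: AgeClass | str) -> _dt.date:
    """March-1 reference birthdate for synchronously breeding populations.

    Pups are aged from March 1 of the capture year; one-year-old juveniles
    from March 1 of the previous year.  Adults have no reference date —
    their age comes from the weight regression — so the adult class raises
    :class:`NotApplicableError`.
    """
    age_class_at_capture = AgeClass(age_class_at_capture)
    if age_class_at_capture is AgeClass.PUP:
        return _dt.date(capture_year, 3, 1)
    if age_class_at_capture is AgeClass.JUVENILE:
        return _dt.date(capture_year - 1, 3, 1)
    raise NotApplicableError("adults are aged from the body-weight model, not a reference date")


def age_at_death_years(
    birth_reference: _dt.date,
    last_seen: _dt.date,
    fractional: bool = False,
) -> float:
    """Age at death, in years to the last season an individual was seen.

    Default is whole years between the March-1 birth reference and the
    March 1 of the last season seen; ``fractional=True`` keeps the exact
    day difference divided by 365.25.
    """
    if last_seen < birth_reference:
        raise DomainError("last_seen precedes the birth reference date")
    if fractional:
        return (last_seen - birth_reference).days / DAYS_PER_YEAR
    last_march = _dt.date(last_seen.year if last_seen.month >= 3 else last_seen.year - 1, 3, 1)
    return max(0, round((last_march - birth_reference).days / DAYS_PER_YEAR))
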