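"""Validated record types shared across the soil-ingestion exposure pipeline.

The vocabulary follows the soil-contact activity questionnaire: a grower
reports, for each season, how often they are on site at all (days/week,
hours/day) and how often they perform each of six meso-activities
(days/month, hours/day), together with the fraction of task time their
hands are in direct contact with soil and behavioural context (glove use,
handwashing, ergonomic position). Demographics and a body-weight table
round out the inputs the dose models need.

Validation never raises: :func:`validate_record` returns a list of
violations so callers can decide whether to drop, fix or fail.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Optional

__all__ = [
    "Season",
    "MesoActivity",
    "Sex",
    "Position",
    "AmountCategory",
    "FarmSizeUnit",
    "TaskActivity",
    "OnSiteActivity",
    "IngestionReport",
    "SeasonRecord",
    "GrowerRecord",
    "BodyWeightBracket",
    "WeightedBodyWeight",
    "BodyWeightTable",
    "Violation",
    "validate_record",
    "DomainError",
    "ConfigurationError",
    "HECTARES_PER_ACRE",
]

HECTARES_PER_ACRE = 0.404686


class DomainError(ValueError):
    """An input violates a documented precondition of an operation."""


class ConfigurationError(ValueError):
    """A configuration object (pools, tables, spec) is unusable as given."""


class Season(str, enum.Enum):
    """The four questionnaire waves; reporting order is spring → winter."""

    SPRING = "spring"
    SUMMER = "summer"
    FALL = "fall"
    WINTER = "winter"


SEASON_ORDER: tuple[Season, ...] = tuple(Season)


class MesoActivity(str, enum.Enum):
    """The six agricultural tasks the questionnaire asks about."""

    BED_PREPARATION = "bed_preparation"
    PLANTING_SEEDS = "planting_seeds"
    TRANSPLANTING = "transplanting"
    IRRIGATION = "irrigation"
    WEEDING = "weeding"
    HARVESTING = "harvesting"


ACTIVITY_ORDER: tuple[MesoActivity, ...] = tuple(MesoActivity)


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class Position(str, enum.Enum):
    """Ergonomic orientation while performing a task."""

    KNEELING = "kneeling"
    STANDING = "standing"
    BENDING = "bending"
    SITTING = "sitting"
    OTHER = "other"


class AmountCategory(str, enum.Enum):
    """Spoon-image anchors for self-reported daily soil ingestion (mg/day)."""

    LT10 = "lt10"
    MG10 = "10"
    MG20 = "20"
    MG50 = "50"
    MG100 = "100"
    MG200 = "200"
    MG1000 = "1000"
    GT1000 = "gt1000"


class FarmSizeUnit(str, enum.Enum):
    HECTARES = "ha"
    ACRES = "acre"


@dataclass(frozen=True)
class TaskActivity:
    """One grower × season × meso-activity questionnaire row.

    ``days_per_month == 0`` means the grower did not engage in the activity
    that season (``hours_per_day`` must then be 0 too). ``contact_fraction``
    is stored as a proportion on [0, 1]; percent is accepted only at the
    file boundary (see :mod:`mesodose.io`).
    """

    grower_id: str
    season: Season
    activity: MesoActivity
    days_per_month: float
    hours_per_day: float
    contact_fraction: float
    glove_use: Optional[bool] = None
    glove_time_fraction: Optional[float] = None
    handwash_after: Optional[bool] = None
    positions: frozenset[Position] = frozenset()

    @property
    def engaged(self) -> bool:
        return self.days_per_month > 0

    @property
    def hours_per_month(self) -> float:
        return self.hours_per_day * self.days_per_month


@dataclass(frozen=True)
class OnSiteActivity:
    """Overall on-site frequency/duration for one grower × season."""

    grower_id: str
    season: Season
    days_per_week: float
    hours_per_day: float


@dataclass(frozen=True)
class IngestionReport:
    """Self-reported incidental-ingestion events and related behaviours.

    These are recorded for context and reliability work only; the dose
    models never use them to adjust exposure.
    """

    grower_id: str
    season: Season
    soil_in_mouth: bool
    days_with_ingestion: Optional[int] = None
    amount_category: Optional[AmountCategory] = None
    face_contact: bool = False
    face_contact_days: Optional[int] = None
    produce_sampling: bool = False
    produce_events_per_month: Optional[float] = None
    produce_wash_fraction: Optional[float] = None
    meals_onsite: bool = False


@dataclass(frozen=True)
class SeasonRecord:
    """Everything one grower reported for one season."""

    onsite: OnSiteActivity
    tasks: Mapping[MesoActivity, TaskActivity]
    ingestion: Optional[IngestionReport] = None


@dataclass(frozen=True)
class GrowerRecord:
    """Demographics plus per-season questionnaire responses for one grower.

    ``employment_status`` is ordinal: 1 = full time, 2 = part time,
    3 = unemployed / retired / other. ``body_weight`` (kg), when present,
    overrides any body-weight table lookup.
    """

    grower_id: str
    sex: Sex
    age: float
    smoking: bool
    employment_status: int
    farm_size: float
    farm_size_unit: FarmSizeUnit
    body_weight: Optional[float]
    seasons: Mapping[Season, SeasonRecord]

    @property
    def farm_size_ha(self) -> float:
        """Farm size in the canonical unit (hectares)."""
        if self.farm_size_unit is FarmSizeUnit.ACRES:
            return self.farm_size * HECTARES_PER_ACRE
        return self.farm_size


@dataclass(frozen=True)
class BodyWeightBracket:
    sex: Sex
    age_low: float  # inclusive
    age_high: float  # exclusive
    median_kg: float


@dataclass(frozen=True)
class WeightedBodyWeight:
    weight_kg: float
    population_weight: float


@dataclass(frozen=True)
class BodyWeightTable:
    """Body weights either as sex × age-bracket medians or a weighted sample.

    ``median_lookup`` mode serves the empirical dose estimates (one median
    per sex and adult age bracket); ``weighted_sample`` mode serves the
    Monte Carlo simulation, where each (weight, population weight) row is
    drawn with probability proportional to its weight. Population weights
    need not sum to one; they are normalised at sampling time.
    """

    mode: str  # "median_lookup" | "weighted_sample"
    brackets: tuple[BodyWeightBracket, ...] = ()
    samples: tuple[WeightedBodyWeight, ...] = ()

    def __post_init__(self) -> None:
        if self.mode not in ("median_lookup", "weighted_sample"):
            raise ConfigurationError(f"unknown body-weight table mode {self.mode!r}")
        if self.mode == "median_lookup":
            for b in self.brackets:
                if b.median_kg <= 0:
                    raise ConfigurationError(
                        f"non-positive median body weight {b.median_kg} in bracket {b}"
                    )
        else:
            for s in self.samples:
                if s.population_weight <= 0:
                    raise ConfigurationError(
                        f"non-positive population weight {s.population_weight}"
                    )


@dataclass(frozen=True)
class Violation:
    """One validation failure: which field, where, and which rule broke."""

    field: str
    location: str
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.location}: {self.field}: {self.rule}"


def _check(violations: list[Violation], ok: bool, field_name: str, location: str, rule: str) -> None:
    if not ok:
        violations.append(Violation(field=field_name, location=location, rule=rule))


def validate_record(record: GrowerRecord) -> list[Violation]:
    """Check every type invariant on ``record``; return all violations.

    Never raises. An empty list means the record fully conforms. Idempotent
    and side-effect-free: the record is not modified.
    """
    v: list[Violation] = []
    loc = f"grower {record.grower_id}"
    _check(v, record.age >= 18, "age", loc, "age must be >= 18")
    _check(v, record.employment_status in (1, 2, 3), "employment_status", loc,
           "employment_status must be 1, 2 or 3")
    _check(v, record.farm_size >= 0, "farm_size", loc, "farm_size must be >= 0")
    if record.body_weight is not None:
        _check(v, record.body_weight > 0, "body_weight", loc, "body_weight must be > 0 kg")
    _check(v, len(record.seasons) >= 1, "seasons", loc, "at least one season must be present")

    for season, srec in record.seasons.items():
        sloc = f"{loc}, {season.value}"
        onsite = srec.onsite
        _check(v, 0 <= onsite.days_per_week <= 7, "days_per_week", sloc,
               "days_per_week must lie in [0, 7]")
        _check(v, 0 <= onsite.hours_per_day <= 24, "hours_per_day", sloc,
               "on-site hours_per_day must lie in [0, 24]")
        for activity, task in srec.tasks.items():
            tloc = f"{sloc}, {activity.value}"
            _check(v, 0 <= task.days_per_month <= 31, "days_per_month", tloc,
                   "days_per_month must lie in [0, 31]")
            _check(v, 0 <= task.hours_per_day <= 24, "hours_per_day", tloc,
                   "hours_per_day must lie in [0, 24]")
            _check(v, 0 <= task.contact_fraction <= 1, "contact_fraction", tloc,
                   "contact_fraction must lie in [0, 1]")
            if task.days_per_month == 0:
                _check(v, task.hours_per_day == 0, "hours_per_day", tloc,
                       "hours_per_day must be 0 when days_per_month is 0 (non-engagement)")
            if task.glove_time_fraction is not None:
                _check(v, 0 <= task.glove_time_fraction <= 1, "glove_time_fraction", tloc,
                       "glove_time_fraction must lie in [0, 1]")
        ing = srec.ingestion
        if ing is not None:
            iloc = f"{sloc}, ingestion"
            if ing.days_with_ingestion is not None:
                _check(v, ing.soil_in_mouth, "days_with_ingestion", iloc,
                       "days_with_ingestion present only when soil_in_mouth is true")
                _check(v, 0 <= ing.days_with_ingestion <= 30, "days_with_ingestion", iloc,
                       "days_with_ingestion must lie in [0, 30]")
            if ing.produce_wash_fraction is not None:
                _check(v, 0 <= ing.produce_wash_fraction <= 1, "produce_wash_fraction", iloc,
                       "produce_wash_fraction must lie in [0, 1]")
    return v
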