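"""Frequency/duration exposure factors derived from questionnaire records.

The dose equations consume three exposure factors per grower-season:

* days on site per month = (days/week) × 4.35, the average weeks per month;
* hours on site per month = (hours/day) × (days/week) × 4.35;
* hours per month on each meso-activity = (hours/day) × (days/month).

The same 4.35 constant fixes the averaging times: 30.5 days for the daily
dose model and 730.8 h (= 4.35 × 7 × 24) for the hourly models. Note the
stated daily averaging time (30.5) and 4.35 × 7 (= 30.45) disagree in the
source defaults; both are carried as-is, never reconciled.

The within-grower reliability check subtracts total task hours from total
on-site hours: a positive difference is on-site time not attributable to
the six tasks, a negative one signals concurrent tasks (e.g. weeding while
irrigating).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

from .domain_types import (
    DomainError,
    GrowerRecord,
    MesoActivity,
    Season,
    TaskActivity,
)

__all__ = [
    "WEEKS_PER_MONTH",
    "HOURS_PER_MONTH",
    "DAYS_PER_MONTH_AVERAGING_METHOD1",
    "OUTDOOR_WORKDAY_HOURS",
    "INDOOR_NONWORK_HOURS",
    "TimeConstants",
    "ExposureFactorSet",
    "days_per_month_onsite",
    "hours_per_month_onsite",
    "task_hours_per_month",
    "reliability_difference",
    "mean_contact_fraction",
    "cohort_contact_means",
    "derive_exposure_factors",
    "cohort_exposure_factors",
]

WEEKS_PER_MONTH = 4.35
#: 4.35 weeks × 7 days × 24 h; equals the 730.8 literal exactly in binary float.
HOURS_PER_MONTH = 730.8
#: Averaging time for the daily-rate dose model, in days (as stated: 30.5,
#: not the 30.45 that 4.35 × 7 would give).
DAYS_PER_MONTH_AVERAGING_METHOD1 = 30.5
OUTDOOR_WORKDAY_HOURS = 8.0
INDOOR_NONWORK_HOURS = 16.0


@dataclass(frozen=True)
class TimeConstants:
    """The time-conversion constants the three dose methods share."""

    weeks_per_month: float = WEEKS_PER_MONTH
    hours_per_month: float = HOURS_PER_MONTH
    days_per_month_avg_method1: float = DAYS_PER_MONTH_AVERAGING_METHOD1
    hours_per_day: float = 24.0
    outdoor_workday_hours: float = OUTDOOR_WORKDAY_HOURS
    indoor_nonwork_hours: float = INDOOR_NONWORK_HOURS


@dataclass(frozen=True)
class ExposureFactorSet:
    """Derived exposure factors for one grower × season."""

    grower_id: str
    season: Season
    days_per_month_onsite: float
    hours_per_month_onsite: float
    task_hours_per_month: Mapping[MesoActivity, float]
    reliability_difference: float


def days_per_month_onsite(days_per_week: float) -> float:
    """Days on site per month: ``days_per_week`` × 4.35, full precision."""
    if not 0 <= days_per_week <= 7:
        raise DomainError(f"days_per_week must lie in [0, 7], got {days_per_week}")
    return days_per_week * WEEKS_PER_MONTH


def hours_per_month_onsite(hours_per_day: float, days_per_week: float) -> float:
    """Hours on site per month: hours/day × days/week × 4.35 (≤ 730.8)."""
    if not 0 <= hours_per_day <= 24:
        raise DomainError(f"hours_per_day must lie in [0, 24], got {hours_per_day}")
    return hours_per_day * days_per_month_onsite(days_per_week)


def task_hours_per_month(hours_per_day: float, days_per_month: float) -> float:
    """Hours per month on one task: hours/day × days/month."""
    if hours_per_day < 0:
        raise DomainError(f"hours_per_day must be >= 0, got {hours_per_day}")
    if days_per_month < 0:
        raise DomainError(f"days_per_month must be >= 0, got {days_per_month}")
    return hours_per_day * days_per_month


def reliability_difference(
    onsite_hours_per_month: float, task_hours: Mapping[MesoActivity, float]
) -> float:
    """On-site hours minus total task hours (signed).

    Positive: on-site time unaccounted for by the six tasks. Negative:
    reported task time exceeds on-site time, a concurrent-activity signal.
    """
    return onsite_hours_per_month - sum(task_hours.values())


def mean_contact_fraction(
    activities: Iterable[TaskActivity],
    activity: MesoActivity,
    season: Optional[Season] = None,
) -> Optional[float]:
    """Mean soil-contact fraction among growers engaged in ``activity``.

    Pools all seasons by default (pass ``season`` for a per-season mean).
    Non-engaged rows (``days_per_month == 0``) are excluded before
    averaging. Returns ``None`` — an explicit no-data result, not zero —
    when no engaged record matches.
    """
    values = [
        t.contact_fraction
        for t in activities
        if t.activity is activity and t.engaged and (season is None or t.season is season)
    ]
    if not values:
        return None
    return sum(values) / len(values)


def _all_tasks(records: Iterable[GrowerRecord]) -> list[TaskActivity]:
    return [
        task
        for record in records
        for srec in record.seasons.values()
        for task in srec.tasks.values()
    ]


def cohort_contact_means(
    records: Iterable[GrowerRecord], season: Optional[Season] = None
) -> dict[MesoActivity, Optional[float]]:
    """Per-activity mean contact fractions over a cohort (pooled seasons)."""
    tasks = _all_tasks(records)
    return {a: mean_contact_fraction(tasks, a, season=season) for a in MesoActivity}


def derive_exposure_factors(record: GrowerRecord) -> list[ExposureFactorSet]:
    """Exposure factors for every season a grower reported.

    Activities without a questionnaire row count as non-engagement
    (0 h/month), so the reliability difference is defined for every season.
    """
    out = []
    for season, srec in record.seasons.items():
        onsite_h = hours_per_month_onsite(
            srec.onsite.hours_per_day, srec.onsite.days_per_week
        )
        task_h = {
            a: task_hours_per_month(t.hours_per_day, t.days_per_month)
            for a, t in srec.tasks.items()
        }
        for a in MesoActivity:
            task_h.setdefault(a, 0.0)
        out.append(
            ExposureFactorSet(
                grower_id=record.grower_id,
                season=season,
                days_per_month_onsite=days_per_month_onsite(srec.onsite.days_per_week),
                hours_per_month_onsite=onsite_h,
                task_hours_per_month=task_h,
                reliability_difference=reliability_difference(onsite_h, task_h),
            )
        )
    return out


def cohort_exposure_factors(records: Iterable[GrowerRecord]) -> list[ExposureFactorSet]:
    """Exposure factors for every grower × season in a cohort."""
    return [efs for record in records for efs in derive_exposure_factors(record)]
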