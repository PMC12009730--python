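"""Average daily dose (ADD) models for incidental soil ingestion.

All three methods evaluate the standard intake equation

    ADD = (C × IR × EF × ED) / (BW × AT)        [mg contaminant / kgBW / day]

for a hypothetical soil contaminant at concentration C (default
400 mg/kg), with the ingestion rate converted from mg to kg of soil by a
single factor of 1e-6 applied here and nowhere else, and an exposure
duration ED of one month throughout. The methods differ in resolution:

* Method 1 (daily): IR = 378 mg/day on days worked; EF in days/month; AT
  = 30.5 days.
* Method 2 (hourly): outdoor hours at 45.25 mg/h, the complementary
  indoor hours (730.8 − outdoor) at 1.375 mg/h; AT = 730.8 h; the hourly
  dose is multiplied by 24 to convert to a daily dose.
* Method 3 (hourly, task-specific): each task's hours/month at its scaled
  rate; all remaining hours are assumed indoors at 1.375 mg/h.

Body weight comes from a sex × age-bracket median table unless the grower
supplied a weight. Glove use, handwashing and position are never applied
as dose modifiers: the models do not account for them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .domain_types import (
    BodyWeightTable,
    DomainError,
    GrowerRecord,
    MesoActivity,
    Season,
)
from .exposure_factors import (
    DAYS_PER_MONTH_AVERAGING_METHOD1,
    HOURS_PER_MONTH,
    cohort_contact_means,
    derive_exposure_factors,
)
from .ingestion_rates import IngestionRateSet, build_rate_set

__all__ = [
    "MG_PER_KG",
    "DEFAULT_CONCENTRATION_MG_PER_KG",
    "ADDResult",
    "AnnualSummary",
    "add_method1",
    "add_method2",
    "add_method3",
    "body_weight_for",
    "annualize",
    "estimate_cohort",
    "results_to_frame",
]

#: kg of soil per mg of soil; the one place mass units are converted.
MG_PER_KG = 1e-6
DEFAULT_CONCENTRATION_MG_PER_KG = 400.0
HOURS_PER_DAY = 24.0


@dataclass(frozen=True)
class ADDResult:
    """One grower × season × method dose, decomposed where applicable.

    ``add_total = add_outdoor + add_indoor`` always; for Method 3
    ``add_outdoor = Σ add_by_task``. All components are in mg/kgBW/day.
    """

    grower_id: str
    season: Optional[Season]
    method: int
    add_total: float
    add_outdoor: float
    add_indoor: float
    add_by_task: Optional[Mapping[MesoActivity, float]] = None
    flags: frozenset[str] = frozenset()


@dataclass(frozen=True)
class AnnualSummary:
    """Aggregate of four seasonal doses for one grower × method.

    ``cumulative`` (the sum of the four seasonal ADDs) is an annual
    exposure index, not a dose rate; ``time_weighted_mean`` is their mean.
    """

    grower_id: str
    method: int
    cumulative: float
    time_weighted_mean: float
    seasonal: Mapping[Season, float]


def _require_positive(name: str, value: float) -> None:
    if value <= 0:
        raise DomainError(f"{name} must be > 0, got {value}")


def add_method1(
    C: float,
    IR_daily: float,
    days_per_month: float,
    BW: float,
    AT_days: float = DAYS_PER_MONTH_AVERAGING_METHOD1,
    grower_id: str = "",
    season: Optional[Season] = None,
) -> ADDResult:
    """Daily-rate dose: (C × IR×1e-6 × days/month × 1) / (BW × AT_days)."""
    _require_positive("C", C)
    _require_positive("IR_daily", IR_daily)
    _require_positive("BW", BW)
    _require_positive("AT_days", AT_days)
    if days_per_month < 0:
        raise DomainError(f"days_per_month must be >= 0, got {days_per_month}")
    add = (C * IR_daily * MG_PER_KG * days_per_month) / (BW * AT_days)
    return ADDResult(
        grower_id=grower_id, season=season, method=1,
        add_total=add, add_outdoor=add, add_indoor=0.0,
    )


def add_method2(
    C: float,
    hourly_outdoor: float,
    hourly_indoor: float,
    outdoor_hours_per_month: float,
    BW: float,
    AT_hours: float = HOURS_PER_MONTH,
    grower_id: str = "",
    season: Optional[Season] = None,
) -> ADDResult:
    """Hourly-rate dose from outdoor work hours and complementary indoor hours.

    The indoor exposure frequency is defined as ``AT_hours − outdoor``, so
    outdoor hours above the averaging time are a domain error (clamping
    would break the complement definition). Each hourly dose is multiplied
    by 24 to express it per day.
    """
    _require_positive("C", C)
    _require_positive("hourly_outdoor", hourly_outdoor)
    _require_positive("hourly_indoor", hourly_indoor)
    _require_positive("BW", BW)
    _require_positive("AT_hours", AT_hours)
    if not 0 <= outdoor_hours_per_month <= AT_hours:
        raise DomainError(
            f"outdoor_hours_per_month must lie in [0, {AT_hours}], got {outdoor_hours_per_month}"
        )
    indoor_hours = AT_hours - outdoor_hours_per_month
    scale = HOURS_PER_DAY * C * MG_PER_KG / (BW * AT_hours)
    add_out = scale * hourly_outdoor * outdoor_hours_per_month
    add_in = scale * hourly_indoor * indoor_hours
    return ADDResult(
        grower_id=grower_id, season=season, method=2,
        add_total=add_out + add_in, add_outdoor=add_out, add_indoor=add_in,
    )


def add_method3(
    C: float,
    rate_set: IngestionRateSet,
    task_hours: Mapping[MesoActivity, float],
    BW: float,
    AT_hours: float = HOURS_PER_MONTH,
    grower_id: str = "",
    season: Optional[Season] = None,
) -> ADDResult:
    """Task-specific hourly dose; unaccounted hours are indoors.

    Indoor hours are ``max(0, AT_hours − Σ task hours)``; when reported
    task hours exceed the averaging time (concurrent tasks), the indoor
    term is clamped to zero and the result is flagged
    ``indoor_hours_clamped``.
    """
    _require_positive("C", C)
    _require_positive("BW", BW)
    _require_positive("AT_hours", AT_hours)
    for a, h in task_hours.items():
        if h < 0:
            raise DomainError(f"task hours for {a.value!r} must be >= 0, got {h}")
    scale = HOURS_PER_DAY * C * MG_PER_KG / (BW * AT_hours)
    by_task = {
        a: scale * rate_set.task_rates[a] * task_hours.get(a, 0.0) for a in MesoActivity
    }
    total_task_hours = sum(task_hours.values())
    flags: frozenset[str] = frozenset()
    indoor_hours = AT_hours - total_task_hours
    if indoor_hours < 0:
        indoor_hours = 0.0
        flags = frozenset({"indoor_hours_clamped"})
    add_out = sum(by_task.values())
    add_in = scale * rate_set.hourly_indoor * indoor_hours
    return ADDResult(
        grower_id=grower_id, season=season, method=3,
        add_total=add_out + add_in, add_outdoor=add_out, add_indoor=add_in,
        add_by_task=by_task, flags=flags,
    )


def body_weight_for(grower: GrowerRecord, table: BodyWeightTable) -> float:
    """Body weight in kg: the grower's own value, else the bracket median.

    The table must be in ``median_lookup`` mode; brackets are half-open
    [age_low, age_high). An age outside the table's coverage for the
    grower's sex is a lookup error naming the gap.
    """
    if grower.body_weight is not None:
        return grower.body_weight
    if table.mode != "median_lookup":
        raise DomainError("body_weight_for requires a median_lookup table")
    for b in table.brackets:
        if b.sex is grower.sex and b.age_low <= grower.age < b.age_high:
            return b.median_kg
    raise DomainError(
        f"no body-weight bracket covers sex={grower.sex.value}, age={grower.age}"
    )


def annualize(seasonal: Sequence[ADDResult]) -> AnnualSummary:
    """Combine exactly four seasonal doses (one grower, one method).

    Returns both the cumulative annual index (sum) and the time-weighted
    mean, retaining the seasonal decomposition.
    """
    if len(seasonal) != 4:
        raise DomainError(f"annualize requires exactly 4 seasonal results, got {len(seasonal)}")
    seasons = {r.season for r in seasonal}
    if len(seasons) != 4 or None in seasons:
        raise DomainError("annualize requires one result per distinct season")
    if len({r.grower_id for r in seasonal}) != 1 or len({r.method for r in seasonal}) != 1:
        raise DomainError("annualize requires a single grower and a single method")
    total = sum(r.add_total for r in seasonal)
    return AnnualSummary(
        grower_id=seasonal[0].grower_id,
        method=seasonal[0].method,
        cumulative=total,
        time_weighted_mean=total / 4.0,
        seasonal={r.season: r.add_total for r in seasonal},
    )


def estimate_cohort(
    records: Iterable[GrowerRecord],
    bodyweight_table: BodyWeightTable,
    method: int,
    rate_set: Optional[IngestionRateSet] = None,
    C: float = DEFAULT_CONCENTRATION_MG_PER_KG,
) -> list[ADDResult]:
    """Empirical doses for every grower × season under one method.

    When no ``rate_set`` is given, one is built from the cohort's own mean
    contact fractions — the workflow the task-specific method is designed
    around. Methods 1 and 2 only use the baseline rates it carries.
    """
    records = list(records)
    if method not in (1, 2, 3):
        raise DomainError(f"method must be 1, 2 or 3, got {method}")
    if rate_set is None:
        means = cohort_contact_means(records)
        if method == 3 and any(v is None for v in means.values()):
            missing = [a.value for a, v in means.items() if v is None]
            raise DomainError(
                "cannot derive contact-fraction scaling: no engaged records for "
                + ", ".join(missing)
            )
        rate_set = build_rate_set(contact_means=means) if method == 3 else build_rate_set()
    results = []
    for record in records:
        bw = body_weight_for(record, bodyweight_table)
        for efs in derive_exposure_factors(record):
            if method == 1:
                results.append(
                    add_method1(
                        C, rate_set.daily_soil_dust, efs.days_per_month_onsite, bw,
                        grower_id=record.grower_id, season=efs.season,
                    )
                )
            elif method == 2:
                results.append(
                    add_method2(
                        C, rate_set.hourly_outdoor, rate_set.hourly_indoor,
                        efs.hours_per_month_onsite, bw,
                        grower_id=record.grower_id, season=efs.season,
                    )
                )
            else:
                results.append(
                    add_method3(
                        C, rate_set, efs.task_hours_per_month, bw,
                        grower_id=record.grower_id, season=efs.season,
                    )
                )
    return results


def results_to_frame(results: Iterable[ADDResult]) -> pd.DataFrame:
    """Tidy results table: one row per grower × season × dose component."""
    rows = []
    for r in results:
        base = {
            "grower_id": r.grower_id,
            "season": r.season.value if r.season is not None else "",
            "method": r.method,
            "flags": "|".join(sorted(r.flags)),
        }
        rows.append({**base, "component": "total", "add_mg_per_kgbw_day": r.add_total})
        rows.append({**base, "component": "outdoor", "add_mg_per_kgbw_day": r.add_outdoor})
        rows.append({**base, "component": "indoor", "add_mg_per_kgbw_day": r.add_indoor})
        if r.add_by_task is not None:
            for a, v in r.add_by_task.items():
                rows.append({**base, "component": a.value, "add_mg_per_kgbw_day": v})
    return pd.DataFrame(rows)
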