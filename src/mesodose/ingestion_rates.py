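"""Hourly and task-specific soil/dust ingestion rates.

Starting points are modelled daily rates for a high-contact soil scenario:
378 mg/day (soil + dust, used by the daily dose model), 362 mg/day (soil
while working outdoors) and 22 mg/day (dust while indoors). Hourly rates
divide these over an assumed 8-h outdoor workday and 16 indoor non-working
hours: 362/8 = 45.25 mg/h outdoors and 22/16 = 1.375 mg/h indoors (printed
elsewhere as 1.38; dose arithmetic here keeps full precision).

Task-specific rates scale the 45.25 mg/h baseline by how much of each
task's time involves direct hand-soil contact: high-contact tasks are
doubled (90.5 mg/h), mid-contact tasks keep the baseline, low-contact
tasks are halved (22.625 mg/h, printed 22.63). The contact bands are a
professional-judgment call; the default cut points (≥ 60% → 2.0,
40–60% → 1.0, < 40% → 0.5) reproduce the published assignment for all six
tasks and are configurable.

Note 362 + 22 = 384 ≠ 378: the daily-model default and the hourly-model
defaults come from different derivations and are deliberately carried as
separate, unreconciled constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional

from .domain_types import ConfigurationError, DomainError, MesoActivity
from .exposure_factors import INDOOR_NONWORK_HOURS, OUTDOOR_WORKDAY_HOURS

__all__ = [
    "DAILY_SOIL_DUST_MG",
    "DAILY_OUTDOOR_SOIL_MG",
    "DAILY_INDOOR_DUST_MG",
    "HIGH_CONTACT_THRESHOLD",
    "MID_CONTACT_THRESHOLD",
    "SCALE_HIGH",
    "SCALE_MID",
    "SCALE_LOW",
    "DEFAULT_CONTACT_MEANS",
    "IngestionRateSet",
    "hourly_outdoor_rate",
    "hourly_indoor_rate",
    "scaling_factor_from_contact",
    "task_specific_rate",
    "build_rate_set",
    "format_rate",
]

DAILY_SOIL_DUST_MG = 378.0
DAILY_OUTDOOR_SOIL_MG = 362.0
DAILY_INDOOR_DUST_MG = 22.0

HIGH_CONTACT_THRESHOLD = 0.60
MID_CONTACT_THRESHOLD = 0.40
SCALE_HIGH = 2.0
SCALE_MID = 1.0
SCALE_LOW = 0.5

#: Published cohort mean contact fractions per task (pooled over seasons).
DEFAULT_CONTACT_MEANS: dict[MesoActivity, float] = {
    MesoActivity.TRANSPLANTING: 0.87,
    MesoActivity.WEEDING: 0.72,
    MesoActivity.PLANTING_SEEDS: 0.49,
    MesoActivity.BED_PREPARATION: 0.41,
    MesoActivity.HARVESTING: 0.35,
    MesoActivity.IRRIGATION: 0.08,
}


def format_rate(value: float, decimals: int = 2) -> str:
    """Report-style rounding: half away from zero, as in the published tables.

    Dose arithmetic keeps full precision (22.625, 1.375); this is only for
    display, where 22.625 prints as 22.63 and 1.375 as 1.38.
    """
    q = Decimal(1).scaleb(-decimals)
    return str(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def hourly_outdoor_rate(
    daily_outdoor_soil: float = DAILY_OUTDOOR_SOIL_MG,
    workday_hours: float = OUTDOOR_WORKDAY_HOURS,
) -> float:
    """Baseline outdoor soil ingestion rate, mg/h (362/8 = 45.25)."""
    if daily_outdoor_soil <= 0:
        raise DomainError(f"daily_outdoor_soil must be > 0, got {daily_outdoor_soil}")
    if workday_hours <= 0:
        raise DomainError(f"workday_hours must be > 0, got {workday_hours}")
    return daily_outdoor_soil / workday_hours


def hourly_indoor_rate(
    daily_indoor_dust: float = DAILY_INDOOR_DUST_MG,
    nonwork_hours: float = INDOOR_NONWORK_HOURS,
) -> float:
    """Indoor dust ingestion rate, mg/h (22/16 = 1.375; 1.38 at 2 dp)."""
    if daily_indoor_dust <= 0:
        raise DomainError(f"daily_indoor_dust must be > 0, got {daily_indoor_dust}")
    if nonwork_hours <= 0:
        raise DomainError(f"nonwork_hours must be > 0, got {nonwork_hours}")
    return daily_indoor_dust / nonwork_hours


def scaling_factor_from_contact(
    mean_contact: float,
    high_threshold: float = HIGH_CONTACT_THRESHOLD,
    mid_threshold: float = MID_CONTACT_THRESHOLD,
) -> float:
    """Map a task's mean contact fraction to a rate multiplier.

    Piecewise and monotone non-decreasing: ≥ ``high_threshold`` → 2.0,
    [``mid_threshold``, ``high_threshold``) → 1.0, below → 0.5.
    """
    if not 0 <= mean_contact <= 1:
        raise DomainError(f"mean_contact must lie in [0, 1], got {mean_contact}")
    if not 0 < mid_threshold < high_threshold <= 1:
        raise ConfigurationError(
            f"thresholds must satisfy 0 < mid < high <= 1, got {mid_threshold}, {high_threshold}"
        )
    if mean_contact >= high_threshold:
        return SCALE_HIGH
    if mean_contact >= mid_threshold:
        return SCALE_MID
    return SCALE_LOW


def task_specific_rate(hourly_outdoor: float, scaling: float) -> float:
    """Task ingestion rate: baseline hourly outdoor rate × scaling factor."""
    if hourly_outdoor <= 0:
        raise DomainError(f"hourly_outdoor must be > 0, got {hourly_outdoor}")
    if scaling <= 0:
        raise DomainError(f"scaling must be > 0, got {scaling}")
    return hourly_outdoor * scaling


@dataclass(frozen=True)
class IngestionRateSet:
    """All ingestion-rate constants one dose run needs, with provenance.

    Invariants (enforced at construction): every rate positive,
    ``hourly_outdoor = daily_outdoor_soil / 8``,
    ``hourly_indoor = daily_indoor_dust / 16``, and
    ``task_rates[a] = hourly_outdoor × scaling_factors[a]`` for each task.
    """

    daily_soil_dust: float
    daily_outdoor_soil: float
    daily_indoor_dust: float
    hourly_outdoor: float
    hourly_indoor: float
    task_rates: Mapping[MesoActivity, float]
    scaling_factors: Mapping[MesoActivity, float]
    contact_means: Mapping[MesoActivity, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("daily_soil_dust", "daily_outdoor_soil", "daily_indoor_dust",
                     "hourly_outdoor", "hourly_indoor"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        for a in MesoActivity:
            if a not in self.task_rates or a not in self.scaling_factors:
                raise ConfigurationError(f"missing task rate for activity {a.value!r}")
            if self.task_rates[a] != self.hourly_outdoor * self.scaling_factors[a]:
                raise ConfigurationError(
                    f"task rate for {a.value!r} does not equal hourly_outdoor × scaling"
                )


def build_rate_set(
    daily_soil_dust: float = DAILY_SOIL_DUST_MG,
    daily_outdoor_soil: float = DAILY_OUTDOOR_SOIL_MG,
    daily_indoor_dust: float = DAILY_INDOOR_DUST_MG,
    contact_means: Optional[Mapping[MesoActivity, float]] = None,
    workday_hours: float = OUTDOOR_WORKDAY_HOURS,
    nonwork_hours: float = INDOOR_NONWORK_HOURS,
    high_threshold: float = HIGH_CONTACT_THRESHOLD,
    mid_threshold: float = MID_CONTACT_THRESHOLD,
    scaling_overrides: Optional[Mapping[MesoActivity, float]] = None,
) -> IngestionRateSet:
    """Assemble a full :class:`IngestionRateSet` from defaults and contact means.

    ``contact_means`` must cover all six activities (defaults to the
    published cohort means) unless explicit ``scaling_overrides`` are
    supplied for the missing ones. With the default inputs the task rates
    come out as 90.5 mg/h (transplanting, weeding), 45.25 mg/h (planting
    seeds, bed preparation) and 22.625 mg/h (harvesting, irrigation).
    """
    if contact_means is None:
        contact_means = DEFAULT_CONTACT_MEANS
    overrides = dict(scaling_overrides or {})
    h_out = hourly_outdoor_rate(daily_outdoor_soil, workday_hours)
    h_in = hourly_indoor_rate(daily_indoor_dust, nonwork_hours)
    scaling: dict[MesoActivity, float] = {}
    for a in MesoActivity:
        if a in overrides:
            scaling[a] = overrides[a]
        elif a in contact_means and contact_means[a] is not None:
            scaling[a] = scaling_factor_from_contact(
                contact_means[a], high_threshold, mid_threshold
            )
        else:
            raise ConfigurationError(
                f"no contact mean or scaling override for activity {a.value!r}"
            )
    task_rates = {a: task_specific_rate(h_out, s) for a, s in scaling.items()}
    return IngestionRateSet(
        daily_soil_dust=daily_soil_dust,
        daily_outdoor_soil=daily_outdoor_soil,
        daily_indoor_dust=daily_indoor_dust,
        hourly_outdoor=h_out,
        hourly_indoor=h_in,
        task_rates=task_rates,
        scaling_factors=scaling,
        contact_means=dict(contact_means),
    )
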