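"""Synthetic questionnaire cohorts with the study's statistical structure.

Real questionnaire data are external; this generator emits grower records
whose summary behaviour matches the published study conditions so every
pipeline stage is testable offline:

* seasonal on-site intensity — mean hours/month highest in summer
  (≈ 204.6) and lowest in winter (≈ 76.8), with spring and fall between;
* six meso-activities with season-specific engagement probabilities;
* per-activity soil-contact fractions drawn from beta distributions whose
  default means are the published per-task means (transplanting 0.87,
  weeding 0.72, planting seeds 0.49, bed preparation 0.41, harvesting
  0.35, irrigation 0.08);
* a reliability structure in which most grower-seasons leave a fraction of
  on-site time unattributed to the six tasks, while a configurable
  fraction (default 0.29, the published share of non-positive
  differences) reports more task time than on-site time (concurrency);
* demographics matching the enrolled cohort (52/48 male/female, ages
  26–69) and a body-weight table for either lookup or weighted sampling.

Distribution families (truncated lognormal for durations, beta for
fractions, Bernoulli for engagement and flags) are documented modelling
choices: the study reports only summaries, so the generator targets those
summaries, not distributional fidelity.

With ``unaccounted_time_fraction = 0`` and ``concurrency_fraction = 0``,
total task hours equal on-site hours by construction, so the reliability
difference is identically zero — a useful test identity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .domain_types import (
    AmountCategory,
    BodyWeightBracket,
    BodyWeightTable,
    ConfigurationError,
    FarmSizeUnit,
    GrowerRecord,
    IngestionReport,
    MesoActivity,
    OnSiteActivity,
    Position,
    Season,
    SeasonRecord,
    Sex,
    TaskActivity,
    WeightedBodyWeight,
)

__all__ = ["CohortSpec", "generate_cohort", "generate_bodyweight_table"]

_MAX_HOURS_PER_DAY = 23.5  # keeps any single task decomposable into <= 30 days x 24 h


@dataclass(frozen=True)
class SeasonOnSite:
    """On-site pattern for one season: days/week ~ Binomial(7, p) (min 1),
    hours/day ~ lognormal with the given mean, clipped to [0.25, 23.5]."""

    days_per_week_p: float
    hours_per_day_mean: float
    hours_per_day_sigma: float = 0.35


def _default_onsite() -> dict[Season, SeasonOnSite]:
    # Means chosen so hours/month ~= 204.6 (summer) and 76.8 (winter) as
    # published, with spring/fall interpolated to preserve the seasonal rank.
    return {
        Season.SPRING: SeasonOnSite(0.83, 6.3),
        Season.SUMMER: SeasonOnSite(0.915, 7.35),
        Season.FALL: SeasonOnSite(0.74, 4.9),
        Season.WINTER: SeasonOnSite(0.61, 4.1),
    }


def _default_engagement() -> dict[MesoActivity, dict[Season, float]]:
    s = Season
    return {
        MesoActivity.BED_PREPARATION: {s.SPRING: 0.85, s.SUMMER: 0.70, s.FALL: 0.60, s.WINTER: 0.40},
        MesoActivity.PLANTING_SEEDS: {s.SPRING: 0.80, s.SUMMER: 0.70, s.FALL: 0.50, s.WINTER: 0.30},
        MesoActivity.TRANSPLANTING: {s.SPRING: 0.80, s.SUMMER: 0.75, s.FALL: 0.50, s.WINTER: 0.25},
        MesoActivity.IRRIGATION: {s.SPRING: 0.70, s.SUMMER: 0.95, s.FALL: 0.60, s.WINTER: 0.30},
        MesoActivity.WEEDING: {s.SPRING: 0.85, s.SUMMER: 0.90, s.FALL: 0.70, s.WINTER: 0.35},
        MesoActivity.HARVESTING: {s.SPRING: 0.60, s.SUMMER: 0.95, s.FALL: 0.80, s.WINTER: 0.45},
    }


def _default_allocation() -> dict[MesoActivity, float]:
    # Relative share of task time; irrigation and bed preparation dominate
    # hours, transplanting the least — mirroring the reported time budget.
    return {
        MesoActivity.BED_PREPARATION: 0.22,
        MesoActivity.PLANTING_SEEDS: 0.10,
        MesoActivity.TRANSPLANTING: 0.08,
        MesoActivity.IRRIGATION: 0.25,
        MesoActivity.WEEDING: 0.15,
        MesoActivity.HARVESTING: 0.20,
    }


def _default_contact_means() -> dict[MesoActivity, float]:
    return {
        MesoActivity.TRANSPLANTING: 0.87,
        MesoActivity.WEEDING: 0.72,
        MesoActivity.PLANTING_SEEDS: 0.49,
        MesoActivity.BED_PREPARATION: 0.41,
        MesoActivity.HARVESTING: 0.35,
        MesoActivity.IRRIGATION: 0.08,
    }


def _default_days_p() -> dict[MesoActivity, float]:
    # p of Binomial(29, p) for days/month when engaged; irrigation happens
    # on many more days than the other tasks.
    return {
        MesoActivity.BED_PREPARATION: 0.15,
        MesoActivity.PLANTING_SEEDS: 0.15,
        MesoActivity.TRANSPLANTING: 0.15,
        MesoActivity.IRRIGATION: 0.45,
        MesoActivity.WEEDING: 0.25,
        MesoActivity.HARVESTING: 0.30,
    }


_TYPICAL_POSITION = {
    MesoActivity.BED_PREPARATION: Position.STANDING,
    MesoActivity.PLANTING_SEEDS: Position.STANDING,
    MesoActivity.TRANSPLANTING: Position.KNEELING,
    MesoActivity.IRRIGATION: Position.STANDING,
    MesoActivity.WEEDING: Position.KNEELING,
    MesoActivity.HARVESTING: Position.BENDING,
}

_AMOUNT_WEIGHTS = {
    AmountCategory.LT10: 0.45,
    AmountCategory.MG10: 0.18,
    AmountCategory.MG20: 0.18,
    AmountCategory.MG50: 0.08,
    AmountCategory.MG100: 0.05,
    AmountCategory.MG200: 0.03,
    AmountCategory.MG1000: 0.02,
    AmountCategory.GT1000: 0.01,
}


@dataclass(frozen=True)
class CohortSpec:
    """Tunable parameters of the synthetic cohort generator."""

    n_growers: int = 38
    seed: int = 0
    onsite: Mapping[Season, SeasonOnSite] = field(default_factory=_default_onsite)
    engagement: Mapping[MesoActivity, Mapping[Season, float]] = field(
        default_factory=_default_engagement
    )
    allocation_weights: Mapping[MesoActivity, float] = field(default_factory=_default_allocation)
    contact_means: Mapping[MesoActivity, float] = field(default_factory=_default_contact_means)
    contact_concentration: float = 12.0
    days_per_month_p: Mapping[MesoActivity, float] = field(default_factory=_default_days_p)
    #: Mean fraction of on-site hours not attributable to the six tasks.
    unaccounted_time_fraction: float = 0.35
    #: Fraction of grower-seasons whose task hours exceed on-site hours.
    concurrency_fraction: float = 0.29
    male_fraction: float = 0.52
    age_low: int = 26
    age_high: int = 69
    smoking_prob: float = 0.05
    employment_probs: tuple[float, float, float] = (0.71, 0.08, 0.21)
    glove_prob: float = 0.60
    handwash_prob: float = 0.55

    def validate(self) -> None:
        if self.n_growers < 0:
            raise ConfigurationError("n_growers must be >= 0")
        probs = (
            [self.unaccounted_time_fraction, self.concurrency_fraction,
             self.male_fraction, self.smoking_prob, self.glove_prob, self.handwash_prob]
            + [p for by_season in self.engagement.values() for p in by_season.values()]
        )
        for p in probs:
            if not 0 <= p <= 1:
                raise ConfigurationError(f"probability {p} outside [0, 1]")
        if not math.isclose(sum(self.employment_probs), 1.0, abs_tol=1e-9):
            raise ConfigurationError("employment_probs must sum to 1")
        if self.contact_concentration <= 0:
            raise ConfigurationError("contact_concentration must be > 0")
        if self.age_low < 18 or self.age_high < self.age_low:
            raise ConfigurationError("age range must be adult and non-empty")
        for a in MesoActivity:
            if a not in self.allocation_weights:
                raise ConfigurationError(f"missing allocation weight for {a.value!r}")
            w = self.allocation_weights[a]
            engaged_somewhere = any(self.engagement[a][s] > 0 for s in Season)
            if engaged_somewhere and w <= 0:
                raise ConfigurationError(
                    f"activity {a.value!r} can be engaged but has allocation weight {w}"
                )
            mu = self.contact_means[a]
            if not 0 < mu < 1:
                raise ConfigurationError(f"contact mean for {a.value!r} must lie in (0, 1)")


def _beta_params(mean: float, kappa: float) -> tuple[float, float]:
    return mean * kappa, (1.0 - mean) * kappa


def generate_cohort(spec: CohortSpec) -> list[GrowerRecord]:
    """Generate ``spec.n_growers`` fully valid grower records (deterministic per seed).

    Every record reports all four seasons and passes
    :func:`mesodose.domain_types.validate_record`.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    records = []
    for i in range(spec.n_growers):
        gid = f"G{i:04d}"
        sex = Sex.MALE if rng.random() < spec.male_fraction else Sex.FEMALE
        age = int(rng.integers(spec.age_low, spec.age_high + 1))
        smoking = bool(rng.random() < spec.smoking_prob)
        employment = int(rng.choice([1, 2, 3], p=spec.employment_probs))
        farm_size = float(np.clip(rng.lognormal(math.log(4.0), 1.2), 0.05, 835.0))
        seasons = {
            season: _generate_season(spec, rng, gid, season) for season in Season
        }
        records.append(
            GrowerRecord(
                grower_id=gid, sex=sex, age=age, smoking=smoking,
                employment_status=employment, farm_size=farm_size,
                farm_size_unit=FarmSizeUnit.HECTARES,
                body_weight=None, seasons=seasons,
            )
        )
    return records


def _generate_season(
    spec: CohortSpec, rng: np.random.Generator, gid: str, season: Season
) -> SeasonRecord:
    pattern = spec.onsite[season]
    days_per_week = int(max(1, rng.binomial(7, pattern.days_per_week_p)))
    sigma = pattern.hours_per_day_sigma
    hours_per_day = float(
        np.clip(
            pattern.hours_per_day_mean * rng.lognormal(-0.5 * sigma**2, sigma),
            0.25,
            _MAX_HOURS_PER_DAY,
        )
    )
    onsite_hours = hours_per_day * days_per_week * 4.35
    onsite = OnSiteActivity(
        grower_id=gid, season=season,
        days_per_week=days_per_week, hours_per_day=hours_per_day,
    )

    engaged = [a for a in MesoActivity if rng.random() < spec.engagement[a][season]]
    tasks: dict[MesoActivity, TaskActivity] = {}
    task_hours: dict[MesoActivity, float] = {a: 0.0 for a in MesoActivity}
    if engaged:
        # Coverage: share of on-site hours spent on the six tasks. Exactly 1
        # when both reliability knobs are zero (the exact-agreement identity).
        if spec.unaccounted_time_fraction == 0 and spec.concurrency_fraction == 0:
            coverage = 1.0
        elif rng.random() < spec.concurrency_fraction:
            coverage = float(rng.uniform(1.02, 1.45))
        else:
            u = spec.unaccounted_time_fraction * float(rng.uniform(0.4, 1.6))
            coverage = float(np.clip(1.0 - u, 0.05, 1.0))
        total_task = onsite_hours * coverage
        alpha = np.array([spec.allocation_weights[a] for a in engaged]) * 8.0
        shares = rng.dirichlet(alpha)
        for a, share in zip(engaged, shares):
            task_hours[a] = min(float(total_task * share), 24.0 * 30.0)

    for a in MesoActivity:
        h = task_hours[a]
        if a in engaged and h > 0:
            d0 = 1 + int(rng.binomial(29, spec.days_per_month_p[a]))
            days = max(d0, math.ceil(h / 24.0))
            hpd = h / days
            mu, kappa = spec.contact_means[a], spec.contact_concentration
            a_par, b_par = _beta_params(mu, kappa)
            contact = float(rng.beta(a_par, b_par))
            glove = bool(rng.random() < spec.glove_prob)
            glove_t = float(rng.beta(*_beta_params(0.7, 8.0))) if glove else None
            positions = {_TYPICAL_POSITION[a]}
            if rng.random() < 0.3:
                positions.add(Position.STANDING)
            tasks[a] = TaskActivity(
                grower_id=gid, season=season, activity=a,
                days_per_month=days, hours_per_day=hpd, contact_fraction=contact,
                glove_use=glove, glove_time_fraction=glove_t,
                handwash_after=bool(rng.random() < spec.handwash_prob),
                positions=frozenset(positions),
            )
        else:
            tasks[a] = TaskActivity(
                grower_id=gid, season=season, activity=a,
                days_per_month=0.0, hours_per_day=0.0, contact_fraction=0.0,
            )

    soil_in_mouth = bool(
        rng.random() < {Season.SPRING: 0.25, Season.SUMMER: 0.30,
                        Season.FALL: 0.15, Season.WINTER: 0.10}[season]
    )
    ingestion = IngestionReport(
        grower_id=gid, season=season, soil_in_mouth=soil_in_mouth,
        days_with_ingestion=(1 + int(rng.binomial(29, 0.25))) if soil_in_mouth else None,
        amount_category=(
            AmountCategory(rng.choice([c.value for c in _AMOUNT_WEIGHTS],
                                      p=list(_AMOUNT_WEIGHTS.values())))
            if soil_in_mouth else None
        ),
        face_contact=bool(rng.random() < 0.3),
        produce_sampling=bool(rng.random() < 0.6),
        meals_onsite=bool(rng.random() < 0.6),
    )
    return SeasonRecord(onsite=onsite, tasks=tasks, ingestion=ingestion)


def generate_bodyweight_table(
    mode: str, seed: int = 0, n_samples: int = 200
) -> BodyWeightTable:
    """A synthetic adult body-weight table (deterministic per seed).

    ``median_lookup`` mode: sex × age-bracket medians tiling ages
    [18, 100) — synthetic plausible values standing in for handbook
    medians, which users should replace for faithful reproduction of any
    real cohort. ``weighted_sample`` mode: ``n_samples`` (weight, weight
    of representation) pairs from a right-skewed lognormal truncated to
    [40, 180] kg, emulating a population-weighted survey sample.
    """
    if mode == "median_lookup":
        edges = [(18, 30), (30, 40), (40, 50), (50, 60), (60, 70), (70, 100)]
        male = [83.9, 88.8, 89.2, 88.2, 86.1, 80.5]
        female = [74.5, 78.2, 79.1, 77.9, 75.8, 70.1]
        brackets = tuple(
            BodyWeightBracket(sex=sex, age_low=lo, age_high=hi, median_kg=m)
            for sex, medians in ((Sex.MALE, male), (Sex.FEMALE, female))
            for (lo, hi), m in zip(edges, medians)
        )
        return BodyWeightTable(mode="median_lookup", brackets=brackets)
    if mode == "weighted_sample":
        if n_samples < 100:
            raise ConfigurationError("weighted_sample tables need >= 100 rows")
        rng = np.random.default_rng(seed)
        weights_kg = np.clip(rng.lognormal(math.log(80.0), 0.22, size=n_samples), 40.0, 180.0)
        pop_weights = rng.gamma(2.0, 1.0, size=n_samples) + 0.05
        samples = tuple(
            WeightedBodyWeight(weight_kg=float(w), population_weight=float(pw))
            for w, pw in zip(weights_kg, pop_weights)
        )
        return BodyWeightTable(mode="weighted_sample", samples=samples)
    raise ConfigurationError(f"unknown body-weight table mode {mode!r}")
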