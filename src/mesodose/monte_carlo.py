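"""Monte Carlo dose simulation for hypothetical grower populations.

Each simulated grower (default population 5000) gets a body weight drawn
from a weighted empirical table (probability proportional to the
population weight of each datum) and exposure factors drawn with
replacement from per-season pools of questionnaire-reported values — an
empirical bootstrap, with no distribution fitted. Method 3 additionally
perturbs each task's ingestion rate with a multiplicative
Uniform(scale − 0.2, scale + 0.2) factor around its scaling factor, e.g.
1.8–2.2× baseline for a doubled task.

Per-task pools are sampled independently across tasks, which discards any
within-grower correlation between tasks; ``row_bootstrap=True`` instead
samples one whole grower-season row of task hours per draw, preserving it.

All randomness flows from a single ``numpy`` generator seeded with the
config seed; variables are drawn vectorised in a fixed order (body weight,
then exposure factors in activity order, then rate perturbations), so a
given config + seed reproduces draws bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .domain_types import (
    BodyWeightTable,
    ConfigurationError,
    GrowerRecord,
    MesoActivity,
    Season,
)
from .exposure_factors import (
    DAYS_PER_MONTH_AVERAGING_METHOD1,
    HOURS_PER_MONTH,
    derive_exposure_factors,
)
from .add_models import DEFAULT_CONCENTRATION_MG_PER_KG, HOURS_PER_DAY, MG_PER_KG
from .ingestion_rates import IngestionRateSet

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "sample_body_weight",
    "sample_exposure_factor",
    "sample_task_rate",
    "run_simulation",
    "pools_from_cohort",
]

DEFAULT_N_GROWERS = 5000
DEFAULT_RATE_HALFWIDTH = 0.2


@dataclass(frozen=True)
class SimulationConfig:
    """Inputs of one simulation run.

    ``factor_pools`` holds the empirical value pools for the configured
    method and season: a sequence of days/month (method 1) or on-site
    hours/month (method 2), or a per-activity mapping of hours/month pools
    (method 3). Zero pool values represent non-engagement and are included
    by default so the simulated population reflects engagement prevalence.
    """

    method: int
    season: Season
    bodyweight_table: BodyWeightTable
    factor_pools: object  # Sequence[float] | Mapping[MesoActivity, Sequence[float]]
    n_growers: int = DEFAULT_N_GROWERS
    seed: int = 0
    rate_perturbation_halfwidth: float = DEFAULT_RATE_HALFWIDTH
    include_zero_pool_values: bool = True
    row_bootstrap: bool = False

    def __post_init__(self) -> None:
        if self.method not in (1, 2, 3):
            raise ConfigurationError(f"method must be 1, 2 or 3, got {self.method}")
        if self.n_growers <= 0:
            raise ConfigurationError(f"n_growers must be > 0, got {self.n_growers}")
        if self.rate_perturbation_halfwidth < 0:
            raise ConfigurationError("rate_perturbation_halfwidth must be >= 0")


@dataclass(frozen=True)
class SimulationResult:
    """Per-draw doses plus their summary for one season × method."""

    config_method: int
    season: Season
    draws: pd.DataFrame  # columns: draw, body_weight_kg, add_total, add_outdoor, add_indoor[, add_<task>...]
    summary: dict

    @property
    def add_total(self) -> np.ndarray:
        return self.draws["add_total"].to_numpy()


def _pool_array(pool: Sequence[float], label: str, include_zeros: bool) -> np.ndarray:
    arr = np.asarray(list(pool), dtype=float)
    if not include_zeros:
        arr = arr[arr != 0]
    if arr.size == 0:
        raise ConfigurationError(f"empty exposure-factor pool for {label}")
    return arr


def sample_body_weight(
    table: BodyWeightTable, rng: np.random.Generator, size: Optional[int] = None
):
    """Draw body weight(s), probability ∝ population weight of each row."""
    if table.mode != "weighted_sample":
        raise ConfigurationError("sample_body_weight requires a weighted_sample table")
    if not table.samples:
        raise ConfigurationError("body-weight table has no entries")
    values = np.array([s.weight_kg for s in table.samples], dtype=float)
    weights = np.array([s.population_weight for s in table.samples], dtype=float)
    p = weights / weights.sum()
    return rng.choice(values, size=size, p=p)


def sample_exposure_factor(
    pool: Sequence[float], rng: np.random.Generator, size: Optional[int] = None,
    label: str = "pool",
):
    """Uniform draw(s) with replacement from an empirical pool."""
    arr = _pool_array(pool, label, include_zeros=True)
    return rng.choice(arr, size=size)


def sample_task_rate(
    base_hourly: float,
    scaling: float,
    halfwidth: float = DEFAULT_RATE_HALFWIDTH,
    rng: Optional[np.random.Generator] = None,
    size: Optional[int] = None,
):
    """Perturbed task rate: base × Uniform(scaling − halfwidth, scaling + halfwidth)."""
    if scaling - halfwidth <= 0:
        raise ConfigurationError(
            f"halfwidth {halfwidth} must be < scaling {scaling} so multipliers stay positive"
        )
    if rng is None:
        rng = np.random.default_rng()
    return base_hourly * rng.uniform(scaling - halfwidth, scaling + halfwidth, size=size)


def run_simulation(
    config: SimulationConfig,
    rates: IngestionRateSet,
    C: float = DEFAULT_CONCENTRATION_MG_PER_KG,
) -> SimulationResult:
    """Simulate ``n_growers`` doses for one season under one method.

    Identical config + seed yields identical draws. The summary reports
    mean, median and the 5th/95th percentiles of the total dose (and per
    task for method 3), recomputable from the stored draws.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_growers
    bw = np.asarray(sample_body_weight(config.bodyweight_table, rng, size=n), dtype=float)

    if config.method == 1:
        days = np.asarray(
            _draw_pool(config, config.factor_pools, rng, n, "days/month"), dtype=float
        )
        add_out = (C * rates.daily_soil_dust * MG_PER_KG * days) / (
            bw * DAYS_PER_MONTH_AVERAGING_METHOD1
        )
        add_in = np.zeros(n)
        frame = _base_frame(bw, add_out + add_in, add_out, add_in)
    elif config.method == 2:
        hours = np.asarray(
            _draw_pool(config, config.factor_pools, rng, n, "hours/month"), dtype=float
        )
        if np.any(hours > HOURS_PER_MONTH) or np.any(hours < 0):
            raise ConfigurationError(
                f"method 2 pool values must lie in [0, {HOURS_PER_MONTH}] h/month"
            )
        scale = HOURS_PER_DAY * C * MG_PER_KG / (bw * HOURS_PER_MONTH)
        add_out = scale * rates.hourly_outdoor * hours
        add_in = scale * rates.hourly_indoor * (HOURS_PER_MONTH - hours)
        frame = _base_frame(bw, add_out + add_in, add_out, add_in)
    else:
        task_hours = _draw_task_hours(config, rng, n)
        scale = HOURS_PER_DAY * C * MG_PER_KG / (bw * HOURS_PER_MONTH)
        by_task = {}
        for a in MesoActivity:
            rate = sample_task_rate(
                rates.hourly_outdoor,
                rates.scaling_factors[a],
                config.rate_perturbation_halfwidth,
                rng,
                size=n,
            )
            by_task[a] = scale * rate * task_hours[a]
        total_hours = np.sum([task_hours[a] for a in MesoActivity], axis=0)
        indoor_hours = np.maximum(0.0, HOURS_PER_MONTH - total_hours)
        add_out = np.sum([by_task[a] for a in MesoActivity], axis=0)
        add_in = scale * rates.hourly_indoor * indoor_hours
        frame = _base_frame(bw, add_out + add_in, add_out, add_in)
        for a in MesoActivity:
            frame[f"add_{a.value}"] = by_task[a]

    summary = _summarize_draws(frame, config)
    return SimulationResult(
        config_method=config.method, season=config.season, draws=frame, summary=summary
    )


def _draw_pool(config, pool, rng, n, label):
    arr = _pool_array(pool, f"{label} ({config.season.value})", config.include_zero_pool_values)
    return rng.choice(arr, size=n)


def _draw_task_hours(
    config: SimulationConfig, rng: np.random.Generator, n: int
) -> dict[MesoActivity, np.ndarray]:
    pools = config.factor_pools
    if not isinstance(pools, Mapping):
        raise ConfigurationError("method 3 requires per-activity factor pools")
    for a in MesoActivity:
        if a not in pools:
            raise ConfigurationError(
                f"missing task-hours pool for {a.value!r} ({config.season.value})"
            )
    if config.row_bootstrap:
        arrays = {}
        lengths = {len(pools[a]) for a in MesoActivity}
        if len(lengths) != 1:
            raise ConfigurationError("row_bootstrap requires equal-length task pools")
        m = lengths.pop()
        if m == 0:
            raise ConfigurationError(f"empty task pools ({config.season.value})")
        idx = rng.integers(0, m, size=n)
        for a in MesoActivity:
            arrays[a] = np.asarray(list(pools[a]), dtype=float)[idx]
        return arrays
    return {
        a: np.asarray(
            _draw_pool(config, pools[a], rng, n, f"{a.value} hours/month"), dtype=float
        )
        for a in MesoActivity
    }


def _base_frame(bw, total, outdoor, indoor) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "draw": np.arange(len(bw)),
            "body_weight_kg": bw,
            "add_total": total,
            "add_outdoor": outdoor,
            "add_indoor": indoor,
        }
    )


def _summarize_draws(frame: pd.DataFrame, config: SimulationConfig) -> dict:
    def stats(x: np.ndarray) -> dict:
        return {
            "mean": float(np.mean(x)),
            "median": float(np.median(x)),
            "p5": float(np.percentile(x, 5)),
            "p95": float(np.percentile(x, 95)),
        }

    out = {
        "method": config.method,
        "season": config.season.value,
        "n_growers": config.n_growers,
        "seed": config.seed,
        "add_total": stats(frame["add_total"].to_numpy()),
    }
    task_cols = [c for c in frame.columns if c.startswith("add_") and
                 c not in ("add_total", "add_outdoor", "add_indoor")]
    if task_cols:
        out["by_task"] = {c.removeprefix("add_"): stats(frame[c].to_numpy()) for c in task_cols}
    return out


def pools_from_cohort(
    records: Iterable[GrowerRecord], method: int, season: Season
) -> object:
    """Build the empirical factor pools a cohort implies for one method/season.

    Method 1: days/month on site; method 2: hours/month on site; method 3:
    per-activity hours/month (aligned across activities per grower, so the
    result also supports row-bootstrap sampling). Growers without that
    season contribute nothing.
    """
    if method not in (1, 2, 3):
        raise ConfigurationError(f"method must be 1, 2 or 3, got {method}")
    factor_rows = [
        efs
        for record in records
        for efs in derive_exposure_factors(record)
        if efs.season is season
    ]
    if method == 1:
        return [efs.days_per_month_onsite for efs in factor_rows]
    if method == 2:
        return [efs.hours_per_month_onsite for efs in factor_rows]
    return {
        a: [efs.task_hours_per_month[a] for efs in factor_rows] for a in MesoActivity
    }
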