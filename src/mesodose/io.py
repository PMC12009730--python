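"""CSV readers/writers for the questionnaire schema, plus configuration.

The cohort lives in three related RFC-4180 CSV tables (UTF-8, header row
required, case-insensitive headers):

* ``growers.csv`` — one row per grower: demographics, farm size (unit
  tagged), optional body weight;
* ``onsite.csv`` — one row per grower × season: overall on-site days/week
  and hours/day;
* ``tasks.csv`` — one row per grower × season × meso-activity: frequency,
  duration, soil-contact percent, behaviour flags, plus the per-season
  ingestion-report columns (repeated on each of the season's task rows).

Percentages appear at the file boundary; proportions are used internally.
The percent columns are converted through decimal strings so a write →
read round trip reproduces every float bit-for-bit. Missing task rows are
read as non-engagement (0 days/month); the reader never invents
engagement.
"""

from __future__ import annotations

import logging
from decimal import Decimal
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd
import yaml

from .domain_types import (
    AmountCategory,
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
    validate_record,
)

__all__ = [
    "SchemaError",
    "GROWERS_COLUMNS",
    "ONSITE_COLUMNS",
    "TASKS_COLUMNS",
    "write_cohort",
    "read_cohort",
    "tasks_wide_to_long",
    "default_config",
    "load_config",
]

log = logging.getLogger("mesodose")


class SchemaError(ValueError):
    """A CSV file does not match the questionnaire schema."""


GROWERS_COLUMNS = [
    "grower_id", "sex", "age", "smoking", "employment_status",
    "farm_size", "farm_size_unit", "body_weight_kg",
]
ONSITE_COLUMNS = ["grower_id", "season", "days_per_week", "hours_per_day"]
TASKS_COLUMNS = [
    "grower_id", "season", "activity", "days_per_month", "hours_per_day",
    "contact_percent", "glove_use", "glove_time_percent", "handwash_after",
    "positions", "soil_in_mouth", "ingestion_days", "amount_category",
]
# Optional extra ingestion-report columns; absent columns read as unknown.
TASKS_EXTRA_COLUMNS = [
    "face_contact", "face_contact_days", "produce_sampling",
    "produce_events_per_month", "produce_wash_fraction", "meals_onsite",
]


def _fraction_to_percent_str(x: Optional[float]) -> str:
    if x is None:
        return ""
    # Through the shortest repr so that percent/100 restores x exactly.
    return str(Decimal(repr(float(x))) * 100)


def _percent_to_fraction(s) -> Optional[float]:
    if s is None or (isinstance(s, float) and pd.isna(s)) or s == "":
        return None
    value = float(Decimal(str(s)) / 100)
    if not 0 <= value <= 1:
        raise SchemaError(f"percent value {s} outside [0, 100]")
    return value


def _bool_str(x: Optional[bool]) -> str:
    if x is None:
        return ""
    return "true" if x else "false"


def _parse_bool(s) -> Optional[bool]:
    if s is None or (isinstance(s, float) and pd.isna(s)) or s == "":
        return None
    s = str(s).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise SchemaError(f"cannot parse boolean value {s!r}")


def _opt_float(s) -> Optional[float]:
    if s is None or (isinstance(s, float) and pd.isna(s)) or s == "":
        return None
    return float(s)


def _opt_int(s) -> Optional[int]:
    f = _opt_float(s)
    return None if f is None else int(f)


def write_cohort(records: Iterable[GrowerRecord], directory) -> dict[str, Path]:
    """Write a cohort to ``growers.csv``, ``onsite.csv`` and ``tasks.csv``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    grower_rows, onsite_rows, task_rows = [], [], []
    for r in records:
        grower_rows.append({
            "grower_id": r.grower_id,
            "sex": r.sex.value,
            "age": r.age,
            "smoking": _bool_str(r.smoking),
            "employment_status": r.employment_status,
            "farm_size": r.farm_size,
            "farm_size_unit": r.farm_size_unit.value,
            "body_weight_kg": "" if r.body_weight is None else r.body_weight,
        })
        for season, srec in r.seasons.items():
            onsite_rows.append({
                "grower_id": r.grower_id,
                "season": season.value,
                "days_per_week": srec.onsite.days_per_week,
                "hours_per_day": srec.onsite.hours_per_day,
            })
            ing = srec.ingestion
            for activity in MesoActivity:
                task = srec.tasks.get(activity)
                if task is None:
                    continue
                task_rows.append({
                    "grower_id": r.grower_id,
                    "season": season.value,
                    "activity": activity.value,
                    "days_per_month": task.days_per_month,
                    "hours_per_day": task.hours_per_day,
                    "contact_percent": _fraction_to_percent_str(task.contact_fraction),
                    "glove_use": _bool_str(task.glove_use),
                    "glove_time_percent": _fraction_to_percent_str(task.glove_time_fraction),
                    "handwash_after": _bool_str(task.handwash_after),
                    "positions": "|".join(sorted(p.value for p in task.positions)),
                    "soil_in_mouth": "" if ing is None else _bool_str(ing.soil_in_mouth),
                    "ingestion_days": ""
                        if ing is None or ing.days_with_ingestion is None
                        else ing.days_with_ingestion,
                    "amount_category": ""
                        if ing is None or ing.amount_category is None
                        else ing.amount_category.value,
                    "face_contact": "" if ing is None else _bool_str(ing.face_contact),
                    "face_contact_days": ""
                        if ing is None or ing.face_contact_days is None
                        else ing.face_contact_days,
                    "produce_sampling": "" if ing is None else _bool_str(ing.produce_sampling),
                    "produce_events_per_month": ""
                        if ing is None or ing.produce_events_per_month is None
                        else ing.produce_events_per_month,
                    "produce_wash_fraction": ""
                        if ing is None or ing.produce_wash_fraction is None
                        else ing.produce_wash_fraction,
                    "meals_onsite": "" if ing is None else _bool_str(ing.meals_onsite),
                })
    paths = {
        "growers": directory / "growers.csv",
        "onsite": directory / "onsite.csv",
        "tasks": directory / "tasks.csv",
    }
    pd.DataFrame(grower_rows, columns=GROWERS_COLUMNS).to_csv(paths["growers"], index=False)
    pd.DataFrame(onsite_rows, columns=ONSITE_COLUMNS).to_csv(paths["onsite"], index=False)
    pd.DataFrame(task_rows, columns=TASKS_COLUMNS + TASKS_EXTRA_COLUMNS).to_csv(
        paths["tasks"], index=False
    )
    return paths


def _read_table(path, required: list[str], label: str) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{label}: missing column(s) {', '.join(missing)}")
    log.info("%s: read %d rows from %s", label, len(df), path)
    return df


def _enum_value(enum_cls, raw, label: str):
    try:
        return enum_cls(str(raw).strip().lower())
    except ValueError:
        raise SchemaError(
            f"{label}: unknown value {raw!r} (expected one of "
            f"{[e.value for e in enum_cls]})"
        ) from None


def read_cohort(directory) -> list[GrowerRecord]:
    """Read a cohort directory written by :func:`write_cohort`.

    Records failing validation are dropped with a logged reason; foreign
    keys must be consistent across the three tables.
    """
    directory = Path(directory)
    growers = _read_table(directory / "growers.csv", GROWERS_COLUMNS[:7], "growers.csv")
    onsite = _read_table(directory / "onsite.csv", ONSITE_COLUMNS, "onsite.csv")
    tasks = _read_table(directory / "tasks.csv", TASKS_COLUMNS, "tasks.csv")

    known_ids = set(growers["grower_id"])
    for label, df in (("onsite.csv", onsite), ("tasks.csv", tasks)):
        orphans = sorted(set(df["grower_id"]) - known_ids)
        if orphans:
            raise SchemaError(f"{label}: grower_id(s) not in growers.csv: {', '.join(orphans)}")

    onsite_by_grower: dict[str, dict[Season, OnSiteActivity]] = {}
    for _, row in onsite.iterrows():
        season = _enum_value(Season, row["season"], "onsite.csv")
        onsite_by_grower.setdefault(row["grower_id"], {})[season] = OnSiteActivity(
            grower_id=row["grower_id"], season=season,
            days_per_week=float(row["days_per_week"]),
            hours_per_day=float(row["hours_per_day"]),
        )

    tasks_by_key: dict[tuple[str, Season], dict[MesoActivity, TaskActivity]] = {}
    ingestion_by_key: dict[tuple[str, Season], IngestionReport] = {}
    for _, row in tasks.iterrows():
        season = _enum_value(Season, row["season"], "tasks.csv")
        activity = _enum_value(MesoActivity, row["activity"], "tasks.csv")
        key = (row["grower_id"], season)
        positions_raw = str(row["positions"]).strip()
        positions = frozenset(
            _enum_value(Position, p, "tasks.csv")
            for p in positions_raw.split("|") if p
        )
        contact = _percent_to_fraction(row["contact_percent"])
        tasks_by_key.setdefault(key, {})[activity] = TaskActivity(
            grower_id=row["grower_id"], season=season, activity=activity,
            days_per_month=float(row["days_per_month"]),
            hours_per_day=float(row["hours_per_day"]),
            contact_fraction=0.0 if contact is None else contact,
            glove_use=_parse_bool(row["glove_use"]),
            glove_time_fraction=_percent_to_fraction(row["glove_time_percent"]),
            handwash_after=_parse_bool(row["handwash_after"]),
            positions=positions,
        )
        soil_in_mouth = _parse_bool(row["soil_in_mouth"])
        if key not in ingestion_by_key and soil_in_mouth is not None:
            amount_raw = str(row["amount_category"]).strip()
            ingestion_by_key[key] = IngestionReport(
                grower_id=row["grower_id"], season=season,
                soil_in_mouth=soil_in_mouth,
                days_with_ingestion=_opt_int(row["ingestion_days"]),
                amount_category=_enum_value(AmountCategory, amount_raw, "tasks.csv")
                    if amount_raw else None,
                face_contact=_parse_bool(row.get("face_contact")) or False,
                face_contact_days=_opt_int(row.get("face_contact_days")),
                produce_sampling=_parse_bool(row.get("produce_sampling")) or False,
                produce_events_per_month=_opt_float(row.get("produce_events_per_month")),
                produce_wash_fraction=_opt_float(row.get("produce_wash_fraction")),
                meals_onsite=_parse_bool(row.get("meals_onsite")) or False,
            )

    records, dropped = [], 0
    for _, row in growers.iterrows():
        gid = row["grower_id"]
        seasons: dict[Season, SeasonRecord] = {}
        for season, onsite_row in onsite_by_grower.get(gid, {}).items():
            key = (gid, season)
            season_tasks = tasks_by_key.get(key, {})
            for a in MesoActivity:  # missing rows mean non-engagement
                season_tasks.setdefault(
                    a,
                    TaskActivity(
                        grower_id=gid, season=season, activity=a,
                        days_per_month=0.0, hours_per_day=0.0, contact_fraction=0.0,
                    ),
                )
            seasons[season] = SeasonRecord(
                onsite=onsite_row, tasks=season_tasks,
                ingestion=ingestion_by_key.get(key),
            )
        record = GrowerRecord(
            grower_id=gid,
            sex=_enum_value(Sex, row["sex"], "growers.csv"),
            age=float(row["age"]),
            smoking=_parse_bool(row["smoking"]) or False,
            employment_status=int(float(row["employment_status"])),
            farm_size=float(row["farm_size"]),
            farm_size_unit=_enum_value(FarmSizeUnit, row["farm_size_unit"], "growers.csv"),
            body_weight=_opt_float(row.get("body_weight_kg")),
            seasons=seasons,
        )
        violations = validate_record(record)
        if violations:
            dropped += 1
            for v in violations:
                log.warning("dropping grower %s: %s", gid, v)
            continue
        records.append(record)
    log.info("read %d valid records (%d dropped)", len(records), dropped)
    return records


def tasks_wide_to_long(df: pd.DataFrame) -> pd.DataFrame:
    """Convert a hand-entered wide task sheet to the long tasks schema.

    Expects ``grower_id``, ``season`` plus ``<activity>_days_per_month``,
    ``<activity>_hours_per_day`` and ``<activity>_contact_percent`` columns
    for each meso-activity present.
    """
    rows = []
    for _, row in df.iterrows():
        for a in MesoActivity:
            prefix = a.value
            if f"{prefix}_days_per_month" not in df.columns:
                continue
            rows.append({
                "grower_id": row["grower_id"],
                "season": row["season"],
                "activity": prefix,
                "days_per_month": row[f"{prefix}_days_per_month"],
                "hours_per_day": row.get(f"{prefix}_hours_per_day", 0.0),
                "contact_percent": row.get(f"{prefix}_contact_percent", ""),
            })
    return pd.DataFrame(rows)


def default_config() -> dict:
    """The full default configuration (every published default pre-filled)."""
    from . import exposure_factors as ef
    from . import ingestion_rates as ir

    return {
        "constants": {
            "concentration_mg_per_kg": 400.0,
            "weeks_per_month": ef.WEEKS_PER_MONTH,
            "hours_per_month": ef.HOURS_PER_MONTH,
            "days_per_month_avg_method1": ef.DAYS_PER_MONTH_AVERAGING_METHOD1,
            "outdoor_workday_hours": ef.OUTDOOR_WORKDAY_HOURS,
            "indoor_nonwork_hours": ef.INDOOR_NONWORK_HOURS,
        },
        "ingestion_rates": {
            "daily_soil_dust_mg": ir.DAILY_SOIL_DUST_MG,
            "daily_outdoor_soil_mg": ir.DAILY_OUTDOOR_SOIL_MG,
            "daily_indoor_dust_mg": ir.DAILY_INDOOR_DUST_MG,
            "contact_means": {a.value: m for a, m in ir.DEFAULT_CONTACT_MEANS.items()},
        },
        "thresholds": {
            "high_contact": ir.HIGH_CONTACT_THRESHOLD,
            "mid_contact": ir.MID_CONTACT_THRESHOLD,
        },
        "simulation": {
            "n_growers": 5000,
            "rate_perturbation_halfwidth": 0.2,
            "include_zero_pool_values": True,
        },
        "cohort_spec": {
            "n_growers": 38,
            "unaccounted_time_fraction": 0.35,
            "concurrency_fraction": 0.29,
        },
    }


def load_config(path=None) -> dict:
    """Defaults overlaid with a YAML/JSON config file, section by section."""
    config = default_config()
    if path is None:
        return config
    with open(path, "r", encoding="utf-8") as fh:
        user = yaml.safe_load(fh) or {}
    for section, values in user.items():
        if section in config and isinstance(values, Mapping):
            config[section] = {**config[section], **values}
        else:
            config[section] = values
    return config
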