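"""CSV/YAML schemas, strict readers and the run-directory layout.

All tables are UTF-8 comma-separated files with required headers and
lowercase snake_case category labels.  Validation is strict and names
the offending column, value and line number; category vocabularies
(age bands, chapters) come from the run configuration, so unknown
labels are rejected rather than silently propagated.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import CalibrationTargetSet, PriorSpec
from .errors import ConfigError, SchemaError
from .need import BurdenTable, ConditionMix, PopulationProjection
from .states import (
    ACTIVE_STATUSES,
    LOCATIONS,
    SEXES,
    STATUSES,
    AgeBand,
    EntryStream,
    HoursProfile,
    StateSpace,
    StockVector,
)
from .supply import AgingRule, MultiplierSet, TransitionTable

#: Pseudo-chapter under which preventative/administrative activity is
#: reported in the condition-mix table.
PREVENT_ADMIN = "prevent_admin"

ENTRY_TYPES = ("graduate", "migrant")


@dataclass(frozen=True)
class TableSchema:
    """Declarative schema for one CSV table."""

    name: str
    columns: tuple[str, ...]
    categorical: dict[str, tuple[str, ...]]
    numeric: dict[str, tuple[float | None, float | None]]


def build_schemas(
    band_labels: tuple[str, ...],
    sexes: tuple[str, ...] = SEXES,
    locations: tuple[str, ...] = LOCATIONS,
    chapters: tuple[str, ...] = (),
) -> dict[str, TableSchema]:
    """Schema set for a given category vocabulary."""
    id_cat = {
        "sex": tuple(sexes),
        "age_band": tuple(band_labels),
        "location": tuple(locations),
        "status": STATUSES,
    }
    trans_cat = {
        "sex": tuple(sexes),
        "age_band": tuple(band_labels),
        "from_location": tuple(locations),
        "from_status": STATUSES,
        "to_location": tuple(locations),
        "to_status": STATUSES,
    }
    chapters_plus = tuple(chapters) + (PREVENT_ADMIN,)
    prob = (0.0, 1.0)
    nonneg = (0.0, None)
    return {
        "stock": TableSchema(
            "stock",
            ("year", "sex", "age_band", "location", "status", "headcount"),
            id_cat,
            {"headcount": nonneg},
        ),
        "hours": TableSchema(
            "hours",
            ("sex", "age_band", "status", "weekly_hours"),
            {
                "sex": tuple(sexes),
                "age_band": tuple(band_labels),
                "status": ACTIVE_STATUSES,
            },
            {"weekly_hours": nonneg},
        ),
        "transitions": TableSchema(
            "transitions",
            (*trans_cat.keys(), "probability"),
            trans_cat,
            {"probability": prob},
        ),
        "multipliers": TableSchema(
            "multipliers",
            (*trans_cat.keys(), "multiplier"),
            trans_cat,
            {"multiplier": (-1.0, 1.0)},
        ),
        "priors": TableSchema(
            "priors",
            (*trans_cat.keys(), "alpha", "beta", "mult_low", "mult_high"),
            trans_cat,
            {
                "alpha": (0.0, None),
                "beta": (0.0, None),
                "mult_low": (None, None),
                "mult_high": (None, None),
            },
        ),
        "entries": TableSchema(
            "entries",
            ("year", "type", "count"),
            {"type": ENTRY_TYPES},
            {"count": nonneg},
        ),
        "allocation": TableSchema(
            "allocation",
            ("type", "sex", "age_band", "location", "status", "fraction"),
            {"type": ENTRY_TYPES, **id_cat},
            {"fraction": prob},
        ),
        "targets": TableSchema(
            "targets",
            ("year", "sex", "age_band", "location", "status", "headcount"),
            id_cat,
            {"headcount": nonneg},
        ),
        "population": TableSchema(
            "population",
            ("year", "sex", "age_band", "persons"),
            {"sex": tuple(sexes), "age_band": tuple(band_labels)},
            {"persons": nonneg},
        ),
        "burden": TableSchema(
            "burden",
            ("chapter", "sex", "age_band", "incident_cases", "prevalent_cases"),
            {
                "chapter": tuple(chapters),
                "sex": tuple(sexes),
                "age_band": tuple(band_labels),
            },
            {"incident_cases": nonneg, "prevalent_cases": nonneg},
        ),
        "mix": TableSchema(
            "mix",
            ("chapter", "sex", "age_band", "proportion"),
            {
                "chapter": chapters_plus,
                "sex": tuple(sexes),
                "age_band": tuple(band_labels),
            },
            {"proportion": prob},
        ),
        "lengths": TableSchema(
            "lengths",
            ("sex", "age_band", "mean_minutes"),
            {"sex": tuple(sexes), "age_band": tuple(band_labels)},
            {"mean_minutes": (0.0, None)},
        ),
        "attendances": TableSchema(
            "attendances",
            ("year", "sex", "age_band", "consultations"),
            {"sex": tuple(sexes), "age_band": tuple(band_labels)},
            {"consultations": nonneg},
        ),
        "mapping": TableSchema(
            "mapping",
            ("source_category", "icpc2_chapter"),
            {"icpc2_chapter": tuple(chapters)},
            {},
        ),
    }


def read_table(path: str | Path, schema: TableSchema) -> pd.DataFrame:
    """Read and validate one CSV table against its schema.

    Raises :class:`SchemaError` with the offending column, value and
    1-based file line number (header is line 1).
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{schema.name}: file not found: {path}")
    if path.stat().st_size == 0 or not path.read_text().strip():
        raise SchemaError(f"{schema.name}: {path} is empty")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    got = tuple(df.columns)
    if set(got) != set(schema.columns):
        raise SchemaError(
            f"{schema.name}: bad header in {path}: expected columns "
            f"{sorted(schema.columns)}, got {sorted(got)}"
        )
    df = df.loc[:, list(schema.columns)]
    if len(df) == 0:
        raise SchemaError(f"{schema.name}: {path} has a header but no rows")

    for col, allowed in schema.categorical.items():
        bad = ~df[col].isin(allowed)
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            raise SchemaError(
                f"{schema.name}: unknown {col} label {df[col].iloc[i]!r} "
                f"at line {i + 2} of {path} (allowed: {list(allowed)})"
            )
    if "year" in df.columns:
        try:
            df["year"] = df["year"].astype(int)
        except ValueError as exc:
            raise SchemaError(f"{schema.name}: non-integer year in {path}: {exc}") from exc
    for col, (low, high) in schema.numeric.items():
        try:
            values = df[col].astype(float)
        except ValueError as exc:
            raise SchemaError(
                f"{schema.name}: non-numeric value in column {col!r} of {path}: {exc}"
            ) from exc
        df[col] = values
        bad = values.isna()
        if low is not None:
            bad |= values < low
        if high is not None:
            bad |= values > high
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            raise SchemaError(
                f"{schema.name}: value {df[col].iloc[i]!r} out of range for "
                f"{col!r} at line {i + 2} of {path}"
            )
    return df


# ---------------------------------------------------------------------------
# run configuration and directory IO


@dataclass
class RunConfig:
    """Parsed run configuration; all paths resolved and existence-checked."""

    root: Path
    sexes: tuple[str, ...]
    age_bands: tuple[AgeBand, ...]
    locations: tuple[str, ...]
    chapters: tuple[str, ...]
    supply_base_year: int
    supply_horizon: int
    need_base_year: int
    need_horizon: int
    calibration_n_samples: int
    calibration_tolerance: float
    calibration_seed: int
    standard_week: float
    working_weeks: float
    files: dict[str, Path]
    raw: dict

    @property
    def space(self) -> StateSpace:
        return StateSpace(self.sexes, self.age_bands, self.locations)

    @property
    def schemas(self) -> dict[str, TableSchema]:
        return build_schemas(
            tuple(b.label for b in self.age_bands),
            self.sexes,
            self.locations,
            self.chapters,
        )


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} is not a YAML mapping")
    try:
        bands = tuple(
            AgeBand(b["label"], int(b["lower"]), None if b.get("upper") in (None, "") else int(b["upper"]))
            for b in raw["age_bands"]
        )
        supply = raw.get("supply", {})
        need = raw.get("need", {})
        cal = raw.get("calibration", {})
        hours = raw.get("hours", {})
        files = {
            name: (path.parent / p).resolve()
            for name, p in raw.get("files", {}).items()
        }
        cfg = RunConfig(
            root=path.parent.resolve(),
            sexes=tuple(raw.get("sexes", SEXES)),
            age_bands=bands,
            locations=tuple(raw.get("locations", LOCATIONS)),
            chapters=tuple(raw.get("chapters", ())),
            supply_base_year=int(supply.get("base_year", 2004)),
            supply_horizon=int(supply.get("horizon", 7)),
            need_base_year=int(need.get("base_year", 2003)),
            need_horizon=int(need.get("horizon", 10)),
            calibration_n_samples=int(cal.get("n_samples", 1000)),
            calibration_tolerance=float(cal.get("tolerance", 0.05)),
            calibration_seed=int(cal.get("seed", 0)),
            standard_week=float(hours.get("standard_week", 40.0)),
            working_weeks=float(hours.get("working_weeks", 44.0)),
            files=files,
            raw=raw,
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"malformed config {path}: {exc}") from exc
    missing = [str(p) for p in cfg.files.values() if not p.exists()]
    if missing:
        raise ConfigError(f"config references missing files: {missing}")
    return cfg


def _table(cfg: RunConfig, name: str) -> pd.DataFrame:
    if name not in cfg.files:
        raise ConfigError(f"config lists no {name!r} file")
    return read_table(cfg.files[name], cfg.schemas[name])


def load_base_stock(cfg: RunConfig) -> StockVector:
    df = _table(cfg, "stock")
    df = df[df["year"] == cfg.supply_base_year]
    if len(df) == 0:
        raise SchemaError(f"stock table has no rows for base year {cfg.supply_base_year}")
    space = cfg.space
    counts = space.empty()
    for row in df.itertuples(index=False):
        counts.iloc[space.position((row.sex, row.age_band, row.location, row.status))] += row.headcount
    return StockVector(cfg.supply_base_year, counts)


def load_hours(cfg: RunConfig) -> HoursProfile:
    df = _table(cfg, "hours")
    weekly = {
        (r.sex, r.age_band, r.status): float(r.weekly_hours)
        for r in df.itertuples(index=False)
    }
    return HoursProfile(
        weekly_hours=weekly,
        standard_week=cfg.standard_week,
        working_weeks=cfg.working_weeks,
    )


def load_transitions(cfg: RunConfig) -> TransitionTable:
    return TransitionTable(cfg.space, _table(cfg, "transitions"))


def load_multipliers(cfg: RunConfig, table: TransitionTable) -> MultiplierSet:
    df = _table(cfg, "multipliers")
    mapping = {
        (r.sex, r.age_band, r.from_location, r.from_status, r.to_location, r.to_status): float(r.multiplier)
        for r in df.itertuples(index=False)
    }
    lo = min(min(mapping.values(), default=0.0), -0.10)
    hi = max(max(mapping.values(), default=0.0), 0.10)
    return MultiplierSet.from_mapping(table, mapping, bounds=(lo, hi))


def load_entries(cfg: RunConfig) -> EntryStream:
    counts = _table(cfg, "entries")
    alloc = _table(cfg, "allocation")
    space = cfg.space
    series = {}
    for etype in ENTRY_TYPES:
        sub = counts[counts["type"] == etype]
        series[etype] = dict(zip(sub["year"], sub["count"]))
    allocs = {}
    for etype in ENTRY_TYPES:
        sub = alloc[alloc["type"] == etype]
        s = space.empty()
        for r in sub.itertuples(index=False):
            s.iloc[space.position((r.sex, r.age_band, r.location, r.status))] += r.fraction
        allocs[etype] = s
    return EntryStream(
        graduates=series["graduate"],
        in_migrants=series["migrant"],
        graduate_allocation=allocs["graduate"],
        migrant_allocation=allocs["migrant"],
    )


def load_aging(cfg: RunConfig) -> AgingRule:
    fractions = cfg.raw.get("supply", {}).get("aging")
    if fractions is None:
        return AgingRule.default_for(cfg.age_bands)
    return AgingRule(fractions={str(k): float(v) for k, v in fractions.items()})


def load_priors(cfg: RunConfig) -> PriorSpec:
    return PriorSpec(cfg.space, _table(cfg, "priors"))


def load_targets(cfg: RunConfig) -> CalibrationTargetSet:
    return CalibrationTargetSet.from_frame(_table(cfg, "targets"))


def load_population(cfg: RunConfig) -> PopulationProjection:
    df = _table(cfg, "population")
    persons = df.set_index(["year", "sex", "age_band"])["persons"]
    return PopulationProjection(persons=persons)


def load_burden(cfg: RunConfig) -> BurdenTable:
    df = _table(cfg, "burden")
    if "mapping" in cfg.files:
        mapping = read_table(cfg.files["mapping"], cfg.schemas["mapping"])
        lookup = dict(zip(mapping["source_category"], mapping["icpc2_chapter"]))
        # burden chapters may arrive as source categories; translate when so
        df = df.assign(chapter=df["chapter"].map(lambda c: lookup.get(c, c)))
    idx = df.set_index(["chapter", "sex", "age_band"]).index
    return BurdenTable(
        incident=pd.Series(df["incident_cases"].to_numpy(), index=idx),
        prevalent=pd.Series(df["prevalent_cases"].to_numpy(), index=idx),
    )


def load_mix(cfg: RunConfig) -> ConditionMix:
    df = _table(cfg, "mix")
    pa = df[df["chapter"] == PREVENT_ADMIN]
    cond = df[df["chapter"] != PREVENT_ADMIN]
    if len(pa) == 0:
        raise SchemaError(
            f"mix table must include {PREVENT_ADMIN!r} rows for every cell"
        )
    prop = cond.set_index(["chapter", "sex", "age_band"])["proportion"]
    share = pa.set_index(["sex", "age_band"])["proportion"]
    return ConditionMix(proportion=prop, prevent_admin_share=share)


def load_lengths(cfg: RunConfig) -> pd.Series:
    df = _table(cfg, "lengths")
    return df.set_index(["sex", "age_band"])["mean_minutes"]


def load_attendances(cfg: RunConfig, year: int | None = None) -> pd.Series:
    df = _table(cfg, "attendances")
    year = cfg.need_base_year if year is None else year
    df = df[df["year"] == year]
    if len(df) == 0:
        raise SchemaError(f"attendance table has no rows for year {year}")
    return df.set_index(["sex", "age_band"])["consultations"]


def validate_run_dir(cfg: RunConfig) -> list[str]:
    """Validate every file the config references; returns the table names read."""
    loaders = {
        "stock": load_base_stock,
        "hours": load_hours,
        "transitions": load_transitions,
        "entries": load_entries,
        "allocation": load_entries,
        "priors": load_priors,
        "targets": load_targets,
        "population": load_population,
        "burden": load_burden,
        "mix": load_mix,
        "lengths": load_lengths,
        "attendances": load_attendances,
    }
    checked = []
    for name in cfg.files:
        if name == "mapping":
            read_table(cfg.files[name], cfg.schemas["mapping"])
            checked.append(name)
            continue
        if name == "multipliers":
            load_multipliers(cfg, load_transitions(cfg))
            checked.append(name)
            continue
        loader = loaders.get(name)
        if loader is None:
            raise ConfigError(f"config references unknown table kind {name!r}")
        loader(cfg)
        checked.append(name)
    return checked
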