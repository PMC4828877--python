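"""Serialise synthetic fixtures to a runnable input directory.

``write_fixture_dir`` lays out every CSV table plus a ``config.yaml``
so the command-line pipeline (validate, simulate-supply, calibrate,
run-scenario) can operate on generated data end to end.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .schemas import ENTRY_TYPES, PREVENT_ADMIN
from .states import ACTIVE_STATUSES
from .supply import TRANSITION_COLUMNS
from .synthetic import NeedFixture, SupplyFixture


def _id_frame(ids) -> pd.DataFrame:
    return pd.DataFrame(list(ids), columns=list(TRANSITION_COLUMNS))


def write_fixture_dir(
    out_dir: str | Path,
    supply: SupplyFixture,
    need: NeedFixture,
) -> Path:
    """Write all input tables and the config; returns the config path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = supply.config

    # --- supply side -------------------------------------------------
    stock = supply.base_stock.counts.rename("headcount").reset_index()
    stock.insert(0, "year", supply.base_stock.year)
    stock.to_csv(out / "stock.csv", index=False)

    hours_rows = [
        (sex, band, status, supply.hours.hours_for(sex, band, status))
        for sex in supply.space.sexes
        for band in supply.space.band_labels
        for status in ACTIVE_STATUSES
    ]
    pd.DataFrame(
        hours_rows, columns=["sex", "age_band", "status", "weekly_hours"]
    ).to_csv(out / "hours.csv", index=False)

    trans = _id_frame(supply.truth.table.ids)
    trans["probability"] = supply.truth.table.probabilities
    trans.to_csv(out / "transitions.csv", index=False)

    mults = _id_frame(supply.truth.table.ids)
    mults["multiplier"] = supply.truth.multipliers.values
    mults.to_csv(out / "multipliers.csv", index=False)

    supply.priors.frame.to_csv(out / "priors.csv", index=False)

    years = range(cfg.supply_base_year, cfg.supply_base_year + cfg.supply_horizon)
    grads, migs = cfg.graduates, cfg.in_migrants
    entries = pd.DataFrame(
        [(y, "graduate", grads) for y in years] + [(y, "migrant", migs) for y in years],
        columns=["year", "type", "count"],
    )
    entries.to_csv(out / "entries.csv", index=False)

    alloc_rows = []
    for etype, series in (
        ("graduate", supply.entries.graduate_allocation),
        ("migrant", supply.entries.migrant_allocation),
    ):
        assert etype in ENTRY_TYPES
        nz = series[series > 0]
        for (sex, band, loc, status), frac in nz.items():
            alloc_rows.append((etype, sex, band, loc, status, frac))
    pd.DataFrame(
        alloc_rows,
        columns=["type", "sex", "age_band", "location", "status", "fraction"],
    ).to_csv(out / "allocation.csv", index=False)

    targets = supply.targets.observed.rename("headcount").reset_index()
    targets.to_csv(out / "targets.csv", index=False)

    # --- need side ---------------------------------------------------
    need.population.persons.rename("persons").reset_index().to_csv(
        out / "population.csv", index=False
    )
    burden = pd.DataFrame(
        {
            "incident_cases": need.burden.incident,
            "prevalent_cases": need.burden.prevalent,
        }
    ).reset_index()
    burden.to_csv(out / "burden.csv", index=False)

    mix_cond = need.mix.proportion.rename("proportion").reset_index()
    mix_pa = need.mix.prevent_admin_share.rename("proportion").reset_index()
    mix_pa.insert(0, "chapter", PREVENT_ADMIN)
    pd.concat([mix_cond, mix_pa], ignore_index=True).to_csv(
        out / "mix.csv", index=False
    )

    need.lengths.rename("mean_minutes").reset_index().to_csv(
        out / "lengths.csv", index=False
    )
    att = need.attendances.rename("consultations").reset_index()
    att.insert(0, "year", cfg.need_base_year)
    att.to_csv(out / "attendances.csv", index=False)
    need.mapping.to_csv(out / "mapping.csv", index=False)

    # --- config ------------------------------------------------------
    config = {
        "sexes": list(cfg.sexes),
        "locations": list(cfg.locations),
        "chapters": list(cfg.chapters),
        "age_bands": [
            {"label": b.label, "lower": b.lower, "upper": b.upper}
            for b in cfg.age_bands
        ],
        "supply": {
            "base_year": cfg.supply_base_year,
            "horizon": cfg.supply_horizon,
            "temp_return_prob": cfg.temp_return_prob,
        },
        "need": {"base_year": cfg.need_base_year, "horizon": cfg.need_horizon},
        "calibration": {"n_samples": 1000, "tolerance": 0.05, "seed": cfg.seed},
        "hours": {"standard_week": 40.0, "working_weeks": 44.0},
        "files": {
            name: f"{name}.csv"
            for name in (
                "stock",
                "hours",
                "transitions",
                "multipliers",
                "priors",
                "entries",
                "allocation",
                "targets",
                "population",
                "burden",
                "mix",
                "lengths",
                "attendances",
                "mapping",
            )
        },
    }
    config_path = out / "config.yaml"
    config_path.write_text(yaml.safe_dump(config, sort_keys=False))
    return config_path
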