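"""Named what-if scenarios and predicted-versus-observed reports.

Three presets mirror the standard assumptions explored with this kind
of planner:

* ``scenario_1`` - base-year utilisation is optimal; per-case service
  use and age/sex-specific case rates stay constant, so requirements
  move with demography alone.
* ``scenario_2`` - utilisation per case rises 1.12% a year (optimal use
  reached at the end of the 10-year window).
* ``scenario_3`` - age/sex-specific incidence and prevalence rates rise
  2% a year.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd

from .errors import ConfigError
from .need import (
    BurdenTable,
    NeedProjection,
    PopulationProjection,
    ServiceProfile,
    consultations_to_fte,
    project_burden,
    project_consultations,
)
from .states import HoursProfile

#: (utilisation_multiplier, burden_growth) per preset.
SCENARIO_PRESETS = {
    "scenario_1": (1.0, 1.0),
    "scenario_2": (1.0112, 1.0),
    "scenario_3": (1.0, 1.02),
}


@dataclass(frozen=True)
class ScenarioSpec:
    """A named pair of annual growth factors plus the projection window."""

    name: str
    utilisation_multiplier: float = 1.0
    burden_growth: float = 1.0
    base_year: int = 2003
    horizon: int = 10

    def __post_init__(self) -> None:
        if self.utilisation_multiplier <= 0 or self.burden_growth <= 0:
            raise ConfigError("scenario growth factors must be positive")
        if self.horizon < 0:
            raise ConfigError("scenario horizon must be non-negative")

    @classmethod
    def preset(
        cls, name: str, base_year: int = 2003, horizon: int = 10
    ) -> "ScenarioSpec":
        try:
            u, g = SCENARIO_PRESETS[name]
        except KeyError:
            raise ConfigError(
                f"unknown scenario preset {name!r}; choose from {sorted(SCENARIO_PRESETS)}"
            ) from None
        return cls(
            name=name,
            utilisation_multiplier=u,
            burden_growth=g,
            base_year=base_year,
            horizon=horizon,
        )


def run_scenario(
    spec: ScenarioSpec,
    profile: ServiceProfile,
    burden_base: BurdenTable,
    population: PopulationProjection,
    hours_profile: HoursProfile,
) -> NeedProjection:
    """Project required consultations and FTE for every year of the window.

    Chains case projection -> consultation projection -> FTE conversion
    for each year from the base year to base + horizon inclusive.
    """
    rows = {}
    fte = {}
    for year in range(spec.base_year, spec.base_year + spec.horizon + 1):
        k = year - spec.base_year
        cases = project_burden(
            burden_base, population, spec.burden_growth, year, spec.base_year
        )
        persons = population.for_year(year)
        consult = project_consultations(
            profile, cases, persons, spec.utilisation_multiplier, k
        )
        rows[year] = consult
        fte[year] = consultations_to_fte(consult, profile.length_minutes, hours_profile)
    consultations = pd.DataFrame(rows).T.rename_axis("year")
    return NeedProjection(
        consultations=consultations,
        fte=pd.Series(fte, name="required_fte").rename_axis("year"),
    )


@dataclass
class ValidationReport:
    """Exact per-year differencing of a predicted against an observed series."""

    frame: pd.DataFrame  # predicted, observed, diff, abs_diff, pct_diff
    summed_abs_difference: float

    def to_dict(self) -> dict:
        return {
            "years": {
                str(year): {
                    k: (None if pd.isna(v) else float(v)) for k, v in row.items()
                }
                for year, row in self.frame.to_dict(orient="index").items()
            },
            "summed_abs_difference": self.summed_abs_difference,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path)


def compare(predicted: pd.Series, observed: pd.Series) -> ValidationReport:
    """Build a validation report on the overlapping years of two series.

    Signed difference is predicted - observed; percent difference uses
    the observed value as denominator (NaN where observed is zero).
    """
    predicted = pd.Series(predicted, dtype=float)
    observed = pd.Series(observed, dtype=float)
    common = predicted.index.intersection(observed.index)
    if len(common) == 0:
        raise ConfigError("predicted and observed series share no years")
    common = common.sort_values()
    p = predicted.loc[common]
    o = observed.loc[common]
    diff = p - o
    pct = diff.where(o != 0) / o.where(o != 0)
    frame = pd.DataFrame(
        {
            "predicted": p,
            "observed": o,
            "diff": diff,
            "abs_diff": diff.abs(),
            "pct_diff": pct,
        }
    ).rename_axis("year")
    return ValidationReport(
        frame=frame, summed_abs_difference=float(diff.abs().sum())
    )
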