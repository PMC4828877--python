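"""Needs-based demand model: from burden of disease to required GP FTE.

The base-year fit inverts observed utilisation: within each (sex, age
band) cell, the share of consultations managing each condition chapter
(ICPC-2 chapter headings) is divided by that chapter's incident plus
prevalent cases, giving average annual consultations per case.  The
residual preventative/administrative activity is expressed per capita.
Projection then re-multiplies: future cases (per-capita case rates
carried forward on the projected population, optionally growing) times
consultations per case, plus per-capita prevent/admin volume scaling
with population, gives required consultations; mean consultation
lengths convert those to clinical hours and hence FTE GPs.

By construction the fitted profile reproduces the base-year attendance
totals exactly whenever the chapter shares and the prevent/admin share
sum to one per cell (the reconstruction identity).
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, FitError, SchemaError
from .states import HoursProfile, annual_clinical_hours

CELL_LEVELS = ("sex", "age_band")
CHAPTER_LEVELS = ("chapter", "sex", "age_band")


def _require_index(series: pd.Series, levels: tuple[str, ...], what: str) -> pd.Series:
    if tuple(series.index.names) != levels:
        raise SchemaError(
            f"{what} must be indexed by {levels}, got {tuple(series.index.names)}"
        )
    if (series < 0).any():
        raise SchemaError(f"{what} contains negative values")
    return series.astype(float)


@dataclass
class PopulationProjection:
    """Persons by (year, sex, age_band)."""

    persons: pd.Series

    def __post_init__(self) -> None:
        self.persons = _require_index(
            self.persons, ("year", *CELL_LEVELS), "population"
        )

    def for_year(self, year: int) -> pd.Series:
        try:
            return self.persons.xs(year, level="year")
        except KeyError:
            raise SchemaError(f"population projection has no year {year}") from None

    @property
    def years(self) -> list[int]:
        return sorted(set(self.persons.index.get_level_values("year")))


@dataclass
class BurdenTable:
    """Incident + prevalent cases by condition chapter and demographic cell."""

    incident: pd.Series
    prevalent: pd.Series

    def __post_init__(self) -> None:
        self.incident = _require_index(self.incident, CHAPTER_LEVELS, "incident cases")
        self.prevalent = _require_index(
            self.prevalent, CHAPTER_LEVELS, "prevalent cases"
        )
        if not self.incident.index.sort_values().equals(
            self.prevalent.index.sort_values()
        ):
            raise SchemaError("incident and prevalent tables cover different cells")
        self.prevalent = self.prevalent.reindex(self.incident.index)

    @property
    def cases(self) -> pd.Series:
        """The service-norm denominator: incident plus prevalent cases."""
        return self.incident + self.prevalent

    @property
    def chapters(self) -> list[str]:
        return sorted(set(self.incident.index.get_level_values("chapter")))


@dataclass
class ConditionMix:
    """Observed share of consultations managing each chapter, per cell.

    Shares may sum above one across chapters within a cell because a
    single consultation can manage several problems; each chapter share
    is treated independently.
    """

    proportion: pd.Series
    prevent_admin_share: pd.Series

    def __post_init__(self) -> None:
        self.proportion = _require_index(
            self.proportion, CHAPTER_LEVELS, "condition mix"
        )
        self.prevent_admin_share = _require_index(
            self.prevent_admin_share, CELL_LEVELS, "prevent/admin share"
        )


@dataclass
class ServiceProfile:
    """Fitted base-year service norms.

    per_case: consultations per incident/prevalent case per year,
    by chapter and cell.  prevent_admin_per_capita: consultations per
    person per year.  length_minutes: mean consultation length per cell.
    """

    per_case: pd.Series
    prevent_admin_per_capita: pd.Series
    length_minutes: pd.Series

    def __post_init__(self) -> None:
        self.per_case = _require_index(self.per_case, CHAPTER_LEVELS, "per-case rates")
        self.prevent_admin_per_capita = _require_index(
            self.prevent_admin_per_capita, CELL_LEVELS, "prevent/admin rates"
        )
        self.length_minutes = _require_index(
            self.length_minutes, CELL_LEVELS, "consultation lengths"
        )
        if (self.length_minutes <= 0).any():
            raise ConfigError("mean consultation lengths must be positive")


def fit_service_profile(
    attendances: pd.Series,
    mix: ConditionMix,
    burden: BurdenTable,
    population: pd.Series,
    lengths: pd.Series,
) -> ServiceProfile:
    """Invert base-year utilisation into consultations-per-case norms.

    per_case(ch,s,a) = attendances(s,a) * proportion(ch,s,a) / cases(ch,s,a);
    prevent_admin_per_capita(s,a) = attendances(s,a) * share(s,a) / persons(s,a).
    A positive share with zero cases is unidentifiable and raises
    :class:`FitError` naming the cell.
    """
    attendances = _require_index(attendances, CELL_LEVELS, "attendances")
    population = _require_index(population, CELL_LEVELS, "base-year population")
    lengths = _require_index(lengths, CELL_LEVELS, "consultation lengths")

    cases = burden.cases
    prop = mix.proportion
    if not prop.index.sort_values().equals(cases.index.sort_values()):
        raise SchemaError("condition mix and burden tables cover different cells")
    cases = cases.reindex(prop.index)

    att_by_cell = attendances.reindex(
        pd.MultiIndex.from_arrays(
            [prop.index.get_level_values("sex"), prop.index.get_level_values("age_band")],
            names=CELL_LEVELS,
        )
    )
    if att_by_cell.isna().any():
        raise SchemaError("attendance table missing a (sex, age_band) cell")
    chapter_consults = att_by_cell.to_numpy() * prop.to_numpy()

    bad = (prop.to_numpy() > 0) & (cases.to_numpy() == 0)
    if bad.any():
        cell = prop.index[np.argmax(bad)]
        raise FitError(
            f"positive consultation share with zero cases at {tuple(cell)}; "
            "supply cases or zero the share"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        per_case_vals = np.where(
            prop.to_numpy() > 0, chapter_consults / cases.to_numpy(), 0.0
        )
    per_case = pd.Series(per_case_vals, index=prop.index)

    persons = population.reindex(mix.prevent_admin_share.index)
    if persons.isna().any() or (persons == 0).any():
        raise SchemaError("base-year population missing or zero for a cell")
    att_cells = attendances.reindex(mix.prevent_admin_share.index)
    pa_per_capita = att_cells * mix.prevent_admin_share / persons

    return ServiceProfile(
        per_case=per_case,
        prevent_admin_per_capita=pa_per_capita,
        length_minutes=lengths,
    )


def project_burden(
    burden_base: BurdenTable,
    population: PopulationProjection,
    burden_growth: float,
    year: int,
    base_year: int,
) -> pd.Series:
    """Cases by chapter/cell in ``year``.

    Base-year per-capita case rates are applied to the projected
    population and compounded by ``burden_growth`` per year, so
    demographic change and (optionally) rising age-specific rates both
    feed through: cases = rate_base * persons(year) * growth^(year-base).
    """
    if burden_growth <= 0:
        raise ConfigError(f"burden growth factor must be positive, got {burden_growth}")
    base_persons = population.for_year(base_year)
    cases_base = burden_base.cases
    cell_index = pd.MultiIndex.from_arrays(
        [
            cases_base.index.get_level_values("sex"),
            cases_base.index.get_level_values("age_band"),
        ],
        names=CELL_LEVELS,
    )
    persons_base_aligned = base_persons.reindex(cell_index)
    persons_now_aligned = population.for_year(year).reindex(cell_index)
    if persons_base_aligned.isna().any() or persons_now_aligned.isna().any():
        raise SchemaError("population projection missing a (sex, age_band) cell")
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(
            persons_base_aligned.to_numpy() > 0,
            cases_base.to_numpy() / persons_base_aligned.to_numpy(),
            0.0,
        )
    k = year - base_year
    cases = rate * persons_now_aligned.to_numpy() * burden_growth**k
    return pd.Series(cases, index=cases_base.index)


def project_consultations(
    profile: ServiceProfile,
    cases: pd.Series,
    persons: pd.Series,
    utilisation_multiplier: float = 1.0,
    k: int = 0,
) -> pd.Series:
    """Required consultations by (sex, age_band) in one projection year.

    consultations(s,a) = sum_ch per_case(ch,s,a) * u^k * cases(ch,s,a)
                         + prevent_admin_per_capita(s,a) * persons(s,a)

    where u is the annual service-use multiplier (1.0112 under the
    rising-utilisation scenario, 1.0 otherwise) and k the years since
    the base year.  Prevent/admin volume scales with population only.
    """
    if utilisation_multiplier <= 0:
        raise ConfigError("utilisation multiplier must be positive")
    if k < 0:
        raise ConfigError("years since base must be non-negative")
    cases = cases.reindex(profile.per_case.index)
    if cases.isna().any():
        raise SchemaError("case projection missing a chapter cell")
    weighted = profile.per_case * (utilisation_multiplier**k) * cases
    by_cell = weighted.groupby(level=list(CELL_LEVELS)).sum()
    persons = persons.reindex(profile.prevent_admin_per_capita.index)
    if persons.isna().any():
        raise SchemaError("population missing a (sex, age_band) cell")
    pa = profile.prevent_admin_per_capita * persons
    return by_cell.reindex(pa.index).fillna(0.0) + pa


def consultations_to_fte(
    consultations: pd.Series,
    lengths: pd.Series,
    profile: HoursProfile,
) -> float:
    """FTE GPs needed to deliver the given consultations.

    FTE = sum_cells consultations * length_minutes / 60 / annual clinical
    hours per FTE (1760 h with the default 40 h x 44 wk year).
    """
    consultations = _require_index(consultations, CELL_LEVELS, "consultations")
    lengths = _require_index(lengths, CELL_LEVELS, "consultation lengths")
    if (lengths <= 0).any():
        raise ConfigError("mean consultation lengths must be positive")
    lengths = lengths.reindex(consultations.index)
    if lengths.isna().any():
        raise SchemaError("consultation length missing for a cell")
    hours = (consultations * lengths).sum() / 60.0
    return float(hours / annual_clinical_hours(profile))


@dataclass
class NeedProjection:
    """Annual required consultations and FTE produced by a scenario run."""

    consultations: pd.DataFrame  # rows: years, columns: (sex, age_band)
    fte: pd.Series  # year -> required FTE

    @property
    def years(self) -> list[int]:
        return list(self.consultations.index)

    def totals(self) -> pd.Series:
        return self.consultations.sum(axis=1).rename("consultations")
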