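"""Employment-state space and workforce accounting primitives.

The supply side of the planner tracks general practitioners (GPs) as a
cohort distributed over discrete employment states.  A state is the
4-tuple ``(sex, age_band, location, status)`` where status is one of
``full_time``, ``part_time`` (the *active* statuses), ``temporary_exit``
(a reversible departure such as parental leave) or ``permanent_exit``
(retirement, death; absorbing).  Full time means at least 35 weekly
clinical hours.

This module provides the state space itself, the stock container, the
clinical-hours profile used to convert headcounts to full-time
equivalents (FTE), and the entry streams (vocational-training graduates
and in-migrating GPs) that feed the stock.
"""

from __future__ import annotations

import math
from collections.abc import Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, ParameterError, SchemaError

SEXES = ("male", "female")
LOCATIONS = ("urban", "rural")
ACTIVE_STATUSES = ("full_time", "part_time")
EXIT_STATUSES = ("temporary_exit", "permanent_exit")
STATUSES = ACTIVE_STATUSES + EXIT_STATUSES

#: Weekly clinical hours at or above which a GP counts as full time.
FULL_TIME_THRESHOLD = 35.0

STATE_LEVELS = ("sex", "age_band", "location", "status")


@dataclass(frozen=True)
class AgeBand:
    """A contiguous age interval, e.g. 35-44 years.

    ``upper is None`` marks the open-ended terminal band (65+).
    """

    label: str
    lower: int
    upper: int | None = None

    @property
    def width(self) -> int | None:
        return None if self.upper is None else self.upper - self.lower + 1

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        hi = "+" if self.upper is None else str(self.upper)
        return f"{self.label}[{self.lower}-{hi}]"


#: Five-band default partition of working ages used throughout.
DEFAULT_AGE_BANDS = (
    AgeBand("lt35", 25, 34),
    AgeBand("35_44", 35, 44),
    AgeBand("45_54", 45, 54),
    AgeBand("55_64", 55, 64),
    AgeBand("65plus", 65, None),
)


def validate_age_bands(bands: tuple[AgeBand, ...]) -> None:
    """Check that bands are non-empty, ordered, disjoint and contiguous."""
    if not bands:
        raise ConfigError("at least one age band is required")
    labels = [b.label for b in bands]
    if len(set(labels)) != len(labels):
        raise ConfigError(f"duplicate age band labels: {labels}")
    for prev, nxt in zip(bands, bands[1:]):
        if prev.upper is None:
            raise ConfigError(f"open-ended band {prev.label!r} must be last")
        if nxt.lower != prev.upper + 1:
            raise ConfigError(
                f"age bands {prev.label!r} and {nxt.label!r} are not contiguous"
            )


class StateSpace:
    """Ordered collection of employment states for one model run.

    Dimensions (sexes, age bands, locations) are configurable so that
    reduced toy spaces can back oracle tests; statuses are fixed.
    """

    def __init__(
        self,
        sexes: tuple[str, ...] = SEXES,
        age_bands: tuple[AgeBand, ...] = DEFAULT_AGE_BANDS,
        locations: tuple[str, ...] = LOCATIONS,
    ) -> None:
        if not sexes or not locations:
            raise ConfigError("state space needs at least one sex and one location")
        validate_age_bands(tuple(age_bands))
        self.sexes = tuple(sexes)
        self.age_bands = tuple(age_bands)
        self.locations = tuple(locations)
        self.band_labels = tuple(b.label for b in self.age_bands)
        states = [
            (sex, band, loc, status)
            for sex in self.sexes
            for band in self.band_labels
            for loc in self.locations
            for status in STATUSES
        ]
        self.index = pd.MultiIndex.from_tuples(states, names=STATE_LEVELS)
        self._pos = {state: i for i, state in enumerate(states)}
        status_arr = np.array([s[3] for s in states])
        self.active_mask = np.isin(status_arr, ACTIVE_STATUSES)
        self.temporary_mask = status_arr == "temporary_exit"
        self.permanent_mask = status_arr == "permanent_exit"

    @property
    def n_states(self) -> int:
        return len(self.index)

    def position(self, state: tuple[str, str, str, str]) -> int:
        try:
            return self._pos[state]
        except KeyError:
            raise SchemaError(f"unknown employment state {state!r}") from None

    def __contains__(self, state) -> bool:
        return state in self._pos

    def band(self, label: str) -> AgeBand:
        for b in self.age_bands:
            if b.label == label:
                return b
        raise SchemaError(f"unknown age band label {label!r}")

    def next_band(self, label: str) -> str | None:
        """Label of the band a cohort graduates into, or None for the terminal band."""
        i = self.band_labels.index(label)
        return None if i == len(self.band_labels) - 1 else self.band_labels[i + 1]

    def empty(self) -> pd.Series:
        return pd.Series(0.0, index=self.index)

    def series(self, mapping: Mapping[tuple, float]) -> pd.Series:
        """Dense state-indexed series from a sparse mapping; unknown keys rejected."""
        s = self.empty()
        for state, value in mapping.items():
            s.iloc[self.position(tuple(state))] = float(value)
        return s


@dataclass
class StockVector:
    """Headcounts (continuous, expected values) in every state for one year."""

    year: int
    counts: pd.Series

    def __post_init__(self) -> None:
        if (self.counts < -1e-9).any():
            bad = self.counts[self.counts < -1e-9]
            raise ParameterError(
                f"negative headcounts are not allowed: {bad.to_dict()}"
            )
        self.counts = self.counts.clip(lower=0.0).astype(float)

    @property
    def total(self) -> float:
        """All states including exits (the conserved quantity)."""
        return float(self.counts.sum())

    @property
    def active(self) -> pd.Series:
        status = self.counts.index.get_level_values("status")
        return self.counts[status.isin(ACTIVE_STATUSES)]

    @property
    def active_total(self) -> float:
        return float(self.active.sum())


@dataclass
class HoursProfile:
    """Mean weekly clinical hours by stratum, with the FTE yardstick.

    Lookup falls back from the full ``(sex, age_band, status)`` key to a
    status-only mean, so a profile may be supplied at either granularity.
    One FTE corresponds to ``standard_week`` clinical hours per week over
    ``working_weeks`` weeks a year (defaults 40 h x 44 wk = 1760 h/yr,
    the conventional full-time yardstick after leave and training).
    """

    weekly_hours: Mapping[tuple[str, str, str], float] = field(default_factory=dict)
    status_means: Mapping[str, float] = field(default_factory=dict)
    standard_week: float = 40.0
    working_weeks: float = 44.0

    def __post_init__(self) -> None:
        if self.standard_week <= 0 or self.working_weeks <= 0:
            raise ConfigError(
                "standard_week and working_weeks must both be positive, got "
                f"{self.standard_week} and {self.working_weeks}"
            )
        for (_, _, status), hours in self.weekly_hours.items():
            self._check_hours(status, hours)
        for status, hours in self.status_means.items():
            self._check_hours(status, hours)

    @staticmethod
    def _check_hours(status: str, hours: float) -> None:
        if hours < 0:
            raise ConfigError(f"negative weekly hours for status {status!r}")
        if status == "part_time" and hours >= FULL_TIME_THRESHOLD:
            raise ConfigError(
                f"part-time mean hours {hours} must be below {FULL_TIME_THRESHOLD}"
            )
        if status == "full_time" and hours < FULL_TIME_THRESHOLD:
            raise ConfigError(
                f"full-time mean hours {hours} must be at least {FULL_TIME_THRESHOLD}"
            )

    @classmethod
    def from_status_means(
        cls,
        full_time: float = 40.0,
        part_time: float = 20.0,
        standard_week: float = 40.0,
        working_weeks: float = 44.0,
    ) -> "HoursProfile":
        return cls(
            status_means={"full_time": full_time, "part_time": part_time},
            standard_week=standard_week,
            working_weeks=working_weeks,
        )

    def hours_for(self, sex: str, age_band: str, status: str) -> float:
        key = (sex, age_band, status)
        if key in self.weekly_hours:
            return float(self.weekly_hours[key])
        if status in self.status_means:
            return float(self.status_means[status])
        raise SchemaError(
            f"no weekly-hours entry for stratum {key} and no status-level fallback"
        )


def annual_clinical_hours(profile: HoursProfile) -> float:
    """Clinical hours supplied by one FTE GP in a year.

    With the defaults (40 h standard week, 44 working weeks) this is
    exactly 1760 h/year.
    """
    if profile.standard_week <= 0 or profile.working_weeks <= 0:
        raise ConfigError("standard_week and working_weeks must be positive")
    return profile.standard_week * profile.working_weeks


def headcount_to_fte(
    stock: StockVector, profile: HoursProfile
) -> tuple[float, pd.Series]:
    """Convert a stock of headcounts into full-time-equivalent GPs.

    FTE(state) = headcount(state) x weekly_hours(state) / standard_week
    for active states; exit states supply no clinical time and
    contribute zero.  Returns ``(total_fte, per_state_fte)``.
    """
    per_state = pd.Series(0.0, index=stock.counts.index)
    for state, count in stock.counts.items():
        sex, band, _loc, status = state
        if status not in ACTIVE_STATUSES:
            continue
        if count == 0.0:
            continue
        hours = profile.hours_for(sex, band, status)
        per_state[state] = count * hours / profile.standard_week
    return float(per_state.sum()), per_state


@dataclass
class EntryStream:
    """Annual inflows of graduates and in-migrating GPs.

    Counts may be constants (held flat across the horizon) or
    per-year mappings.  Each entry type carries an allocation over the
    state space: non-negative, zero on exit states, summing to one over
    active states.
    """

    graduates: float | Mapping[int, float]
    in_migrants: float | Mapping[int, float]
    graduate_allocation: pd.Series
    migrant_allocation: pd.Series

    def __post_init__(self) -> None:
        for name, alloc in (
            ("graduate", self.graduate_allocation),
            ("migrant", self.migrant_allocation),
        ):
            if (alloc < -1e-12).any():
                raise ConfigError(f"{name} allocation has negative fractions")
            status = alloc.index.get_level_values("status")
            exit_share = alloc[~status.isin(ACTIVE_STATUSES)].abs().sum()
            if exit_share > 1e-9:
                raise ConfigError(f"{name} allocation places entrants in exit states")
            total = float(alloc.sum())
            if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-6):
                raise ConfigError(
                    f"{name} allocation fractions sum to {total}, expected 1"
                )

    @staticmethod
    def _count(source: float | Mapping[int, float], year: int, what: str) -> float:
        if isinstance(source, Mapping):
            try:
                return float(source[year])
            except KeyError:
                raise ConfigError(f"no {what} entry count for year {year}") from None
        return float(source)

    def counts_for(self, year: int) -> tuple[float, float]:
        return (
            self._count(self.graduates, year, "graduate"),
            self._count(self.in_migrants, year, "in-migrant"),
        )

    def entries_for(self, year: int) -> pd.Series:
        """Entrant headcounts by state for the cycle starting in ``year``."""
        grads, migs = self.counts_for(year)
        return grads * self.graduate_allocation + migs * self.migrant_allocation

    @property
    def total_base(self) -> float:  # pragma: no cover - convenience
        g = self.graduates if not isinstance(self.graduates, Mapping) else float("nan")
        m = (
            self.in_migrants
            if not isinstance(self.in_migrants, Mapping)
            else float("nan")
        )
        return float(g) + float(m)
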