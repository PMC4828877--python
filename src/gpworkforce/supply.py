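"""Deterministic state-transition cohort projection of GP supply.

Each annual cycle applies, in a fixed documented order: (1) entries
(graduates and in-migrants) allocated over active states, (2) expected
flows between states driven by annual transition probabilities with a
compounding time multiplier, (3) cohort aging that graduates a fixed
fraction of each age band into the next.  The model propagates expected
values (fractional headcounts), not stochastic individuals, so total
headcount including exit states is conserved exactly up to entries.

Allowed transitions, all within a (sex, age_band) stratum:
full<->part time (same location), urban<->rural (same status),
active -> temporary_exit (same location), active -> permanent_exit,
temporary_exit -> active (explicit destination), and
temporary_exit -> permanent_exit.  Permanent exit is absorbing.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, ParameterError, SchemaError
from .states import (
    ACTIVE_STATUSES,
    AgeBand,
    EntryStream,
    HoursProfile,
    StateSpace,
    StockVector,
    headcount_to_fte,
)

TRANSITION_COLUMNS = (
    "sex",
    "age_band",
    "from_location",
    "from_status",
    "to_location",
    "to_status",
)

#: Default bounds for annual percentage-change multipliers.
DEFAULT_MULTIPLIER_RANGE = (-0.10, 0.10)


def classify_move(
    from_location: str, from_status: str, to_location: str, to_status: str
) -> str:
    """Name the kind of an allowed move, or raise :class:`SchemaError`."""
    if from_status in ACTIVE_STATUSES:
        if to_status in ACTIVE_STATUSES:
            if to_location == from_location and to_status != from_status:
                return "status_change"
            if to_location != from_location and to_status == from_status:
                return "relocation"
        elif to_status == "temporary_exit" and to_location == from_location:
            return "to_temporary"
        elif to_status == "permanent_exit" and to_location == from_location:
            return "to_permanent"
    elif from_status == "temporary_exit":
        if to_status in ACTIVE_STATUSES:
            return "return"
        if to_status == "permanent_exit" and to_location == from_location:
            return "to_permanent"
    raise SchemaError(
        "transition not allowed: "
        f"({from_location},{from_status}) -> ({to_location},{to_status})"
    )


class TransitionTable:
    """Annual base transition probabilities on a :class:`StateSpace`.

    Stored as a canonical frame with one row per directed move; rows are
    validated (known labels, allowed move kinds, probabilities in [0,1])
    and sorted so that a table is fully determined by its (id, value)
    content.  The residual 1 - sum(outbound) of each from-state is the
    stay probability; per-from-state outbound sums above one are only
    resolved at simulation time (see :func:`normalize_outflows`).
    """

    def __init__(self, space: StateSpace, frame: pd.DataFrame) -> None:
        missing = [c for c in (*TRANSITION_COLUMNS, "probability") if c not in frame]
        if missing:
            raise SchemaError(f"transition table missing columns {missing}")
        frame = (
            frame.loc[:, [*TRANSITION_COLUMNS, "probability"]]
            .copy()
            .sort_values(list(TRANSITION_COLUMNS))
            .reset_index(drop=True)
        )
        probs = frame["probability"].to_numpy(float)
        if np.any(~np.isfinite(probs)) or np.any(probs < 0) or np.any(probs > 1):
            raise ParameterError("transition probabilities must lie in [0, 1]")
        ids = []
        from_pos = np.empty(len(frame), dtype=np.intp)
        to_pos = np.empty(len(frame), dtype=np.intp)
        for i, row in enumerate(frame.itertuples(index=False)):
            classify_move(row.from_location, row.from_status, row.to_location, row.to_status)
            frm = (row.sex, row.age_band, row.from_location, row.from_status)
            to = (row.sex, row.age_band, row.to_location, row.to_status)
            from_pos[i] = space.position(frm)
            to_pos[i] = space.position(to)
            ids.append(tuple(row)[:6])
        if len(set(ids)) != len(ids):
            raise SchemaError("duplicate transition rows")
        self.space = space
        self.frame = frame
        self.ids: tuple[tuple, ...] = tuple(ids)
        self.from_pos = from_pos
        self.to_pos = to_pos
        self.probabilities = probs

    def __len__(self) -> int:
        return len(self.ids)

    def with_probabilities(self, probs: Sequence[float]) -> "TransitionTable":
        probs = np.asarray(probs, dtype=float)
        if probs.shape != self.probabilities.shape:
            raise ParameterError("probability vector has the wrong length")
        frame = self.frame.copy()
        frame["probability"] = probs
        return TransitionTable(self.space, frame)

    @classmethod
    def from_records(
        cls, space: StateSpace, records: Mapping[tuple, float]
    ) -> "TransitionTable":
        """Build from ``{(sex, age_band, from_loc, from_st, to_loc, to_st): p}``."""
        rows = [(*key, p) for key, p in records.items()]
        frame = pd.DataFrame(rows, columns=[*TRANSITION_COLUMNS, "probability"])
        return cls(space, frame)


@dataclass
class MultiplierSet:
    """Annual percentage-change multipliers aligned to a transition table.

    Each value m shifts its base probability to p*(1+m)^k after k years,
    modelling a steady drift in workforce behaviour.  Values must lie in
    the sampling range (default -10% .. +10% a year).
    """

    values: np.ndarray
    bounds: tuple[float, float] = DEFAULT_MULTIPLIER_RANGE

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        low, high = self.bounds
        if low > high:
            raise ConfigError(f"multiplier bounds reversed: {self.bounds}")
        if np.any(self.values < low - 1e-12) or np.any(self.values > high + 1e-12):
            raise ParameterError(
                f"multipliers outside the allowed range {self.bounds}"
            )

    @classmethod
    def zeros(cls, table: TransitionTable) -> "MultiplierSet":
        return cls(np.zeros(len(table)))

    @classmethod
    def from_mapping(
        cls,
        table: TransitionTable,
        mapping: Mapping[tuple, float],
        default: float = 0.0,
        bounds: tuple[float, float] = DEFAULT_MULTIPLIER_RANGE,
    ) -> "MultiplierSet":
        values = np.array([mapping.get(tid, default) for tid in table.ids])
        return cls(values, bounds=bounds)


@dataclass
class AgingRule:
    """Annual fraction of each age band graduating into the next band.

    The default steady-state approximation moves 1/width of a band per
    year; the terminal open-ended band retains everyone (fraction 0).
    """

    fractions: Mapping[str, float]

    def __post_init__(self) -> None:
        for label, f in self.fractions.items():
            if not 0.0 <= f <= 1.0:
                raise ParameterError(f"aging fraction for {label!r} not in [0,1]")

    @classmethod
    def default_for(cls, bands: Sequence[AgeBand]) -> "AgingRule":
        fractions = {}
        for band in bands:
            fractions[band.label] = 0.0 if band.upper is None else 1.0 / band.width
        # terminal band must be 0 even if closed in a custom space
        fractions[bands[-1].label] = 0.0
        return cls(fractions)

    def fraction(self, label: str) -> float:
        return float(self.fractions.get(label, 0.0))


def effective_probability(p: float, m: float, k: int) -> float:
    """Transition probability after k years of annual drift m.

    Returns ``clamp(p * (1+m)**k, 0, 1)``.
    """
    if not 0.0 <= p <= 1.0:
        raise ParameterError(f"base probability {p} not in [0, 1]")
    if k < 0 or int(k) != k:
        raise ParameterError(f"years since base must be a non-negative integer, got {k}")
    return float(min(max(p * (1.0 + m) ** k, 0.0), 1.0))


def normalize_outflows(probs: Sequence[float], warn: bool = True) -> np.ndarray:
    """Proportionally rescale one state's outbound probabilities if they exceed 1.

    An empty vector (an absorbing state) is returned unchanged; the
    implicit stay probability is then one.
    """
    probs = np.asarray(probs, dtype=float)
    if np.any(probs < 0):
        raise ParameterError("outbound probabilities must be non-negative")
    total = probs.sum()
    if total > 1.0:
        if warn:
            warnings.warn(
                f"outbound probabilities sum to {total:.4f} > 1; rescaled to 1",
                stacklevel=2,
            )
        return probs / total
    return probs


def step_year(
    stock: StockVector,
    table: TransitionTable,
    multipliers: MultiplierSet | None = None,
    entries: EntryStream | None = None,
    aging: AgingRule | None = None,
    k: int = 0,
    warn: bool = True,
) -> StockVector:
    """Advance the stock one calendar year.

    ``k`` is the number of years elapsed since the base year, used to
    compound the multipliers.  Expected flows are computed from the
    start-of-year stock (after entries), so e.g. 100 full-time urban
    male GPs with p(full->part)=0.05 send exactly 5 to part time.
    """
    space = table.space
    if not stock.counts.index.equals(space.index):
        raise SchemaError("stock and transition table use different state spaces")

    s = stock.counts.to_numpy(dtype=float).copy()
    if entries is not None:
        e = entries.entries_for(stock.year)
        if not e.index.equals(space.index):
            raise SchemaError("entry allocation uses a different state space")
        s = s + e.to_numpy(dtype=float)

    m = multipliers.values if multipliers is not None else np.zeros(len(table))
    if len(m) != len(table):
        raise SchemaError("multiplier set not aligned with transition table")
    p_eff = np.clip(table.probabilities * (1.0 + m) ** k, 0.0, 1.0)

    n = space.n_states
    out_sums = np.bincount(table.from_pos, weights=p_eff, minlength=n)
    over = out_sums > 1.0
    if over.any():
        if warn:
            worst = float(out_sums.max())
            warnings.warn(
                f"outbound probabilities exceed 1 for {int(over.sum())} state(s) "
                f"(max {worst:.4f}); rescaled proportionally",
                stacklevel=2,
            )
        scale = np.where(over, 1.0 / np.where(over, out_sums, 1.0), 1.0)
        p_eff = p_eff * scale[table.from_pos]

    flows = s[table.from_pos] * p_eff
    s = (
        s
        - np.bincount(table.from_pos, weights=flows, minlength=n)
        + np.bincount(table.to_pos, weights=flows, minlength=n)
    )

    if aging is not None:
        aged = s.copy()
        for sex in space.sexes:
            for band in space.band_labels:
                nxt = space.next_band(band)
                frac = aging.fraction(band)
                if nxt is None or frac == 0.0:
                    continue
                for loc in space.locations:
                    for status in ("full_time", "part_time", "temporary_exit"):
                        i = space.position((sex, band, loc, status))
                        j = space.position((sex, nxt, loc, status))
                        moved = s[i] * frac
                        aged[i] -= moved
                        aged[j] += moved
        s = aged

    return StockVector(stock.year + 1, pd.Series(s, index=space.index))


@dataclass
class SupplyProjection:
    """Annual stock series produced by :func:`project_supply`."""

    stocks: list[StockVector]
    fte_totals: pd.Series | None = None

    @property
    def years(self) -> list[int]:
        return [s.year for s in self.stocks]

    def headcounts(self) -> pd.DataFrame:
        """Year-by-state headcount frame (rows: years, columns: states)."""
        return pd.DataFrame(
            {s.year: s.counts for s in self.stocks}
        ).T.rename_axis("year")

    def active_totals(self) -> pd.Series:
        return pd.Series(
            {s.year: s.active_total for s in self.stocks}, name="active_headcount"
        ).rename_axis("year")

    def totals(self) -> pd.Series:
        return pd.Series(
            {s.year: s.total for s in self.stocks}, name="total_headcount"
        ).rename_axis("year")

    def stratum_headcounts(self) -> pd.Series:
        """Active headcounts keyed by (year, sex, age_band, location, status)."""
        parts = {s.year: s.active for s in self.stocks}
        level_names = ["year", *self.stocks[0].counts.index.names]
        return pd.concat(parts, names=level_names)


def project_supply(
    stock_base: StockVector,
    table: TransitionTable,
    multipliers: MultiplierSet | None = None,
    entries: EntryStream | None = None,
    aging: AgingRule | None = None,
    horizon: int = 1,
    hours_profile: HoursProfile | None = None,
    warn: bool = True,
) -> SupplyProjection:
    """Iterate :func:`step_year` for ``horizon`` years from the base stock.

    Returns the full series including the base year.  If an hours
    profile is given, an annual total-FTE series is attached.
    """
    if horizon < 1:
        raise ConfigError(f"horizon must be at least 1 year, got {horizon}")
    stocks = [stock_base]
    current = stock_base
    for k in range(horizon):
        current = step_year(
            current, table, multipliers, entries, aging, k=k, warn=warn
        )
        stocks.append(current)
    fte = None
    if hours_profile is not None:
        fte = pd.Series(
            {s.year: headcount_to_fte(s, hours_profile)[0] for s in stocks},
            name="fte",
        ).rename_axis("year")
    return SupplyProjection(stocks=stocks, fte_totals=fte)
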