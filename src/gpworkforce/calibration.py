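"""Accept-reject calibration of the supply model against observed stocks.

Candidate parameter sets (base transition probabilities from beta
priors, annual-change multipliers from uniform priors) are sampled,
the cohort model is projected over the observation window, and every
candidate whose predictions deviate from the smoothed observed stock by
less than the tolerance (default 5%) *at every target* is retained.
Retaining all convergent sets, rather than a single best fit, preserves
the joint uncertainty of the inputs for later sensitivity analysis.

Observed series are smoothed with a per-stratum ordinary-least-squares
linear trend before comparison, absorbing definitional breaks in the
survey series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ConfigError, ParameterError, SchemaError
from .states import ACTIVE_STATUSES, EntryStream, StateSpace, StockVector
from .supply import (
    TRANSITION_COLUMNS,
    AgingRule,
    MultiplierSet,
    TransitionTable,
    project_supply,
)

PRIOR_COLUMNS = (*TRANSITION_COLUMNS, "alpha", "beta", "mult_low", "mult_high")
TARGET_LEVELS = ("year", "sex", "age_band", "location", "status")


class PriorSpec:
    """Per-transition priors: Beta(alpha, beta) base probability and a
    uniform multiplier range (default -10% .. +10% per year)."""

    def __init__(self, space: StateSpace, frame: pd.DataFrame) -> None:
        missing = [c for c in PRIOR_COLUMNS if c not in frame]
        if missing:
            raise SchemaError(f"prior table missing columns {missing}")
        frame = (
            frame.loc[:, list(PRIOR_COLUMNS)]
            .copy()
            .sort_values(list(TRANSITION_COLUMNS))
            .reset_index(drop=True)
        )
        if (frame["alpha"] <= 0).any() or (frame["beta"] <= 0).any():
            raise ConfigError("beta shape parameters must be positive")
        if (frame["mult_low"] > frame["mult_high"]).any():
            raise ConfigError("multiplier range has low > high")
        # validate the transition structure by building a table once
        self._template = TransitionTable(
            space, frame.assign(probability=0.0)[[*TRANSITION_COLUMNS, "probability"]]
        )
        self.space = space
        self.frame = frame

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def ids(self) -> tuple[tuple, ...]:
        return self._template.ids

    @classmethod
    def centred_on(
        cls,
        table: TransitionTable,
        concentration: float = 2000.0,
        mult_range: tuple[float, float] = (-0.10, 0.10),
    ) -> "PriorSpec":
        """Priors whose beta means equal the probabilities of ``table``.

        ``concentration`` is alpha+beta; larger means tighter priors.
        Zero-probability transitions get a near-degenerate prior.
        """
        p = np.clip(table.probabilities, 1e-6, 1 - 1e-6)
        frame = table.frame[list(TRANSITION_COLUMNS)].copy()
        frame["alpha"] = p * concentration
        frame["beta"] = (1 - p) * concentration
        frame["mult_low"] = mult_range[0]
        frame["mult_high"] = mult_range[1]
        return cls(table.space, frame)


@dataclass
class ParameterSet:
    """One sampled candidate: base probabilities plus multipliers."""

    table: TransitionTable
    multipliers: MultiplierSet
    seed: int | None = None
    convergent: bool | None = None
    deviations: pd.Series | None = None
    max_deviation: float | None = None
    summed_abs_deviation: float | None = None

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "convergent": self.convergent,
            "max_deviation": self.max_deviation,
            "summed_abs_deviation": self.summed_abs_deviation,
            "probabilities": {
                "|".join(map(str, tid)): float(p)
                for tid, p in zip(self.table.ids, self.table.probabilities)
            },
            "multipliers": {
                "|".join(map(str, tid)): float(m)
                for tid, m in zip(self.table.ids, self.multipliers.values)
            },
        }


def sample_parameter_set(
    priors: PriorSpec, seed: int | np.random.Generator
) -> ParameterSet:
    """Draw one candidate from the priors; reproducible given the seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    alpha = priors.frame["alpha"].to_numpy(float)
    beta = priors.frame["beta"].to_numpy(float)
    low = priors.frame["mult_low"].to_numpy(float)
    high = priors.frame["mult_high"].to_numpy(float)
    probs = rng.beta(alpha, beta)
    mults = rng.uniform(low, high)
    table = priors._template.with_probabilities(probs)
    bounds = (float(low.min()), float(high.max()))
    return ParameterSet(
        table=table,
        multipliers=MultiplierSet(mults, bounds=bounds),
        seed=None if isinstance(seed, np.random.Generator) else int(seed),
    )


@dataclass
class CalibrationTargetSet:
    """Observed stock series per stratum, with its smoothed counterpart."""

    observed: pd.Series
    _smoothed: pd.Series | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if list(self.observed.index.names) != list(TARGET_LEVELS):
            raise SchemaError(
                f"targets must be indexed by {TARGET_LEVELS}, "
                f"got {tuple(self.observed.index.names)}"
            )

    @property
    def years(self) -> list[int]:
        return sorted(set(self.observed.index.get_level_values("year")))

    @property
    def smoothed(self) -> pd.Series:
        if self._smoothed is None:
            self._smoothed = smooth_targets(self.observed)
        return self._smoothed

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CalibrationTargetSet":
        obs = frame.set_index(list(TARGET_LEVELS))["headcount"].astype(float)
        return cls(observed=obs)


def smooth_targets(observed: pd.Series) -> pd.Series:
    """Replace each stratum's series by its OLS linear-trend fitted values.

    Requires at least two observations per stratum; a flat series maps
    to itself and an exactly linear series is reproduced exactly.
    """
    if "year" not in (observed.index.names or ()):
        raise SchemaError("observed series must carry a 'year' index level")
    strata = [n for n in observed.index.names if n != "year"]
    out = observed.copy().astype(float)
    grouped = observed.groupby(level=strata) if strata else [(None, observed)]
    for _, series in grouped:
        years = series.index.get_level_values("year").to_numpy(float)
        values = series.to_numpy(float)
        if len(series) < 2:
            raise ConfigError(
                "smoothing needs at least 2 observations per stratum; "
                "use the raw value directly for single-year targets"
            )
        slope, intercept = np.polyfit(years, values, deg=1)
        out.loc[series.index] = intercept + slope * years
    return out


@dataclass
class DeviationReport:
    """Per-target percent deviations of predictions from smoothed targets."""

    percent: pd.Series
    convergent: bool
    max_deviation: float
    summed_abs_deviation: float
    n_excluded: int = 0


def deviation(
    predicted: pd.Series, smoothed: pd.Series, tolerance: float = 0.05
) -> DeviationReport:
    """Percent deviation per target and the all-targets convergence flag.

    A candidate is convergent iff |predicted - smoothed| / smoothed is
    below ``tolerance`` at every target.  Targets with a zero smoothed
    value carry no relative information and are excluded with a warning.
    Also reports the summed absolute headcount deviation over all targets.
    """
    predicted = predicted.astype(float)
    smoothed = smoothed.astype(float)
    if not predicted.index.sort_values().equals(smoothed.index.sort_values()):
        raise SchemaError("predicted and smoothed series have different target keys")
    smoothed = smoothed.reindex(predicted.index)
    zero = smoothed == 0.0
    n_excluded = int(zero.sum())
    if n_excluded:
        warnings.warn(
            f"{n_excluded} target(s) with zero smoothed value excluded from "
            "percent deviations",
            stacklevel=2,
        )
    abs_dev = (predicted - smoothed).abs()
    pct = abs_dev[~zero] / smoothed[~zero]
    convergent = bool((pct < tolerance).all())
    return DeviationReport(
        percent=pct,
        convergent=convergent,
        max_deviation=float(pct.max()) if len(pct) else 0.0,
        summed_abs_deviation=float(abs_dev.sum()),
        n_excluded=n_excluded,
    )


@dataclass
class CalibrationResult:
    accepted: list[ParameterSet]
    best: ParameterSet | None
    n_samples: int
    tolerance: float

    @property
    def n_accepted(self) -> int:
        return len(self.accepted)


def _predict_targets(
    params: ParameterSet,
    base_stock: StockVector,
    entries: EntryStream | None,
    aging: AgingRule | None,
    target_index: pd.Index,
    horizon: int,
) -> pd.Series:
    projection = project_supply(
        base_stock,
        params.table,
        params.multipliers,
        entries,
        aging,
        horizon=horizon,
        warn=False,
    )
    per_stratum = projection.stratum_headcounts()
    try:
        return per_stratum.loc[target_index]
    except KeyError as exc:
        raise SchemaError(f"calibration target not in model state space: {exc}") from exc


def calibrate(
    priors: PriorSpec,
    targets: CalibrationTargetSet,
    base_stock: StockVector,
    entries: EntryStream | None = None,
    aging: AgingRule | None = None,
    n_samples: int = 1000,
    seed: int = 0,
    tolerance: float = 0.05,
    extra_candidates: Iterable[ParameterSet] = (),
) -> CalibrationResult:
    """Sample candidates, project each, and retain all convergent sets.

    Deterministic given (priors, targets, n_samples, seed).  If no
    candidate converges, the result is empty but ``best`` still holds
    the minimum-max-deviation candidate as a diagnostic.
    ``extra_candidates`` lets callers force known parameter sets (e.g. a
    synthetic truth) into the evaluated pool ahead of the sampled ones.
    """
    if n_samples < 1:
        raise ConfigError("n_samples must be at least 1")
    years = targets.years
    horizon = max(years) - base_stock.year
    if horizon < 1:
        raise ConfigError(
            f"targets end in {max(years)} which is not after base year {base_stock.year}"
        )
    smoothed = targets.smoothed
    target_index = smoothed.index

    root = np.random.SeedSequence(seed)
    children = root.spawn(n_samples)

    accepted: list[ParameterSet] = []
    best: ParameterSet | None = None
    candidates: list[ParameterSet] = list(extra_candidates)
    for i, child in enumerate(children):
        ps = sample_parameter_set(priors, np.random.default_rng(child))
        ps.seed = i
        candidates.append(ps)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-target warnings repeat per candidate
        for ps in candidates:
            predicted = _predict_targets(
                ps, base_stock, entries, aging, target_index, horizon
            )
            report = deviation(predicted, smoothed, tolerance=tolerance)
            ps.convergent = report.convergent
            ps.deviations = report.percent
            ps.max_deviation = report.max_deviation
            ps.summed_abs_deviation = report.summed_abs_deviation
            if report.convergent:
                accepted.append(ps)
            if best is None or ps.max_deviation < best.max_deviation:
                best = ps

    return CalibrationResult(
        accepted=accepted, best=best, n_samples=n_samples, tolerance=tolerance
    )
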