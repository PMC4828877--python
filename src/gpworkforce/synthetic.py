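"""Internally consistent synthetic fixtures with known ground truth.

Every input table the pipeline consumes can be generated here, so the
whole package is testable without any external workforce or burden
data.  Supply fixtures embed a known-truth transition parameter set and
derive the observed calibration targets from it (optionally with
multiplicative lognormal noise); need fixtures are built forward from a
known service profile so the base-year fit recovers it exactly.

Fixtures are structural stand-ins: they mirror the shape of the real
data landscape (workforce survey stocks, burden-of-disease cases,
problem-management shares, claimed attendances, population projections)
without being epidemiologically calibrated to any jurisdiction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .calibration import CalibrationTargetSet, ParameterSet, PriorSpec
from .errors import ConfigError
from .need import (
    BurdenTable,
    ConditionMix,
    PopulationProjection,
    ServiceProfile,
)
from .states import (
    ACTIVE_STATUSES,
    AgeBand,
    EntryStream,
    HoursProfile,
    StateSpace,
    StockVector,
)
from .supply import (
    AgingRule,
    MultiplierSet,
    TransitionTable,
    project_supply,
    step_year,
)

TOY_AGE_BANDS = (AgeBand("lt45", 25, 44), AgeBand("45plus", 45, None))

#: Chapter vocabulary shaped like the ICPC-2 chapter headings under
#: which managed problems are classified in primary-care activity data.
PAPER_LIKE_CHAPTERS = (
    "general_unspecified",
    "blood_immune",
    "digestive",
    "eye",
    "ear",
    "circulatory",
    "musculoskeletal",
    "neurological",
    "psychological",
    "respiratory",
    "skin",
    "endocrine_metabolic",
    "urological",
    "pregnancy_family_planning",
    "female_genital",
    "male_genital",
    "infections",
)
TOY_CHAPTERS = ("respiratory", "circulatory", "musculoskeletal")


@dataclass
class FixtureConfig:
    """Everything a fixture build depends on; the seed fixes it all.

    Defaults describe the study conditions the package is validated
    under: a 2004 supply base year observed through 2011 (seven annual
    cycles), a 2003 need base year projected through 2013, entry streams
    of 42 graduates and 47 in-migrants a year, and an accept-reject
    tolerance window served by beta priors centred on the truth.
    """

    seed: int = 0
    sexes: tuple[str, ...] = ("male", "female")
    age_bands: tuple[AgeBand, ...] = TOY_AGE_BANDS
    locations: tuple[str, ...] = ("urban",)
    chapters: tuple[str, ...] = TOY_CHAPTERS

    supply_base_year: int = 2004
    supply_horizon: int = 7
    need_base_year: int = 2003
    need_horizon: int = 10

    total_active_stock: float = 1789.0
    graduates: float = 42.0
    in_migrants: float = 47.0
    temp_return_prob: float = 0.5

    target_noise: float = 0.0
    burn_in_years: int = 10
    prior_concentration: float = 2000.0
    mult_range: tuple[float, float] = (-0.10, 0.10)
    true_mult_scale: float = 0.02

    total_population: float = 1_529_424.0
    population_growth: float = 1.01
    prevent_admin_per_capita: float = 1.5

    full_time_hours: float = 40.0
    part_time_hours: float = 20.0


def toy_config(seed: int = 0, **overrides) -> FixtureConfig:
    """Reduced 2 sexes x 2 bands x 1 location space for oracle tests."""
    return replace(FixtureConfig(seed=seed), **overrides)


def paper_like_config(seed: int = 0, **overrides) -> FixtureConfig:
    """Full 2 x 5 x 2 x 2 state space and 17-chapter vocabulary."""
    from .states import DEFAULT_AGE_BANDS

    cfg = FixtureConfig(
        seed=seed,
        age_bands=DEFAULT_AGE_BANDS,
        locations=("urban", "rural"),
        chapters=PAPER_LIKE_CHAPTERS,
    )
    return replace(cfg, **overrides)


def _age_shares(n: int) -> np.ndarray:
    # hump-shaped age profile, oldest band smallest
    raw = np.array([0.18, 0.26, 0.25, 0.19, 0.12][:n], dtype=float)
    if len(raw) < n:
        raw = np.linspace(1.5, 0.8, n)
    return raw / raw.sum()


def _true_transition_records(cfg: FixtureConfig, space: StateSpace) -> dict:
    """Deterministic, demographically graded truth probabilities.

    Permanent-exit rates are anchored to the midpoint age of each band
    (a band aggregating 45+ is dominated by its low-exit younger ages,
    so it gets a mid-50s rate, not the 65+ rate).
    """
    midpoints = [
        b.lower + 10 if b.upper is None else (b.lower + b.upper) / 2
        for b in space.age_bands
    ]
    perm_by_band = np.interp(
        midpoints, [30, 40, 50, 60, 70], [0.005, 0.010, 0.020, 0.050, 0.120]
    )
    records: dict[tuple, float] = {}
    for sex in space.sexes:
        for bi, band in enumerate(space.band_labels):
            for loc in space.locations:
                # participation moves
                ft_pt = 0.07 if sex == "female" else 0.05
                records[(sex, band, loc, "full_time", loc, "part_time")] = ft_pt
                records[(sex, band, loc, "part_time", loc, "full_time")] = 0.03
                # mobility between locations
                for other in space.locations:
                    if other == loc:
                        continue
                    rate = 0.02 if loc == "rural" else 0.01
                    for status in ACTIVE_STATUSES:
                        records[(sex, band, loc, status, other, status)] = rate
                # exits
                temp = 0.04 if (sex == "female" and bi < 2) else 0.02
                for status in ACTIVE_STATUSES:
                    records[(sex, band, loc, status, loc, "temporary_exit")] = temp
                    records[(sex, band, loc, status, loc, "permanent_exit")] = float(
                        perm_by_band[bi]
                    )
                # re-entry from temporary exit, split full/part
                records[(sex, band, loc, "temporary_exit", loc, "full_time")] = (
                    0.6 * cfg.temp_return_prob
                )
                records[(sex, band, loc, "temporary_exit", loc, "part_time")] = (
                    0.4 * cfg.temp_return_prob
                )
                records[(sex, band, loc, "temporary_exit", loc, "permanent_exit")] = 0.05
    return records


def _base_stock(cfg: FixtureConfig, space: StateSpace) -> StockVector:
    age = dict(zip(space.band_labels, _age_shares(len(space.band_labels))))
    loc_share = (
        {space.locations[0]: 1.0}
        if len(space.locations) == 1
        else {"urban": 0.72, "rural": 0.28}
    )
    status_share = {"full_time": 0.62, "part_time": 0.38}
    counts = space.empty()
    for sex in space.sexes:
        for band in space.band_labels:
            for loc in space.locations:
                for status in ACTIVE_STATUSES:
                    counts.loc[(sex, band, loc, status)] = (
                        cfg.total_active_stock
                        * 0.5
                        * age[band]
                        * loc_share.get(loc, 1.0 / len(space.locations))
                        * status_share[status]
                    )
                # a small standing pool of temporary exits
                counts.loc[(sex, band, loc, "temporary_exit")] = (
                    cfg.total_active_stock
                    * 0.5
                    * age[band]
                    * loc_share.get(loc, 1.0 / len(space.locations))
                    * 0.03
                )
    return StockVector(cfg.supply_base_year, counts)


def _entry_stream(cfg: FixtureConfig, space: StateSpace, base: StockVector) -> EntryStream:
    active = base.active
    # graduates: 70/30 into the two youngest bands, spread within each
    # band by the base stock's own location/status mix
    band_weights = (
        {space.band_labels[0]: 1.0}
        if len(space.band_labels) == 1
        else {space.band_labels[0]: 0.7, space.band_labels[1]: 0.3}
    )
    grad = space.empty()
    for band, w in band_weights.items():
        in_band = active.xs(band, level="age_band", drop_level=False)
        share = in_band / in_band.sum()
        for state, frac in share.items():
            grad.loc[state] += w * frac
    # in-migrants follow the full joint distribution of the active stock
    mig = space.empty()
    mig.loc[active.index] = (active / active.sum()).to_numpy()
    return EntryStream(
        graduates=cfg.graduates,
        in_migrants=cfg.in_migrants,
        graduate_allocation=grad,
        migrant_allocation=mig,
    )


@dataclass
class SupplyFixture:
    """Known-truth supply world: model inputs plus calibration targets."""

    config: FixtureConfig
    space: StateSpace
    base_stock: StockVector
    truth: ParameterSet
    entries: EntryStream
    aging: AgingRule
    hours: HoursProfile
    priors: PriorSpec
    targets: CalibrationTargetSet
    truth_targets: pd.Series = field(repr=False)


def gen_supply_fixture(cfg: FixtureConfig) -> SupplyFixture:
    """Build the supply world and its (optionally noisy) observed targets.

    The seed stock is burned in under the truth base probabilities for
    ``burn_in_years`` before being rescaled to the configured active
    total: an observed workforce sits near the quasi-stationary profile
    of its own dynamics, and starting the observation window there keeps
    the target series free of artificial transients.
    """
    if cfg.target_noise < 0:
        raise ConfigError("target noise must be non-negative")
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 11)))
    space = StateSpace(cfg.sexes, cfg.age_bands, cfg.locations)
    base = _base_stock(cfg, space)
    table = TransitionTable.from_records(space, _true_transition_records(cfg, space))
    mults = MultiplierSet(
        rng.uniform(-cfg.true_mult_scale, cfg.true_mult_scale, size=len(table)),
        bounds=cfg.mult_range,
    )
    truth = ParameterSet(table=table, multipliers=mults, seed=None)
    entries = _entry_stream(cfg, space, base)
    aging = AgingRule.default_for(space.age_bands)

    if cfg.burn_in_years > 0:
        settled = base
        for _ in range(cfg.burn_in_years):
            settled = step_year(settled, table, None, entries, aging, k=0, warn=False)
        counts = settled.counts.copy()
        counts[space.permanent_mask] = 0.0
        scale = cfg.total_active_stock / counts[space.active_mask].sum()
        base = StockVector(cfg.supply_base_year, counts * scale)
        entries = _entry_stream(cfg, space, base)
    hours = HoursProfile.from_status_means(cfg.full_time_hours, cfg.part_time_hours)

    projection = project_supply(
        base, table, mults, entries, aging, horizon=cfg.supply_horizon, warn=False
    )
    truth_targets = projection.stratum_headcounts()
    observed = truth_targets.copy()
    if cfg.target_noise > 0:
        noise = np.exp(rng.normal(0.0, cfg.target_noise, size=len(observed)))
        observed = observed * noise

    priors = PriorSpec.centred_on(
        table, concentration=cfg.prior_concentration, mult_range=cfg.mult_range
    )
    return SupplyFixture(
        config=cfg,
        space=space,
        base_stock=base,
        truth=truth,
        entries=entries,
        aging=aging,
        hours=hours,
        priors=priors,
        targets=CalibrationTargetSet(observed=observed),
        truth_targets=truth_targets,
    )


@dataclass
class NeedFixture:
    """Known-truth demand world built forward from a service profile."""

    config: FixtureConfig
    population: PopulationProjection
    burden: BurdenTable
    mix: ConditionMix
    attendances: pd.Series  # base-year consultations by (sex, age_band)
    lengths: pd.Series
    truth: ServiceProfile
    mapping: pd.DataFrame  # source burden category -> chapter
    hours: HoursProfile


def gen_need_fixture(cfg: FixtureConfig) -> NeedFixture:
    """Population, burden, mix, lengths and attendances with exact closure.

    Attendances are computed forward from the true per-case rates and
    prevent/admin rates, and the condition-mix shares are derived from
    the same arithmetic, so chapter shares plus the prevent/admin share
    sum to exactly one per cell and the base-year fit round-trips.
    """
    bands = tuple(b.label for b in cfg.age_bands)
    cells = pd.MultiIndex.from_product([cfg.sexes, bands], names=("sex", "age_band"))
    chap_index = pd.MultiIndex.from_product(
        [cfg.chapters, cfg.sexes, bands], names=("chapter", "sex", "age_band")
    )

    # population: fixed cell shares at base, uniform annual growth
    age = _age_population_shares(len(bands))
    base_cell = pd.Series(
        [
            cfg.total_population * 0.5 * age[bands.index(b)]
            for (_s, b) in cells
        ],
        index=cells,
    )
    years = range(cfg.need_base_year, cfg.need_base_year + cfg.need_horizon + 1)
    pop_rows = {}
    for year in years:
        k = year - cfg.need_base_year
        pop_rows[year] = base_cell * cfg.population_growth**k
    persons = pd.concat(pop_rows, names=["year", "sex", "age_band"])
    population = PopulationProjection(persons=persons)

    # burden: per-capita case rates graded by chapter and age
    rates = []
    for ch, sex, band in chap_index:
        ci = cfg.chapters.index(ch)
        bi = bands.index(band)
        rate = 0.015 + 0.012 * (ci % 5) + 0.02 * bi + (0.004 if sex == "female" else 0)
        rates.append(rate)
    case_rate = pd.Series(rates, index=chap_index)
    cell_persons = base_cell.reindex(
        pd.MultiIndex.from_arrays(
            [chap_index.get_level_values("sex"), chap_index.get_level_values("age_band")],
            names=("sex", "age_band"),
        )
    )
    cases = case_rate * cell_persons.to_numpy()
    burden = BurdenTable(incident=0.3 * cases, prevalent=0.7 * cases)

    # true service norms
    per_case_vals = []
    for ch, sex, band in chap_index:
        ci = cfg.chapters.index(ch)
        bi = bands.index(band)
        v = 0.8 + 0.4 * (ci % 4) + 0.15 * bi + (0.1 if sex == "female" else 0.0)
        per_case_vals.append(v)
    per_case = pd.Series(per_case_vals, index=chap_index)
    pa_rate = pd.Series(
        [
            cfg.prevent_admin_per_capita * (1.0 + 0.05 * bands.index(b))
            for (_s, b) in cells
        ],
        index=cells,
    )
    lengths = pd.Series(
        [14.0 + 0.6 * bands.index(b) + (1.0 if s == "female" else 0.0) for (s, b) in cells],
        index=cells,
    )
    truth = ServiceProfile(
        per_case=per_case, prevent_admin_per_capita=pa_rate, length_minutes=lengths
    )

    # forward attendances and the implied condition mix
    chapter_consults = per_case * cases
    by_cell = chapter_consults.groupby(level=["sex", "age_band"]).sum().reindex(cells)
    pa_consults = pa_rate * base_cell
    attendances = by_cell + pa_consults
    att_aligned = attendances.reindex(cell_persons.index)
    proportion = pd.Series(
        chapter_consults.to_numpy() / att_aligned.to_numpy(), index=chap_index
    )
    pa_share = pa_consults / attendances
    mix = ConditionMix(proportion=proportion, prevent_admin_share=pa_share)

    mapping = pd.DataFrame(
        {
            "source_category": [f"icd_group_{i:02d}" for i in range(len(cfg.chapters))],
            "icpc2_chapter": list(cfg.chapters),
        }
    )
    hours = HoursProfile.from_status_means(cfg.full_time_hours, cfg.part_time_hours)
    return NeedFixture(
        config=cfg,
        population=population,
        burden=burden,
        mix=mix,
        attendances=attendances,
        lengths=lengths,
        truth=truth,
        mapping=mapping,
        hours=hours,
    )


def _age_population_shares(n: int) -> np.ndarray:
    raw = np.array([0.28, 0.24, 0.20, 0.16, 0.12][:n], dtype=float)
    if len(raw) < n:
        raw = np.linspace(1.5, 0.8, n)
    return raw / raw.sum()
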