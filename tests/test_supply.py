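"""Cohort step mechanics: effective probabilities, flows, conservation."""

import numpy as np
import pandas as pd
import pytest

import gpworkforce as g
from gpworkforce.errors import ParameterError, SchemaError
from gpworkforce.supply import classify_move

from .oracles import oracle_step, random_stock, random_transition_records


class TestEffectiveProbability:
    @pytest.mark.parametrize(
        "p,m,k,expected",
        [
            (0.05, 0.0, 5, 0.05),
            (0.05, 0.10, 2, 0.0605),
            (0.95, 0.10, 10, 1.0),  # clamped at 1
            (0.05, -0.10, 1, 0.045),
        ],
    )
    def test_compounding_with_clamp(self, p, m, k, expected):
        assert g.effective_probability(p, m, k) == pytest.approx(expected, rel=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ParameterError):
            g.effective_probability(1.2, 0.0, 1)
        with pytest.raises(ParameterError):
            g.effective_probability(0.5, 0.0, -1)


class TestNormalizeOutflows:
    def test_sums_below_one_unchanged(self):
        out = g.normalize_outflows([0.2, 0.3])
        assert out.tolist() == [0.2, 0.3]

    def test_proportional_rescale_above_one(self):
        with pytest.warns(UserWarning):
            out = g.normalize_outflows([0.8, 0.6])
        assert out.sum() == pytest.approx(1.0)
        assert out[0] / out[1] == pytest.approx(0.8 / 0.6)

    def test_empty_is_absorbing(self):
        assert g.normalize_outflows([]).size == 0

    def test_negative_rejected(self):
        with pytest.raises(ParameterError):
            g.normalize_outflows([-0.1, 0.5])


class TestMoveClassification:
    @pytest.mark.parametrize(
        "move,kind",
        [
            (("urban", "full_time", "urban", "part_time"), "status_change"),
            (("urban", "full_time", "rural", "full_time"), "relocation"),
            (("urban", "full_time", "urban", "temporary_exit"), "to_temporary"),
            (("urban", "temporary_exit", "urban", "part_time"), "return"),
            (("urban", "temporary_exit", "urban", "permanent_exit"), "to_permanent"),
        ],
    )
    def test_allowed_moves(self, move, kind):
        assert classify_move(*move) == kind

    @pytest.mark.parametrize(
        "move",
        [
            ("urban", "permanent_exit", "urban", "full_time"),  # absorbing
            ("urban", "full_time", "rural", "part_time"),  # two attributes at once
            ("urban", "full_time", "rural", "temporary_exit"),
        ],
    )
    def test_disallowed_moves_rejected(self, move):
        with pytest.raises(SchemaError):
            classify_move(*move)


def _stock_with(space, state, count, year=2004):
    counts = space.empty()
    counts.loc[state] = count
    return g.StockVector(year, counts)


class TestStepYear:
    def test_worked_flow_example(self, single_stratum_space):
        """100 full-time urban male GPs with p(full->part)=0.05 send 5."""
        space = single_stratum_space
        stock = _stock_with(space, ("male", "lt45", "urban", "full_time"), 100.0)
        table = g.TransitionTable.from_records(
            space, {("male", "lt45", "urban", "full_time", "urban", "part_time"): 0.05}
        )
        nxt = g.step_year(stock, table)
        assert nxt.counts.loc[("male", "lt45", "urban", "part_time")] == pytest.approx(5.0)
        assert nxt.counts.loc[("male", "lt45", "urban", "full_time")] == pytest.approx(95.0)
        assert nxt.year == 2005

    def test_zero_dynamics_is_identity(self, toy_supply):
        table = toy_supply.truth.table.with_probabilities(
            np.zeros(len(toy_supply.truth.table))
        )
        aging = g.AgingRule(fractions={b: 0.0 for b in toy_supply.space.band_labels})
        nxt = g.step_year(toy_supply.base_stock, table, aging=aging)
        pd.testing.assert_series_equal(nxt.counts, toy_supply.base_stock.counts)

    def test_mismatched_state_space_rejected(self, toy_supply, single_stratum_space):
        stock = _stock_with(single_stratum_space, ("male", "lt45", "urban", "full_time"), 1.0)
        with pytest.raises(SchemaError):
            g.step_year(stock, toy_supply.truth.table)

    def test_conservation_with_entries(self, toy_supply):
        fix = toy_supply
        nxt = g.step_year(
            fix.base_stock, fix.truth.table, fix.truth.multipliers, fix.entries, fix.aging, k=0
        )
        entered = fix.entries.entries_for(fix.base_stock.year).sum()
        assert nxt.total == pytest.approx(fix.base_stock.total + entered, rel=1e-12)

    def test_matches_brute_force_on_toy_space(self, toy_supply):
        """Vectorised step equals explicit flow enumeration, 50 random trials."""
        fix = toy_supply
        space = fix.space
        rng = np.random.default_rng(7)
        aging_moves = [
            (b, space.next_band(b), fix.aging.fraction(b)) for b in space.band_labels
        ]
        for trial in range(50):
            records = random_transition_records(space, rng)
            table = g.TransitionTable.from_records(space, records)
            mults = {tid: rng.uniform(-0.1, 0.1) for tid in table.ids}
            mset = g.MultiplierSet.from_mapping(table, mults)
            stock = g.StockVector(2004, random_stock(space, rng))
            k = int(rng.integers(0, 6))
            got = g.step_year(stock, table, mset, fix.entries, fix.aging, k=k, warn=False)
            mult_by_id = dict(zip(table.ids, mset.values))
            oracle_records = [
                (
                    (tid[0], tid[1], tid[2], tid[3]),
                    (tid[0], tid[1], tid[4], tid[5]),
                    records[tid],
                    mult_by_id[tid],
                )
                for tid in table.ids
            ]
            expected = oracle_step(
                stock.counts.to_dict(),
                oracle_records,
                k,
                entries=fix.entries.entries_for(2004).to_dict(),
                aging=aging_moves,
            )
            for state in space.index:
                assert got.counts.loc[state] == pytest.approx(
                    expected[state], rel=1e-9, abs=1e-9
                ), (trial, state)

    def test_raising_permanent_exit_never_raises_active_headcount(self, toy_supply):
        fix = toy_supply
        table = fix.truth.table
        probs = table.probabilities.copy()
        bumped = probs.copy()
        for i, tid in enumerate(table.ids):
            if tid[5] == "permanent_exit" and tid[3] == "full_time":
                bumped[i] = min(probs[i] + 0.05, 1.0)
        low = g.project_supply(
            fix.base_stock, table.with_probabilities(probs), fix.truth.multipliers,
            fix.entries, fix.aging, horizon=7,
        ).active_totals()
        high = g.project_supply(
            fix.base_stock, table.with_probabilities(bumped), fix.truth.multipliers,
            fix.entries, fix.aging, horizon=7,
        ).active_totals()
        assert (high <= low + 1e-9).all()


class TestProjectSupply:
    def test_horizon_one_equals_single_step(self, toy_supply):
        fix = toy_supply
        proj = g.project_supply(
            fix.base_stock, fix.truth.table, fix.truth.multipliers,
            fix.entries, fix.aging, horizon=1,
        )
        step = g.step_year(
            fix.base_stock, fix.truth.table, fix.truth.multipliers,
            fix.entries, fix.aging, k=0,
        )
        pd.testing.assert_series_equal(proj.stocks[1].counts, step.counts)

    def test_zero_dynamics_grows_by_entries_linearly(self, toy_supply):
        fix = toy_supply
        table = fix.truth.table.with_probabilities(np.zeros(len(fix.truth.table)))
        aging = g.AgingRule(fractions={b: 0.0 for b in fix.space.band_labels})
        h = 5
        proj = g.project_supply(fix.base_stock, table, None, fix.entries, aging, horizon=h)
        per_year = fix.entries.entries_for(fix.base_stock.year).sum()
        assert proj.totals().iloc[-1] == pytest.approx(
            fix.base_stock.total + h * per_year, rel=1e-12
        )

    def test_temporary_exits_can_reenter_but_supply_no_fte(self, single_stratum_space):
        space = single_stratum_space
        stock = _stock_with(space, ("male", "lt45", "urban", "temporary_exit"), 10.0)
        profile = g.HoursProfile.from_status_means()
        assert g.headcount_to_fte(stock, profile)[0] == 0.0
        table = g.TransitionTable.from_records(
            space, {("male", "lt45", "urban", "temporary_exit", "urban", "full_time"): 0.5}
        )
        nxt = g.step_year(stock, table)
        assert nxt.counts.loc[("male", "lt45", "urban", "full_time")] == pytest.approx(5.0)
        assert g.headcount_to_fte(nxt, profile)[0] == pytest.approx(5.0)

    def test_trajectory_regression_toy_seed1(self, toy_supply):
        """Frozen golden values from the oracle-verified first run."""
        fix = toy_supply
        proj = g.project_supply(
            fix.base_stock, fix.truth.table, fix.truth.multipliers,
            fix.entries, fix.aging, horizon=7,
        )
        totals = proj.active_totals()
        # frozen from the first run verified against the brute-force oracle
        golden = {
            2004: 1789.0,
            2005: 1824.247111,
            2006: 1857.90211,
            2007: 1890.237344,
            2008: 1921.38271,
            2009: 1951.409251,
            2010: 1980.363334,
            2011: 2008.280693,
        }
        for year, value in golden.items():
            assert totals.loc[year] == pytest.approx(value, abs=5e-6)
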