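"""Prior sampling, trend smoothing, deviation rule and accept-reject search."""

import numpy as np
import pandas as pd
import pytest

import gpworkforce as g
from gpworkforce.calibration import TARGET_LEVELS
from gpworkforce.errors import ConfigError, SchemaError

from .oracles import ols_line


class TestSampleParameterSet:
    def test_concentrated_beta_draws_near_mean(self, toy_supply):
        priors = g.PriorSpec(
            toy_supply.space,
            toy_supply.priors.frame.assign(alpha=1e6, beta=1e6),
        )
        ps = g.sample_parameter_set(priors, seed=0)
        assert np.allclose(ps.table.probabilities, 0.5, atol=1e-2)

    def test_fixed_seed_is_reproducible(self, toy_supply):
        a = g.sample_parameter_set(toy_supply.priors, seed=123)
        b = g.sample_parameter_set(toy_supply.priors, seed=123)
        assert np.array_equal(a.table.probabilities, b.table.probabilities)
        assert np.array_equal(a.multipliers.values, b.multipliers.values)

    def test_beta_sample_mean_matches_moment(self, toy_supply):
        """10 000 draws from Beta(2,38) average to 0.05 within 3 SE."""
        frame = toy_supply.priors.frame.copy()
        frame["alpha"] = 2.0
        frame["beta"] = 38.0
        priors = g.PriorSpec(toy_supply.space, frame)
        rng = np.random.default_rng(5)
        n = 10_000 // len(frame) + 1
        draws = np.concatenate(
            [g.sample_parameter_set(priors, rng).table.probabilities for _ in range(n)]
        )[:10_000]
        mean = 2.0 / 40.0
        sd = np.sqrt(mean * (1 - mean) / 41.0)
        se = sd / np.sqrt(10_000)
        assert abs(draws.mean() - mean) < 3 * se

    def test_multipliers_respect_prior_range(self, toy_supply):
        ps = g.sample_parameter_set(toy_supply.priors, seed=9)
        assert (ps.multipliers.values >= -0.10).all()
        assert (ps.multipliers.values <= 0.10).all()

    def test_invalid_shapes_rejected(self, toy_supply):
        frame = toy_supply.priors.frame.copy()
        frame.loc[0, "alpha"] = 0.0
        with pytest.raises(ConfigError):
            g.PriorSpec(toy_supply.space, frame)


def _target_series(values_by_stratum: dict, years) -> pd.Series:
    rows, idx = [], []
    for stratum, values in values_by_stratum.items():
        for year, v in zip(years, values):
            idx.append((year, *stratum))
            rows.append(float(v))
    index = pd.MultiIndex.from_tuples(idx, names=TARGET_LEVELS)
    return pd.Series(rows, index=index)


STRATUM = ("male", "lt45", "urban", "full_time")


class TestSmoothTargets:
    def test_constant_series_unchanged(self):
        obs = _target_series({STRATUM: [7.0, 7.0, 7.0]}, [2004, 2005, 2006])
        sm = g.smooth_targets(obs)
        assert np.allclose(sm.values, 7.0)

    def test_linear_series_reproduced_exactly(self):
        obs = _target_series({STRATUM: [10.0, 12.0, 14.0, 16.0]}, range(2004, 2008))
        sm = g.smooth_targets(obs)
        assert np.allclose(sm.values, obs.values)

    def test_matches_closed_form_ols(self):
        """Fitted values agree with hand-computed least squares."""
        years = np.array([1, 2, 3, 4])
        values = np.array([10.0, 14.0, 12.0, 16.0])
        slope, intercept = ols_line(years, values)
        assert slope == pytest.approx(1.6)
        assert intercept == pytest.approx(9.0)
        obs = _target_series({STRATUM: values}, years)
        sm = g.smooth_targets(obs)
        assert np.allclose(sm.values, intercept + slope * years)

    def test_single_observation_errors(self):
        obs = _target_series({STRATUM: [5.0]}, [2004])
        with pytest.raises(ConfigError, match="raw value"):
            g.smooth_targets(obs)

    def test_strata_smoothed_independently(self):
        other = ("female", "lt45", "urban", "part_time")
        obs = _target_series(
            {STRATUM: [10, 12, 14], other: [30, 20, 10]}, [2004, 2005, 2006]
        )
        sm = g.smooth_targets(obs)
        assert sm.xs(STRATUM[0], level="sex").iloc[0] == pytest.approx(10.0)
        assert sm.xs(other[0], level="sex").iloc[0] == pytest.approx(30.0)


class TestDeviation:
    def test_identical_series_convergent(self):
        s = _target_series({STRATUM: [10.0, 11.0]}, [2004, 2005])
        rep = g.deviation(s, s)
        assert rep.convergent
        assert rep.max_deviation == 0.0
        assert rep.summed_abs_deviation == 0.0

    def test_single_breach_defeats_convergence(self):
        sm = _target_series({STRATUM: [100.0, 100.0, 100.0]}, [2004, 2005, 2006])
        pred = sm.copy()
        pred.iloc[1] = 106.0  # 6% off on one target
        rep = g.deviation(pred, sm)
        assert not rep.convergent
        assert rep.max_deviation == pytest.approx(0.06)

    def test_summed_absolute_headcount_difference(self):
        sm = _target_series({STRATUM: [1719.0]}, [2004])
        pred = _target_series({STRATUM: [1717.0]}, [2004])
        rep = g.deviation(pred, sm)
        assert rep.summed_abs_deviation == pytest.approx(2.0)

    def test_zero_denominator_excluded_with_warning(self):
        sm = _target_series({STRATUM: [0.0, 10.0]}, [2004, 2005])
        pred = _target_series({STRATUM: [1.0, 10.0]}, [2004, 2005])
        with pytest.warns(UserWarning):
            rep = g.deviation(pred, sm)
        assert rep.n_excluded == 1
        assert rep.convergent

    def test_mismatched_keys_rejected(self):
        a = _target_series({STRATUM: [1.0]}, [2004])
        b = _target_series({STRATUM: [1.0]}, [2005])
        with pytest.raises(SchemaError):
            g.deviation(a, b)

    def test_tolerance_monotonicity(self):
        sm = _target_series({STRATUM: [100.0, 100.0]}, [2004, 2005])
        pred = _target_series({STRATUM: [104.0, 97.0]}, [2004, 2005])
        assert g.deviation(pred, sm, tolerance=0.05).convergent
        assert g.deviation(pred, sm, tolerance=0.10).convergent


class TestCalibrate:
    def test_truth_accepted_on_noise_free_targets(self, toy_supply):
        fix = toy_supply
        res = g.calibrate(
            fix.priors, fix.targets, fix.base_stock, fix.entries, fix.aging,
            n_samples=1, seed=0, extra_candidates=[fix.truth],
        )
        assert fix.truth.convergent

    def test_deterministic_given_seed(self, toy_supply):
        fix = toy_supply
        kw = dict(n_samples=40, seed=11)
        r1 = g.calibrate(fix.priors, fix.targets, fix.base_stock, fix.entries, fix.aging, **kw)
        r2 = g.calibrate(fix.priors, fix.targets, fix.base_stock, fix.entries, fix.aging, **kw)
        assert [p.seed for p in r1.accepted] == [p.seed for p in r2.accepted]
        assert r1.best.max_deviation == r2.best.max_deviation

    def test_far_priors_yield_empty_result_with_diagnostics(self, toy_supply):
        fix = toy_supply
        frame = fix.priors.frame.copy()
        # concentrate priors at ~10x the truth probabilities
        frame["alpha"] = 3000.0
        frame["beta"] = 7000.0
        far = g.PriorSpec(fix.space, frame)
        res = g.calibrate(
            far, fix.targets, fix.base_stock, fix.entries, fix.aging,
            n_samples=20, seed=2,
        )
        assert res.n_accepted == 0
        assert res.best is not None
        assert res.best.max_deviation > 0.05

    def test_acceptance_monotone_in_tolerance(self, toy_supply):
        fix = toy_supply
        kw = dict(n_samples=60, seed=4)
        tight = g.calibrate(
            fix.priors, fix.targets, fix.base_stock, fix.entries, fix.aging,
            tolerance=0.05, **kw,
        )
        loose = g.calibrate(
            fix.priors, fix.targets, fix.base_stock, fix.entries, fix.aging,
            tolerance=0.10, **kw,
        )
        assert {p.seed for p in tight.accepted} <= {p.seed for p in loose.accepted}

    def test_accepted_sets_respect_conservation(self, toy_supply):
        fix = toy_supply
        res = g.calibrate(
            fix.priors, fix.targets, fix.base_stock, fix.entries, fix.aging,
            n_samples=30, seed=8, tolerance=0.10,
        )
        pool = res.accepted or [res.best]
        per_year = fix.entries.entries_for(fix.base_stock.year).sum()
        for ps in pool:
            proj = g.project_supply(
                fix.base_stock, ps.table, ps.multipliers, fix.entries, fix.aging, horizon=7
            )
            totals = proj.totals()
            for a, b in zip(totals.values, totals.values[1:]):
                assert b == pytest.approx(a + per_year, rel=1e-9)
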