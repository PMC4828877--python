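"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive: plain dict arithmetic, explicit
enumeration of every (from, to) flow, closed-form least squares.  These
code paths share nothing with the vectorised implementation they check.
"""

from __future__ import annotations

import numpy as np

ACTIVE = ("full_time", "part_time")
AGED_STATUSES = ("full_time", "part_time", "temporary_exit")


def oracle_step(
    counts: dict,
    records: list[tuple],
    k: int,
    entries: dict | None = None,
    aging: list[tuple] | None = None,
) -> dict:
    """One annual cycle by explicit flow enumeration.

    ``records`` is a list of ``(from_state, to_state, p, m)``;
    ``aging`` a list of ``(band, next_band, fraction)``.  Order of
    application: entries, transitions (expected flows from the
    start-of-year stock, outbound sums proportionally capped at 1),
    then aging of non-permanent states.
    """
    s = {state: float(v) for state, v in counts.items()}
    if entries:
        for state, v in entries.items():
            s[state] = s.get(state, 0.0) + float(v)

    effective = []
    for frm, to, p, m in records:
        effective.append((frm, to, min(max(p * (1.0 + m) ** k, 0.0), 1.0)))
    out_sums: dict = {}
    for frm, _to, p in effective:
        out_sums[frm] = out_sums.get(frm, 0.0) + p
    start = dict(s)
    for frm, to, p in effective:
        scale = 1.0 / out_sums[frm] if out_sums[frm] > 1.0 else 1.0
        flow = start[frm] * p * scale
        s[frm] -= flow
        s[to] += flow

    if aging:
        snapshot = dict(s)
        for band, next_band, frac in aging:
            if next_band is None or frac == 0.0:
                continue
            for state, value in snapshot.items():
                sex, b, loc, status = state
                if b == band and status in AGED_STATUSES:
                    moved = value * frac
                    s[state] -= moved
                    target = (sex, next_band, loc, status)
                    s[target] = s.get(target, 0.0) + moved
    return s


def ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Closed-form simple linear regression (slope, intercept)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x.mean(), y.mean()
    slope = ((x - xm) * (y - ym)).sum() / ((x - xm) ** 2).sum()
    return slope, ym - slope * xm


def random_transition_records(space, rng, scale: float = 0.15) -> dict:
    """Random probabilities on every allowed move of a state space."""
    records = {}
    for sex in space.sexes:
        for band in space.band_labels:
            for loc in space.locations:
                other_locs = [l for l in space.locations if l != loc]
                records[(sex, band, loc, "full_time", loc, "part_time")] = rng.uniform(0, scale)
                records[(sex, band, loc, "part_time", loc, "full_time")] = rng.uniform(0, scale)
                for status in ACTIVE:
                    for ol in other_locs:
                        records[(sex, band, loc, status, ol, status)] = rng.uniform(0, scale / 2)
                    records[(sex, band, loc, status, loc, "temporary_exit")] = rng.uniform(0, scale / 2)
                    records[(sex, band, loc, status, loc, "permanent_exit")] = rng.uniform(0, scale / 2)
                records[(sex, band, loc, "temporary_exit", loc, "full_time")] = rng.uniform(0, 0.5)
                records[(sex, band, loc, "temporary_exit", loc, "part_time")] = rng.uniform(0, 0.5)
                records[(sex, band, loc, "temporary_exit", loc, "permanent_exit")] = rng.uniform(0, scale)
    return records


def random_stock(space, rng, scale: float = 200.0):
    import pandas as pd

    values = rng.uniform(0, scale, size=space.n_states)
    values[space.permanent_mask] = 0.0
    return pd.Series(values, index=space.index)
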