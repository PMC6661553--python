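"""Independent brute-force oracle for the decision-tree expectation.

Enumerates every root-to-leaf path of the care pathway with its probability
and summed payoff using plain year-by-year Python loops, sharing no code with
the implementation under test beyond the parameter names.
"""

from __future__ import annotations


def _disc(year: int, rate: float) -> float:
    return 1.0 if year == 1 else (1.0 + rate) ** -(year - 1)


def _five_year_survivor(utility, annual_cost, rate):
    q = c = 0.0
    for year in range(1, 6):
        q += utility * _disc(year, rate)
        c += annual_cost * _disc(year, rate)
    return q, c


def _five_year_decedent(py, utility, annual_cost, rate):
    q = c = 0.0
    remaining = py
    year = 1
    while remaining > 1e-15:
        frac = min(1.0, remaining)
        q += frac * utility * _disc(year, rate)
        c += frac * annual_cost * _disc(year, rate)
        remaining -= frac
        year += 1
    return q, c


def _tail(entry_age, utility, annual_cost, table, rate):
    q = c = 0.0
    alive = 1.0
    year = 6
    for age in range(entry_age, table.max_age + 1):
        q += alive * utility * _disc(year, rate)
        c += alive * annual_cost * _disc(year, rate)
        alive *= 1.0 - table.q(age)
        year += 1
    return q, c


def enumerate_paths(strategy, params, config, table, clamp=False):
    """List of ``(probability, cost, qaly)`` per terminal path."""
    pre = strategy.prehospital_cost
    p_h = strategy.p_survival_hospital
    if p_h == 0.0:
        return [(1.0, pre, 0.0)]
    p_icu = params["p_icu_admission"]
    cond = strategy.p_survival_discharge_overall / (p_h * p_icu)
    if cond > 1.0:
        if not clamp:
            raise ValueError("infeasible strategy")
        cond = 1.0
    ed = params["cost_ed"]
    icu_death = ed + params["cost_icu_daily_death"] * params["los_icu_death"] + params[
        "cost_nonicu_death"
    ]
    icu_surv = ed + params["cost_icu_daily_survivor"] * params[
        "los_icu_survivor"
    ] + params["cost_nonicu_survivor"]
    rate = config.discount_rate
    paths = [
        (1.0 - p_h, pre, 0.0),
        (p_h * (1.0 - p_icu), pre + ed, 0.0),
        (p_h * p_icu * (1.0 - cond), pre + icu_death, 0.0),
    ]
    p_discharge = p_h * p_icu * cond
    for group, p_group in (("12", params["p_cpc12"]), ("34", 1.0 - params["p_cpc12"])):
        p5 = params[f"p_5yr_cpc{group}"]
        py = params[f"py_death_cpc{group}"]
        u = params[f"utility_cpc{group}"]
        ac = params[f"annual_cost_cpc{group}"]
        sq, sc = _five_year_survivor(u, ac, rate)
        tq, tc = _tail(config.start_age + 5, u, ac, table, rate)
        dq, dc = _five_year_decedent(py, u, ac, rate)
        # path: discharged, alive at 5 years, then the Markov tail
        paths.append(
            (p_discharge * p_group * p5, pre + icu_surv + sc + tc, sq + tq)
        )
        # path: discharged, dead within 5 years
        paths.append(
            (p_discharge * p_group * (1.0 - p5), pre + icu_surv + dc, dq)
        )
    return paths


def expected_outcome(strategy, params, config, table, clamp=False):
    """(expected cost, expected QALY) by direct path enumeration."""
    paths = enumerate_paths(strategy, params, config, table, clamp=clamp)
    cost = sum(p * c for p, c, _ in paths)
    qaly = sum(p * q for p, _, q in paths)
    return cost, qaly
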