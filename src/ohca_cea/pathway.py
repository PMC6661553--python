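"""Decision-tree model of the OHCA care pathway.

The tree follows one cohort of out-of-hospital cardiac arrest patients through
three phases:

* **Prehospital** -- the strategy's cost is incurred by everyone; a fraction
  ``p_survival_hospital`` reaches hospital alive, the rest die on scene.
* **In-hospital** -- arrivals incur emergency-department (ED) cost.  A fraction
  ``p_icu_admission`` is admitted to intensive care; the remainder receive
  palliative care and die in the ED.  ICU patients either die in hospital
  (ICU non-survivor costs) or survive to discharge (ICU survivor costs).
  Because the strategy states survival to discharge *of all arrests*, the
  per-node discharge probability is the overall rate divided by
  ``p_survival_hospital`` and ``p_icu_admission``.
* **Post-discharge** -- survivors split by Cerebral Performance Category (CPC
  1-2 favourable vs 3-4 poor).  Each group passes through a five-year phase
  with group-specific survival, then joins the long-term Markov tail at
  national mortality rates.

Payoffs (costs in pound sterling, effects in QALYs) are summed along each
root-to-leaf path and weighted by the path probability.  Discounting applies
to post-discharge years after the first; prehospital and in-hospital payoffs
are undiscounted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

from .life_tables import LifeTable
from .markov import discount_factor, markov_tail
from .parameters import ParameterSet

__all__ = [
    "STRATEGY_NAMES",
    "InfeasibleStrategyError",
    "Strategy",
    "CohortConfig",
    "PathwayOutcome",
    "no_treatment_strategy",
    "als_strategy",
    "conditional_discharge_probability",
    "achievable",
    "inhospital_cost",
    "five_year_phase",
    "evaluate_strategy",
]

STRATEGY_NAMES = ("no_treatment", "als", "als_plus_ccm")

TERMINAL_NODES = (
    "prehospital_death",
    "ed_death",
    "icu_death",
    "discharge_cpc12",
    "discharge_cpc34",
)


class InfeasibleStrategyError(ValueError):
    """Survival-to-discharge rate not reachable through the ICU pathway."""


@dataclass(frozen=True)
class Strategy:
    """A prehospital care option with its cost and survival rates.

    ``p_survival_discharge_overall`` is survival to hospital discharge among
    *all* arrests, not among hospital arrivals.
    """

    name: str
    prehospital_cost: float
    p_survival_hospital: float
    p_survival_discharge_overall: float

    def __post_init__(self) -> None:
        for p in (self.p_survival_hospital, self.p_survival_discharge_overall):
            if not 0.0 <= p <= 1.0:
                raise InfeasibleStrategyError(f"{self.name}: probability {p} outside [0, 1]")
        if self.p_survival_discharge_overall > self.p_survival_hospital:
            raise InfeasibleStrategyError(
                f"{self.name}: discharge survival {self.p_survival_discharge_overall} "
                f"exceeds hospital survival {self.p_survival_hospital}"
            )
        if self.prehospital_cost < 0:
            raise InfeasibleStrategyError(f"{self.name}: negative prehospital cost")


def no_treatment_strategy() -> Strategy:
    """The empty comparator: no cost, no survivors."""
    return Strategy("no_treatment", 0.0, 0.0, 0.0)


def als_strategy(params: ParameterSet) -> Strategy:
    """Standard advanced life support, at the given parameter realization."""
    return Strategy(
        "als",
        params["cost_prehospital_als"],
        params["p_survival_hospital_als"],
        params["p_survival_discharge_als"],
    )


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level settings: age at arrest, discounting, horizon, WTP."""

    start_age: int = 65
    discount_rate: float = 0.035
    max_age: int = 110
    wtp_default: float = 20_000.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.discount_rate < 1.0:
            raise ValueError(f"discount_rate {self.discount_rate} outside [0, 1)")
        if not 0 <= self.start_age < self.max_age:
            raise ValueError(
                f"start_age {self.start_age} must lie in [0, max_age={self.max_age})"
            )


@dataclass(frozen=True)
class PathwayOutcome:
    """Expected discounted cost and QALYs per patient for one strategy."""

    strategy_name: str
    expected_cost: float
    expected_qaly: float
    terminal_probabilities: dict[str, float] = field(default_factory=dict)


def conditional_discharge_probability(
    p_discharge_overall: float,
    p_hospital: float,
    p_icu: float,
    clamp: bool = False,
) -> float:
    """Per-node probability of discharge given ICU admission.

    The overall discharge rate is stated over all arrests, so the tree node
    conditional on reaching ICU is ``p_discharge_overall / (p_hospital *
    p_icu)``.  A ratio above 1 means the stated discharge rate cannot be
    reached through the ICU pathway; with ``clamp=True`` it is truncated to 1
    (the feasibility boundary), otherwise :class:`InfeasibleStrategyError`
    is raised.
    """
    if p_hospital <= 0 or p_icu <= 0:
        raise InfeasibleStrategyError(
            "p_hospital and p_icu must be positive to condition on ICU admission"
        )
    ratio = p_discharge_overall / (p_hospital * p_icu)
    if ratio > 1.0:
        if clamp:
            return 1.0
        raise InfeasibleStrategyError(
            f"conditional discharge probability {ratio:.4f} exceeds 1"
        )
    return ratio


def achievable(
    delta_hospital: float,
    delta_discharge: float,
    base: ParameterSet,
) -> bool:
    """Whether a (Δ hospital survival, Δ discharge survival) combination, in
    absolute percentage points on the ALS rates, keeps the conditional
    discharge probability at or below 1."""
    p_hosp = base["p_survival_hospital_als"] + delta_hospital / 100.0
    p_dis = base["p_survival_discharge_als"] + delta_discharge / 100.0
    limit = base["p_icu_admission"] * p_hosp
    return p_dis <= limit + 1e-12


def inhospital_cost(path: str, params: ParameterSet) -> float:
    """Hospital-phase cost of one terminal path.

    ``ed_death`` incurs ED treatment only; ``icu_death`` adds ICU bed-days and
    non-ICU costs of non-survivors; ``icu_survivor`` adds the survivor
    equivalents.
    """
    ed = params["cost_ed"]
    if path == "ed_death":
        return ed
    if path == "icu_death":
        return (
            ed
            + params["cost_icu_daily_death"] * params["los_icu_death"]
            + params["cost_nonicu_death"]
        )
    if path == "icu_survivor":
        return (
            ed
            + params["cost_icu_daily_survivor"] * params["los_icu_survivor"]
            + params["cost_nonicu_survivor"]
        )
    raise ValueError(f"unknown in-hospital path {path!r}")


class FiveYearResult(NamedTuple):
    qaly: float
    cost: float
    p_alive_at_5: float


def five_year_phase(
    cpc_group: str,
    params: ParameterSet,
    config: CohortConfig,
) -> FiveYearResult:
    """Discounted payoffs of the first five post-discharge years for one CPC group.

    Five-year survivors (probability ``p_5yr``) accrue five full annual cycles
    of utility and annual healthcare cost.  Decedents accrue the group's mean
    person-years per death, spread over consecutive annual cycles from
    discharge with the fractional final year pro-rated.  Each post-discharge
    year ``y`` is weighted by the shared discount rule (year 1 undiscounted).
    """
    if cpc_group not in ("cpc12", "cpc34"):
        raise ValueError(f"unknown CPC group {cpc_group!r}")
    suffix = cpc_group[3:]
    p5 = params[f"p_5yr_cpc{suffix}"]
    py = params[f"py_death_cpc{suffix}"]
    utility = params[f"utility_cpc{suffix}"]
    annual_cost = params[f"annual_cost_cpc{suffix}"]
    if py > 5.0:
        raise ValueError(f"person-years per death within 5 years is {py} > 5")

    disc = [discount_factor(y, config.discount_rate) for y in range(1, 6)]
    survivor_years = sum(disc)
    full_years = math.floor(py)
    fraction = py - full_years
    decedent_years = sum(disc[:full_years])
    if fraction > 0.0:
        decedent_years += fraction * disc[full_years]
    expected_disc_years = p5 * survivor_years + (1.0 - p5) * decedent_years
    return FiveYearResult(
        qaly=expected_disc_years * utility,
        cost=expected_disc_years * annual_cost,
        p_alive_at_5=p5,
    )


def _discharge_payoff(
    cpc_group: str,
    params: ParameterSet,
    config: CohortConfig,
    table: LifeTable,
) -> tuple[float, float]:
    """(QALY, cost) for one discharged patient of the given CPC group,
    covering hospital survivor costs, the five-year phase and the Markov tail."""
    suffix = cpc_group[3:]
    five = five_year_phase(cpc_group, params, config)
    tail = markov_tail(
        entry_age=config.start_age + 5,
        utility=params[f"utility_cpc{suffix}"],
        annual_cost=params[f"annual_cost_cpc{suffix}"],
        table=table,
        discount_rate=config.discount_rate,
        years_offset=6,
    )
    qaly = five.qaly + five.p_alive_at_5 * tail.qaly
    cost = (
        inhospital_cost("icu_survivor", params)
        + five.cost
        + five.p_alive_at_5 * tail.cost
    )
    return qaly, cost


def evaluate_strategy(
    strategy: Strategy,
    params: ParameterSet,
    config: CohortConfig,
    table: LifeTable,
    clamp_infeasible: bool = False,
) -> PathwayOutcome:
    """Expected discounted cost and QALYs per OHCA patient for one strategy.

    The expectation runs over the five terminal nodes of the decision tree:
    prehospital death, ED death, in-hospital (ICU) death, and discharge with
    CPC 1-2 or CPC 3-4.  The no-treatment comparator (zero survival, zero
    cost) yields (0, 0) with all mass on prehospital death.

    With ``clamp_infeasible=True`` a discharge rate exceeding the ICU pathway
    bound is truncated to the feasibility boundary (conditional probability
    1), mirroring the "not achievable" limit of the two-way sensitivity
    analysis; otherwise it raises :class:`InfeasibleStrategyError`.
    """
    p_h = strategy.p_survival_hospital
    if p_h == 0.0:
        return PathwayOutcome(
            strategy_name=strategy.name,
            expected_cost=strategy.prehospital_cost,
            expected_qaly=0.0,
            terminal_probabilities={
                "prehospital_death": 1.0,
                "ed_death": 0.0,
                "icu_death": 0.0,
                "discharge_cpc12": 0.0,
                "discharge_cpc34": 0.0,
            },
        )

    p_icu = params["p_icu_admission"]
    p_cond = conditional_discharge_probability(
        strategy.p_survival_discharge_overall, p_h, p_icu, clamp=clamp_infeasible
    )
    p_cpc12 = params["p_cpc12"]

    p_prehosp_death = 1.0 - p_h
    p_ed_death = p_h * (1.0 - p_icu)
    p_icu_death = p_h * p_icu * (1.0 - p_cond)
    p_discharge = p_h * p_icu * p_cond
    probs = {
        "prehospital_death": p_prehosp_death,
        "ed_death": p_ed_death,
        "icu_death": p_icu_death,
        "discharge_cpc12": p_discharge * p_cpc12,
        "discharge_cpc34": p_discharge * (1.0 - p_cpc12),
    }

    cost = strategy.prehospital_cost
    cost += p_ed_death * inhospital_cost("ed_death", params)
    cost += p_icu_death * inhospital_cost("icu_death", params)
    qaly = 0.0
    for group in ("cpc12", "cpc34"):
        p_leaf = probs[f"discharge_{group}"]
        if p_leaf > 0.0:
            g_qaly, g_cost = _discharge_payoff(group, params, config, table)
            qaly += p_leaf * g_qaly
            cost += p_leaf * g_cost

    return PathwayOutcome(
        strategy_name=strategy.name,
        expected_cost=cost,
        expected_qaly=qaly,
        terminal_probabilities=probs,
    )
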