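"""Probabilistic sensitivity analysis, ICERs and acceptability curves.

Parameter uncertainty is propagated through the pathway model by Monte-Carlo
simulation: each iteration draws one shared parameter set from the fitted
sampling distributions and evaluates every strategy on it, so between-strategy
differences within an iteration reflect the strategies, not sampling noise.
The paper-grade run uses 1000 iterations.

Strategies whose discharge rate a draw renders unreachable through the ICU
pathway are clamped to the feasibility boundary (conditional discharge
probability 1) and counted, rather than discarded, so the sampling
distributions are not biased.
"""

from __future__ import annotations

import math
from collections.abc import Callable, Iterable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .life_tables import LifeTable
from .parameters import ParameterSet, ParameterSpec, sample_parameters
from .pathway import (
    CohortConfig,
    PathwayOutcome,
    Strategy,
    evaluate_strategy,
)

__all__ = [
    "StrategyBuilder",
    "PsaResult",
    "IcerResult",
    "CeacCurve",
    "PsaSummary",
    "run_psa",
    "icer",
    "incrementals",
    "ceac",
    "summarize",
]

#: A strategy builder maps one parameter realization to a concrete strategy,
#: so survival rates and costs can co-vary with the draw.
StrategyBuilder = Callable[[ParameterSet], Strategy]


@dataclass(frozen=True)
class PsaResult:
    """Per-iteration (cost, QALY) pairs for every strategy.

    ``samples`` has columns ``iteration, strategy, cost, qaly`` in long form.
    """

    samples: pd.DataFrame
    n_iterations: int
    seed: int
    strategy_names: tuple[str, ...]
    #: Number of (iteration, strategy) evaluations clamped to feasibility.
    n_clamped: int = 0

    def wide(self, value: str = "cost") -> pd.DataFrame:
        """Pivot to one row per iteration, one column per strategy."""
        return self.samples.pivot(index="iteration", columns="strategy", values=value)


def run_psa(
    strategy_builders: Mapping[str, StrategyBuilder],
    specs: Iterable[ParameterSpec],
    config: CohortConfig,
    table: LifeTable,
    n_iterations: int = 1000,
    seed: int = 0,
) -> PsaResult:
    """Monte-Carlo PSA: evaluate all strategies on shared parameter draws.

    Identical ``seed`` (and registry order) yields identical output.
    """
    if n_iterations < 1:
        raise ValueError(f"n_iterations must be >= 1, got {n_iterations}")
    specs = list(specs)
    rng = np.random.default_rng(seed)
    rows = []
    n_clamped = 0
    names = tuple(strategy_builders)
    for i in range(n_iterations):
        params = sample_parameters(specs, rng)
        for name, build in strategy_builders.items():
            strat = build(params)
            if strat.p_survival_hospital > 0.0:
                ratio = strat.p_survival_discharge_overall / (
                    strat.p_survival_hospital * params["p_icu_admission"]
                )
                if ratio > 1.0:
                    n_clamped += 1
            outcome = evaluate_strategy(
                strat, params, config, table, clamp_infeasible=True
            )
            rows.append((i, name, outcome.expected_cost, outcome.expected_qaly))
    samples = pd.DataFrame(rows, columns=["iteration", "strategy", "cost", "qaly"])
    return PsaResult(
        samples=samples,
        n_iterations=n_iterations,
        seed=seed,
        strategy_names=names,
        n_clamped=n_clamped,
    )


@dataclass(frozen=True)
class IcerResult:
    """Incremental cost-effectiveness of a reference versus a comparator.

    ``flag`` is ``"ratio"`` when ΔQALY > 0 and Δcost >= 0 (ordinary ICER),
    ``"dominant"`` (cheaper and more effective), ``"dominated"`` (dearer and
    less effective), ``"undefined"`` (ΔQALY = 0), or ``"ratio_sw"`` for the
    cheaper-but-less-effective quadrant, where the ratio is a savings-per-QALY-
    forgone figure.
    """

    delta_cost: float
    delta_qaly: float
    value: float
    flag: str


def _cost_qaly(outcome) -> tuple[float, float]:
    if isinstance(outcome, PathwayOutcome):
        return outcome.expected_cost, outcome.expected_qaly
    cost, qaly = outcome
    return float(cost), float(qaly)


def icer(reference, comparator) -> IcerResult:
    """ICER of ``reference`` relative to ``comparator``.

    Arguments may be :class:`~ohca_cea.pathway.PathwayOutcome` objects or
    ``(cost, qaly)`` pairs.
    """
    ref_c, ref_q = _cost_qaly(reference)
    comp_c, comp_q = _cost_qaly(comparator)
    dc, dq = ref_c - comp_c, ref_q - comp_q
    if dq > 0 and dc < 0:
        return IcerResult(dc, dq, dc / dq, "dominant")
    if dq < 0 and dc > 0:
        return IcerResult(dc, dq, math.nan, "dominated")
    if dq == 0:
        return IcerResult(dc, dq, math.nan, "undefined")
    flag = "ratio" if dq > 0 else "ratio_sw"
    return IcerResult(dc, dq, dc / dq, flag)


def incrementals(
    result: PsaResult, reference_name: str, comparator_name: str
) -> pd.DataFrame:
    """Per-iteration Δcost and ΔQALY of reference minus comparator."""
    cost = result.wide("cost")
    qaly = result.wide("qaly")
    for name in (reference_name, comparator_name):
        if name not in cost.columns:
            raise KeyError(f"strategy {name!r} not present in PSA result")
    return pd.DataFrame(
        {
            "delta_cost": cost[reference_name] - cost[comparator_name],
            "delta_qaly": qaly[reference_name] - qaly[comparator_name],
        }
    )


@dataclass(frozen=True)
class CeacCurve:
    """Probability of cost-effectiveness across a willingness-to-pay grid."""

    wtp_grid: np.ndarray
    probability_ce: np.ndarray

    def __post_init__(self) -> None:
        wtp = np.asarray(self.wtp_grid, dtype=float)
        prob = np.asarray(self.probability_ce, dtype=float)
        if wtp.shape != prob.shape:
            raise ValueError("wtp_grid and probability_ce must have equal length")
        object.__setattr__(self, "wtp_grid", wtp)
        object.__setattr__(self, "probability_ce", prob)

    def at(self, wtp: float) -> float:
        """Probability of cost-effectiveness at one WTP value on the grid."""
        idx = np.nonzero(np.isclose(self.wtp_grid, wtp))[0]
        if idx.size == 0:
            raise KeyError(f"WTP {wtp} not on the curve's grid")
        return float(self.probability_ce[idx[0]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"wtp": self.wtp_grid, "probability_ce": self.probability_ce}
        )


def ceac(
    result: PsaResult,
    reference_name: str,
    comparator_name: str,
    wtp_grid: Sequence[float],
) -> CeacCurve:
    """Cost-effectiveness acceptability curve.

    At each willingness-to-pay λ, the probability that the reference strategy
    is cost-effective is the fraction of iterations with positive net monetary
    benefit ``λ·ΔQALY − Δcost``.
    """
    wtp = np.asarray(list(wtp_grid), dtype=float)
    if wtp.size == 0:
        return CeacCurve(wtp, np.empty(0))
    inc = incrementals(result, reference_name, comparator_name)
    dq = inc["delta_qaly"].to_numpy()
    dc = inc["delta_cost"].to_numpy()
    nmb = wtp[:, None] * dq[None, :] - dc[None, :]
    return CeacCurve(wtp, (nmb > 0).mean(axis=1))


@dataclass(frozen=True)
class PsaSummary:
    """Distributional summary of per-iteration ICERs and cost-effectiveness."""

    median_icer: float
    iqr: tuple[float, float]
    ci95: tuple[float, float]
    fraction_ce: float
    wtp: float
    n_iterations: int
    n_positive_dq: int
    n_dominant: int


def summarize(
    result: PsaResult,
    reference_name: str,
    comparator_name: str,
    wtp: float = 20_000.0,
) -> PsaSummary:
    """Median, IQR and 95% interval of per-iteration ICERs, plus the fraction
    of iterations cost-effective at ``wtp``.

    Quantiles are computed over iterations with ΔQALY > 0; dominant
    iterations (Δcost < 0) carry negative ratios and therefore rank below all
    finite positive ICERs, matching the convention of placing dominance at
    the favourable extreme.
    """
    inc = incrementals(result, reference_name, comparator_name)
    dq = inc["delta_qaly"].to_numpy()
    dc = inc["delta_cost"].to_numpy()
    pos = dq > 0
    ratios = dc[pos] / dq[pos]
    if ratios.size:
        q2_5, q25, q50, q75, q97_5 = np.percentile(ratios, [2.5, 25, 50, 75, 97.5])
    else:
        q2_5 = q25 = q50 = q75 = q97_5 = math.nan
    fraction_ce = float(((wtp * dq - dc) > 0).mean())
    return PsaSummary(
        median_icer=float(q50),
        iqr=(float(q25), float(q75)),
        ci95=(float(q2_5), float(q97_5)),
        fraction_ce=fraction_ce,
        wtp=float(wtp),
        n_iterations=result.n_iterations,
        n_positive_dq=int(pos.sum()),
        n_dominant=int(((dq > 0) & (dc < 0)).sum()),
    )
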