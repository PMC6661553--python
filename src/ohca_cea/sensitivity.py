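"""Two-way sensitivity grids, effect scaling and the MEID threshold search.

The effectiveness of prehospital critical care for OHCA is too uncertain for a
single point estimate, so the model explores a range of absolute improvements
in survival to hospital discharge (1-6 percentage points on the 9.0% ALS
baseline).  Two constructions are exposed:

* **proportional scaling** -- survival to hospital arrival is scaled so the
  discharge/arrival ratio stays at its ALS value (used for the acceptability
  curves and the cost grid);
* **independent shifts** -- hospital-arrival and discharge survival are moved
  separately in absolute percentage points (the survival grid), including the
  combinations that are not achievable because discharge survival cannot
  exceed ``p_icu x hospital survival``.

The minimally economically important difference (MEID) is the smallest
discharge-survival improvement at which critical care reaches a target
probability of cost-effectiveness (default 50%) at the willingness-to-pay
threshold.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .life_tables import LifeTable
from .parameters import ParameterSet, ParameterSpec, point_estimates
from .pathway import (
    CohortConfig,
    InfeasibleStrategyError,
    Strategy,
    achievable,
    als_strategy,
)
from .psa import ceac, run_psa, summarize

__all__ = [
    "DELTA_DISCHARGE_GRID",
    "DELTA_HOSPITAL_GRID",
    "COST_MULTIPLIER_GRID",
    "proportional_scaling",
    "shifted_strategy",
    "GridResult",
    "survival_grid",
    "cost_grid",
    "MeidResult",
    "select_meid",
    "find_meid",
]

#: Column grid of Δ discharge survival (absolute percentage points).
DELTA_DISCHARGE_GRID = (1.0, 2.0, 3.0, 4.0, 5.0, 6.0)
#: Row grid of Δ hospital-arrival survival (absolute percentage points).
DELTA_HOSPITAL_GRID = (-5.0, 0.0, 5.0, 10.0, 15.0, 20.0)
#: Row grid of critical-care add-on cost multipliers (−50% .. +50%).
COST_MULTIPLIER_GRID = (0.5, 0.8, 1.0, 1.2, 1.5)


def proportional_scaling(
    delta_discharge: float,
    base: ParameterSet,
    cost_multiplier: float = 1.0,
) -> Strategy:
    """Critical-care strategy with a constant discharge/arrival survival ratio.

    Discharge survival is the ALS rate plus ``delta_discharge`` percentage
    points; hospital-arrival survival scales by the same factor, preserving
    the base ratio (0.258 / 0.09 at the point estimates).  The prehospital
    cost is the ALS cost plus the critical-care add-on, optionally scaled.
    """
    p_dis_base = base["p_survival_discharge_als"]
    p_hosp_base = base["p_survival_hospital_als"]
    p_dis = p_dis_base + delta_discharge / 100.0
    p_hosp = p_dis * (p_hosp_base / p_dis_base)
    if not 0.0 <= p_dis <= 1.0 or p_hosp > 1.0:
        raise InfeasibleStrategyError(
            f"scaled survival rates out of range (discharge {p_dis}, hospital {p_hosp})"
        )
    cost = base["cost_prehospital_als"] + cost_multiplier * base[
        "cost_prehospital_ccm_addon"
    ]
    return Strategy("als_plus_ccm", cost, p_hosp, p_dis)


def shifted_strategy(
    delta_hospital: float,
    delta_discharge: float,
    base: ParameterSet,
    cost_multiplier: float = 1.0,
) -> Strategy:
    """Critical-care strategy with independently shifted survival rates
    (absolute percentage points on the ALS rates)."""
    p_hosp = base["p_survival_hospital_als"] + delta_hospital / 100.0
    p_dis = base["p_survival_discharge_als"] + delta_discharge / 100.0
    if not 0.0 <= p_dis <= 1.0 or not 0.0 <= p_hosp <= 1.0:
        raise InfeasibleStrategyError(
            f"shifted survival rates out of range (discharge {p_dis}, hospital {p_hosp})"
        )
    cost = base["cost_prehospital_als"] + cost_multiplier * base[
        "cost_prehospital_ccm_addon"
    ]
    return Strategy("als_plus_ccm", cost, p_hosp, p_dis)


@dataclass(frozen=True)
class GridResult:
    """Two-way sensitivity grid of incremental cost-effectiveness.

    ``median``, ``low`` and ``high`` are DataFrames (rows x columns of the
    swept quantities) holding the per-cell median and 2.5/97.5 percentile
    ICER of critical care versus ALS; ``achievable`` marks cells whose
    survival combination is feasible.  Unachievable cells hold NaN.
    """

    median: pd.DataFrame
    low: pd.DataFrame
    high: pd.DataFrame
    achievable: pd.DataFrame
    n_iterations: int
    seed: int

    def display(self, rounding: float = 500.0) -> pd.DataFrame:
        """Presentation table: values rounded to the nearest ``rounding`` (£500
        by convention), unachievable cells shown as 'Not achievable'."""
        def fmt(med, lo, hi, ok):
            if not ok:
                return "Not achievable"
            r = lambda x: int(np.round(x / rounding) * rounding)
            return f"{r(med)} ({r(lo)} to {r(hi)})"

        out = self.median.copy().astype(object)
        for r in self.median.index:
            for c in self.median.columns:
                out.loc[r, c] = fmt(
                    self.median.loc[r, c],
                    self.low.loc[r, c],
                    self.high.loc[r, c],
                    bool(self.achievable.loc[r, c]),
                )
        return out


def _grid_cell(
    builder,
    specs: Sequence[ParameterSpec],
    config: CohortConfig,
    table: LifeTable,
    n_iterations: int,
    seed: int,
) -> tuple[float, float, float]:
    result = run_psa(
        {"als": als_strategy, "als_plus_ccm": builder},
        specs,
        config,
        table,
        n_iterations=n_iterations,
        seed=seed,
    )
    s = summarize(result, "als_plus_ccm", "als", wtp=config.wtp_default)
    return s.median_icer, s.ci95[0], s.ci95[1]


def survival_grid(
    delta_hospital_list: Sequence[float] = DELTA_HOSPITAL_GRID,
    delta_discharge_list: Sequence[float] = DELTA_DISCHARGE_GRID,
    specs: Iterable[ParameterSpec] | None = None,
    config: CohortConfig = CohortConfig(),
    table: LifeTable | None = None,
    n_iterations: int = 1000,
    seed: int = 0,
) -> GridResult:
    """Median (95% interval) ICER of critical care vs ALS for independent
    shifts of hospital-arrival and discharge survival.

    Every cell reuses the same PSA seed, so between-cell differences reflect
    the shifted rates rather than Monte-Carlo noise.  Cells whose survival
    combination exceeds the ICU feasibility bound at the point estimates are
    marked unachievable and left empty.
    """
    from .life_tables import synthesize_life_table

    specs = list(specs) if specs is not None else _default_specs()
    table = table if table is not None else synthesize_life_table(max_age=config.max_age)
    if not delta_hospital_list or not delta_discharge_list:
        raise ValueError("delta lists must be non-empty")
    base = point_estimates(specs)
    shape = (len(delta_hospital_list), len(delta_discharge_list))
    med = np.full(shape, np.nan)
    lo = np.full(shape, np.nan)
    hi = np.full(shape, np.nan)
    ok = np.zeros(shape, dtype=bool)
    for i, dh in enumerate(delta_hospital_list):
        for j, dd in enumerate(delta_discharge_list):
            if not achievable(dh, dd, base):
                continue
            ok[i, j] = True
            builder = lambda p, dh=dh, dd=dd: shifted_strategy(dh, dd, p)
            med[i, j], lo[i, j], hi[i, j] = _grid_cell(
                builder, specs, config, table, n_iterations, seed
            )
    index = pd.Index(delta_hospital_list, name="delta_hospital_pp")
    cols = pd.Index(delta_discharge_list, name="delta_discharge_pp")
    frame = lambda a: pd.DataFrame(a, index=index, columns=cols)
    return GridResult(frame(med), frame(lo), frame(hi), frame(ok), n_iterations, seed)


def cost_grid(
    cost_multipliers: Sequence[float] = COST_MULTIPLIER_GRID,
    delta_discharge_list: Sequence[float] = DELTA_DISCHARGE_GRID,
    specs: Iterable[ParameterSpec] | None = None,
    config: CohortConfig = CohortConfig(),
    table: LifeTable | None = None,
    n_iterations: int = 1000,
    seed: int = 0,
) -> GridResult:
    """Median (95% interval) ICER of critical care vs ALS for scaled
    critical-care costs, with survival improved by proportional scaling."""
    from .life_tables import synthesize_life_table

    specs = list(specs) if specs is not None else _default_specs()
    table = table if table is not None else synthesize_life_table(max_age=config.max_age)
    if not cost_multipliers or not delta_discharge_list:
        raise ValueError("grid axes must be non-empty")
    if any(m <= 0 for m in cost_multipliers):
        raise ValueError("cost multipliers must be positive")
    shape = (len(cost_multipliers), len(delta_discharge_list))
    med = np.full(shape, np.nan)
    lo = np.full(shape, np.nan)
    hi = np.full(shape, np.nan)
    ok = np.ones(shape, dtype=bool)
    for i, mult in enumerate(cost_multipliers):
        for j, dd in enumerate(delta_discharge_list):
            builder = lambda p, m=mult, dd=dd: proportional_scaling(dd, p, cost_multiplier=m)
            med[i, j], lo[i, j], hi[i, j] = _grid_cell(
                builder, specs, config, table, n_iterations, seed
            )
    index = pd.Index(cost_multipliers, name="cost_multiplier")
    cols = pd.Index(delta_discharge_list, name="delta_discharge_pp")
    frame = lambda a: pd.DataFrame(a, index=index, columns=cols)
    return GridResult(frame(med), frame(lo), frame(hi), frame(ok), n_iterations, seed)


def select_meid(
    probabilities: dict[float, float], prob_threshold: float
) -> float | None:
    """Smallest delta (in ascending key order) whose probability of
    cost-effectiveness meets ``prob_threshold``; None if none qualifies."""
    for delta in sorted(probabilities):
        if probabilities[delta] >= prob_threshold:
            return delta
    return None


@dataclass(frozen=True)
class MeidResult:
    """Outcome of the MEID threshold search."""

    #: Smallest qualifying Δ discharge survival (percentage points), or None.
    meid: float | None
    #: CEAC probability at the WTP threshold for every delta searched.
    probabilities: dict[float, float]
    wtp: float
    prob_threshold: float


def find_meid(
    specs: Iterable[ParameterSpec] | None = None,
    config: CohortConfig = CohortConfig(),
    table: LifeTable | None = None,
    wtp: float = 20_000.0,
    prob_threshold: float = 0.5,
    deltas: Sequence[float] = DELTA_DISCHARGE_GRID,
    n_iterations: int = 1000,
    seed: int = 0,
) -> MeidResult:
    """Smallest discharge-survival improvement making critical care
    cost-effective with the requested certainty.

    For each delta (ascending), critical care is built by proportional
    scaling and compared with ALS in a PSA sharing the same seed; the MEID is
    the first delta whose probability of positive net monetary benefit at
    ``wtp`` meets ``prob_threshold``.
    """
    from .life_tables import synthesize_life_table

    specs = list(specs) if specs is not None else _default_specs()
    table = table if table is not None else synthesize_life_table(max_age=config.max_age)
    deltas = list(deltas)
    if not deltas:
        raise ValueError("deltas list must be non-empty")
    if sorted(deltas) != deltas:
        raise ValueError("deltas must be sorted ascending")
    probs: dict[float, float] = {}
    for delta in deltas:
        builder = lambda p, d=delta: proportional_scaling(d, p)
        result = run_psa(
            {"als": als_strategy, "als_plus_ccm": builder},
            specs,
            config,
            table,
            n_iterations=n_iterations,
            seed=seed,
        )
        curve = ceac(result, "als_plus_ccm", "als", [wtp])
        probs[delta] = curve.at(wtp)
    return MeidResult(
        meid=select_meid(probs, prob_threshold),
        probabilities=probs,
        wtp=wtp,
        prob_threshold=prob_threshold,
    )


def _default_specs() -> list[ParameterSpec]:
    from .parameters import default_specs

    return default_specs()
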