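"""Long-term Markov cohort tail beyond five years post-discharge.

Survivors of the five-year post-discharge phase enter an annual-cycle Markov
model in which the only transition is death at national age-specific rates
taken from a period life table.  While alive they accrue a constant
neurological-outcome-specific utility weight and annual healthcare cost.

Discounting follows the NICE reference case: 3.5% per year applied to costs
and effects occurring after the first year following hospital discharge, so
post-discharge year 1 is undiscounted and year ``y >= 2`` is weighted by
``(1 + rate) ** -(y - 1)``.  The tail's first cycle is post-discharge year 6
(``years_offset = 6``).

Cycle convention: a cohort member alive at a cycle start accrues that full
cycle's utility and cost; deaths apply at cycle end.  No half-cycle
correction is applied.  The table's closure (``q = 1`` at its final age)
bounds the computation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .life_tables import LifeTable

__all__ = ["TailResult", "discount_factor", "discount_factors", "markov_tail"]


class DiscountError(ValueError):
    """Invalid discounting arguments."""


def discount_factor(years_since_discharge: int, rate: float) -> float:
    """Discount weight for post-discharge year ``y``: 1 for year 1, then
    ``(1 + rate) ** -(y - 1)``."""
    if years_since_discharge < 1:
        raise DiscountError(
            f"years_since_discharge must be >= 1, got {years_since_discharge}"
        )
    if years_since_discharge == 1:
        return 1.0
    return float((1.0 + rate) ** -(years_since_discharge - 1))


def discount_factors(years: np.ndarray, rate: float) -> np.ndarray:
    """Vectorized :func:`discount_factor` over an array of post-discharge years."""
    years = np.asarray(years)
    if np.any(years < 1):
        raise DiscountError("all years must be >= 1")
    return np.where(years == 1, 1.0, (1.0 + rate) ** -(years - 1.0))


@dataclass(frozen=True)
class TailResult:
    """Discounted payoffs of the Markov tail for one entrant."""

    qaly: float
    cost: float
    #: Undiscounted expected remaining years (life expectancy at entry).
    expected_years: float
    #: Optional per-cycle trace: age, survival, discounted qaly and cost.
    trace: pd.DataFrame | None = None


def markov_tail(
    entry_age: int,
    utility: float,
    annual_cost: float,
    table: LifeTable,
    discount_rate: float = 0.035,
    years_offset: int = 6,
    keep_trace: bool = False,
) -> TailResult:
    """Expected discounted QALYs and costs of the long-term survival tail.

    Parameters
    ----------
    entry_age:
        Age at the start of the first tail cycle (start age + 5 in the full
        pathway).  An entry age beyond the table returns an all-zero tail.
    utility, annual_cost:
        Per-year QALY weight and healthcare cost while alive.
    years_offset:
        Post-discharge year number of the first tail cycle (default 6), used
        for the discount clock.
    """
    if years_offset < 1:
        raise DiscountError(f"years_offset must be >= 1, got {years_offset}")
    if entry_age > table.max_age:
        return TailResult(0.0, 0.0, 0.0, None)
    S = table.survival_curve(entry_age)
    t = np.arange(S.size)
    df = discount_factors(years_offset + t, discount_rate)
    qaly_by_cycle = S * df * utility
    cost_by_cycle = S * df * annual_cost
    trace = None
    if keep_trace:
        trace = pd.DataFrame(
            {
                "age": entry_age + t,
                "years_since_discharge": years_offset + t,
                "survival": S,
                "discounted_qaly": qaly_by_cycle,
                "discounted_cost": cost_by_cycle,
            }
        )
    return TailResult(
        qaly=float(qaly_by_cycle.sum()),
        cost=float(cost_by_cycle.sum()),
        expected_years=float(S.sum()),
        trace=trace,
    )
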