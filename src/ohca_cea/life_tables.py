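"""Period life tables for the long-term survival phase.

The long-term (Markov) phase of the pathway model assumes that patients alive
five years after hospital discharge die at national age-specific rates.  This
module provides a synthetic national-style period life table -- a Gompertz
hazard ``q(x) = min(1, A * exp(B * x))`` with defaults calibrated so that life
expectancy at 65 is roughly 20 years -- plus reading and writing of
user-supplied tables (CSV with columns ``age,qx``) so a real national extract
can be substituted.

Cycle convention (shared with the Markov tail): a cohort member alive at the
start of an annual cycle accrues that full year; deaths apply at cycle end.
Life expectancy at age ``a`` is therefore ``sum over t >= 0 of S(t)`` with
``S(0) = 1`` and ``S(t) = prod_{k<t} (1 - q(a + k))``, and a person facing
``q = 1`` still lives exactly one final year.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LifeTableError",
    "LifeTable",
    "synthesize_life_table",
    "read_life_table",
    "write_life_table",
    "life_expectancy",
]

DEFAULT_HAZARD_SCALE = 3.0e-5
DEFAULT_LOG_HAZARD_SLOPE = 0.09
DEFAULT_MAX_AGE = 110


class LifeTableError(ValueError):
    """Malformed or out-of-range life table."""


@dataclass(frozen=True)
class LifeTable:
    """Annual probabilities of death ``qx[age]`` for ages ``0..max_age``.

    Ages beyond ``max_age`` are treated as certain death (the cohort is closed
    at the table's end).
    """

    qx: np.ndarray

    def __post_init__(self) -> None:
        qx = np.asarray(self.qx, dtype=float)
        if qx.ndim != 1 or qx.size < 1:
            raise LifeTableError("qx must be a non-empty 1-D array")
        if np.any(~np.isfinite(qx)) or np.any(qx < 0.0) or np.any(qx > 1.0):
            raise LifeTableError("every qx must be a finite probability in [0, 1]")
        object.__setattr__(self, "qx", qx)

    @property
    def max_age(self) -> int:
        return self.qx.size - 1

    def q(self, age: int) -> float:
        """Annual probability of death at integer ``age``."""
        if not 0 <= age <= self.max_age:
            raise LifeTableError(f"age {age} outside table range 0..{self.max_age}")
        return float(self.qx[age])

    def survival_curve(self, age: int) -> np.ndarray:
        """``S(t)`` for ``t = 0..max_age - age``: probability of being alive at
        the start of cycle ``t`` for someone aged ``age`` at cycle 0."""
        if not 0 <= age <= self.max_age:
            raise LifeTableError(f"age {age} outside table range 0..{self.max_age}")
        p_live = 1.0 - self.qx[age:]
        S = np.empty(p_live.size, dtype=float)
        S[0] = 1.0
        if p_live.size > 1:
            np.cumprod(p_live[:-1], out=S[1:])
        return S


def synthesize_life_table(
    hazard_scale: float = DEFAULT_HAZARD_SCALE,
    log_hazard_slope: float = DEFAULT_LOG_HAZARD_SLOPE,
    max_age: int = DEFAULT_MAX_AGE,
) -> LifeTable:
    """Deterministic Gompertz-style synthetic national life table.

    ``q(x) = min(1, hazard_scale * exp(log_hazard_slope * x))``, with
    ``q(max_age)`` forced to 1 so the cohort closes.  No randomness is
    involved: the table is a pure function of its three arguments.
    """
    if hazard_scale <= 0 or log_hazard_slope <= 0:
        raise LifeTableError("hazard_scale and log_hazard_slope must be positive")
    if max_age < 100:
        raise LifeTableError(f"max_age must be >= 100, got {max_age}")
    ages = np.arange(max_age + 1, dtype=float)
    qx = np.minimum(1.0, hazard_scale * np.exp(log_hazard_slope * ages))
    qx[-1] = 1.0
    return LifeTable(qx)


def read_life_table(path: str | Path) -> LifeTable:
    """Read a CSV life table with columns ``age,qx``, ages contiguous from 0."""
    df = pd.read_csv(path)
    if not {"age", "qx"}.issubset(df.columns):
        raise LifeTableError(f"{path}: expected columns age,qx")
    ages = df["age"].to_numpy()
    expected = np.arange(len(df))
    if not np.array_equal(ages, expected):
        raise LifeTableError(f"{path}: ages must be contiguous integers from 0")
    return LifeTable(df["qx"].to_numpy(dtype=float))


def write_life_table(table: LifeTable, path: str | Path) -> None:
    """Write a life table as CSV ``age,qx`` (inverse of :func:`read_life_table`)."""
    pd.DataFrame({"age": np.arange(table.max_age + 1), "qx": table.qx}).to_csv(
        path, index=False
    )


def life_expectancy(table: LifeTable, age: int) -> float:
    """Expected remaining years at ``age`` under the alive-at-cycle-start
    accrual convention (see module docstring)."""
    return float(table.survival_curve(age).sum())
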