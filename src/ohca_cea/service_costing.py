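"""Prehospital service expenditure and per-case OHCA costs.

An ambulance service's annual ledger is attributed to out-of-hospital cardiac
arrest by caseload share: the per-patient cost is ``total expenditure x
fraction of activity devoted to OHCA / number of OHCA patients``.  The package
ships the two ledgers used by the model -- a regional advanced-life-support
(ALS) ambulance service and a charity-funded prehospital critical care team --
and reproduces their per-case costs (about £348 for ALS, about £1686 for the
critical-care add-on at 2015-16 prices, £1711 after inflation to 2016-17).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "CATEGORIES",
    "ServiceLedger",
    "ALS_LEDGER",
    "CRITICAL_CARE_LEDGER",
    "cost_per_case",
    "inflate_cost",
    "round_pounds",
    "ledger_table",
    "read_ledger",
    "write_ledger",
]

#: Expenditure categories, in ledger display order.
CATEGORIES = (
    "staff",
    "vehicles",
    "helicopter",
    "buildings",
    "equipment",
    "other",
    "dispatch",
)


class LedgerError(ValueError):
    """Malformed service ledger."""


def cost_per_case(total: float, fraction_ohca: float, n_ohca: int) -> float:
    """Per-patient cost of OHCA care: ``total * fraction_ohca / n_ohca``.

    Unrounded; use :func:`round_pounds` for display.
    """
    if total < 0:
        raise LedgerError(f"negative total expenditure {total}")
    if not 0.0 <= fraction_ohca <= 1.0:
        raise LedgerError(f"fraction_ohca {fraction_ohca} outside [0, 1]")
    if n_ohca < 1:
        raise LedgerError(f"n_ohca must be >= 1, got {n_ohca}")
    return total * fraction_ohca / n_ohca


def inflate_cost(cost: float, index_ratio: float) -> float:
    """Adjust a cost by a pay-and-prices index ratio (``cost * index_ratio``)."""
    if index_ratio <= 0:
        raise LedgerError(f"index ratio must be positive, got {index_ratio}")
    return cost * index_ratio


def round_pounds(x: float) -> int:
    """Round to whole pounds, ties to even (display only)."""
    q = round(x)  # Python round is half-even
    return int(q)


@dataclass(frozen=True)
class ServiceLedger:
    """Annual expenditure of one prehospital service, with its OHCA share."""

    service_name: str
    expenditure_by_category: dict[str, float]
    fraction_ohca: float
    n_ohca: int
    #: Printed grand total; checked against the category sum to within £1.
    total: float | None = field(default=None)

    def __post_init__(self) -> None:
        unknown = set(self.expenditure_by_category) - set(CATEGORIES)
        if unknown:
            raise LedgerError(f"unknown categories: {sorted(unknown)}")
        if not 0.0 <= self.fraction_ohca <= 1.0:
            raise LedgerError(f"fraction_ohca {self.fraction_ohca} outside [0, 1]")
        if self.n_ohca < 1:
            raise LedgerError(f"n_ohca must be >= 1, got {self.n_ohca}")
        if self.total is None:
            object.__setattr__(self, "total", self.category_sum)
        elif abs(self.total - self.category_sum) > 1.0:
            raise LedgerError(
                f"{self.service_name}: total {self.total} differs from category "
                f"sum {self.category_sum} by more than £1"
            )

    @property
    def category_sum(self) -> float:
        return float(sum(self.expenditure_by_category.values()))

    def cost_per_case(self) -> float:
        """Per-OHCA-patient cost attributed from this ledger (unrounded)."""
        return cost_per_case(self.total, self.fraction_ohca, self.n_ohca)


#: 2015-16 ledger of the regional ALS ambulance service (£; 0.85% of activity
#: attributed to 1412 OHCA patients).
ALS_LEDGER = ServiceLedger(
    service_name="als",
    expenditure_by_category={
        "staff": 36_732_844,
        "vehicles": 8_145_245,
        "helicopter": 0,
        "buildings": 2_705_442,
        "equipment": 1_681_383,
        "other": 6_261_901,
        "dispatch": 2_226_955,
    },
    fraction_ohca=0.0085,
    n_ohca=1412,
    total=57_753_770,
)

#: 2015-16 ledger of the charity-funded prehospital critical care team (£;
#: 30% of activity attributed to 388 OHCA patients).
CRITICAL_CARE_LEDGER = ServiceLedger(
    service_name="critical_care",
    expenditure_by_category={
        "staff": 665_293,
        "vehicles": 13_659,
        "helicopter": 1_318_432,
        "buildings": 37_693,
        "equipment": 63_296,
        "other": 37_752,
        "dispatch": 45_000,
    },
    fraction_ohca=0.30,
    n_ohca=388,
    total=2_181_125,
)


def ledger_table(*ledgers: ServiceLedger) -> pd.DataFrame:
    """Side-by-side expenditure table for one or more ledgers.

    Rows are the expenditure categories plus total, OHCA share, patient count
    and the (rounded) per-case cost; columns are services.
    """
    if not ledgers:
        ledgers = (ALS_LEDGER, CRITICAL_CARE_LEDGER)
    cols = {}
    for led in ledgers:
        col = {cat: led.expenditure_by_category.get(cat, 0.0) for cat in CATEGORIES}
        col["total"] = led.total
        col["fraction_ohca"] = led.fraction_ohca
        col["n_ohca"] = led.n_ohca
        col["cost_per_case"] = round_pounds(led.cost_per_case())
        cols[led.service_name] = col
    return pd.DataFrame(cols)


def write_ledger(ledger: ServiceLedger, path: str | Path) -> None:
    """Serialize a ledger to CSV: ``#``-prefixed header block, then category,amount."""
    lines = [
        f"# service_name,{ledger.service_name}",
        f"# fraction_ohca,{ledger.fraction_ohca!r}",
        f"# n_ohca,{ledger.n_ohca}",
        "category,amount",
    ]
    for cat in CATEGORIES:
        lines.append(f"{cat},{ledger.expenditure_by_category.get(cat, 0.0)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_ledger(path: str | Path) -> ServiceLedger:
    """Read a ledger written by :func:`write_ledger`."""
    header: dict[str, str] = {}
    body_lines = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            key, _, value = line.lstrip("# ").partition(",")
            header[key.strip()] = value.strip()
        elif line.strip():
            body_lines.append(line)
    try:
        name = header["service_name"]
        fraction = float(header["fraction_ohca"])
        n_ohca = int(header["n_ohca"])
    except KeyError as exc:
        raise LedgerError(f"{path}: missing header field {exc}") from exc
    df = pd.read_csv(io.StringIO("\n".join(body_lines)))
    if list(df.columns) != ["category", "amount"]:
        raise LedgerError(f"{path}: expected columns category,amount")
    amounts = dict(zip(df["category"], df["amount"].astype(float)))
    return ServiceLedger(
        service_name=name,
        expenditure_by_category=amounts,
        fraction_ohca=fraction,
        n_ohca=n_ohca,
    )
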