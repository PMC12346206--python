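"""Bottom-up direct/indirect cost aggregation.

Per-patient itemised costs (hospitalization, ICU, medication, outpatient
follow-up, surgery) are converted to inflation-adjusted target-period USD
and summed by category — a bottom-up costing from the healthcare payer
perspective.  Indirect productivity losses follow the human-capital
approach: missed workdays priced at an average daily wage.

Monetary arithmetic is carried out unrounded; rounding (half-even, two
decimals) happens only at presentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import COST_CATEGORIES, CostItem, PatientRecord
from .currency import ConversionTables, convert_amount
from .errors import DataError

TARGET_CURRENCY = "USD-2022Q4"


@dataclass(frozen=True)
class WageModel:
    """Average daily wage with its currency-year tag (human-capital approach)."""

    daily_wage: float
    currency: str = "USD"
    year: int = 2020

    def __post_init__(self) -> None:
        if self.daily_wage < 0:
            raise DataError("daily_wage must be nonnegative")


def indirect_cost(incapacity_days: int, wage: WageModel) -> CostItem:
    """Productivity loss: missed workdays x daily wage, as an incapacity item."""
    if incapacity_days < 0:
        raise DataError(f"incapacity_days must be nonnegative, got {incapacity_days}")
    return CostItem(
        "incapacity", incapacity_days * wage.daily_wage, wage.currency, wage.year
    )


@dataclass(frozen=True)
class CostBreakdown:
    """Per-category totals in target-period USD for one patient."""

    totals: tuple  # aligned with COST_CATEGORIES
    currency: str = TARGET_CURRENCY

    def __getitem__(self, category: str) -> float:
        return self.totals[COST_CATEGORIES.index(category)]

    @property
    def total(self) -> float:
        return float(sum(self.totals))

    @property
    def subtotal_without_surgical(self) -> float:
        """Total minus surgical-category items (the documented definition)."""
        return self.total - self["surgical"]

    def as_dict(self) -> dict:
        return dict(zip(COST_CATEGORIES, self.totals))


def aggregate_patient(
    record: PatientRecord, tables: ConversionTables
) -> CostBreakdown:
    """Convert every cost item to target-period USD and sum by category."""
    sums = dict.fromkeys(COST_CATEGORIES, 0.0)
    for item in record.cost_items:
        sums[item.category] += convert_amount(
            item.amount, item.currency, item.year, tables
        )
    return CostBreakdown(totals=tuple(sums[c] for c in COST_CATEGORIES))


def aggregate_cohort(
    cohort: list[PatientRecord], tables: ConversionTables
) -> list[CostBreakdown]:
    return [aggregate_patient(rec, tables) for rec in cohort]


_SUMMARY_ROWS = list(COST_CATEGORIES) + ["subtotal_without_surgical", "total"]


def summarize_cohort(breakdowns: list[CostBreakdown]) -> pd.DataFrame:
    """Cohort cost summary: mean, sample SD, median, min, max per category.

    SD uses the n-1 denominator; with a single patient the SD is reported
    as 0 and the ``degenerate`` flag is set.
    """
    if not breakdowns:
        raise DataError("summarize_cohort requires at least one breakdown")
    n = len(breakdowns)
    rows = {}
    for name in _SUMMARY_ROWS:
        if name == "total":
            values = np.array([b.total for b in breakdowns])
        elif name == "subtotal_without_surgical":
            values = np.array([b.subtotal_without_surgical for b in breakdowns])
        else:
            values = np.array([b[name] for b in breakdowns])
        rows[name] = {
            "n": n,
            "mean": values.mean(),
            "sd": 0.0 if n == 1 else values.std(ddof=1),
            "median": float(np.median(values)),
            "min": values.min(),
            "max": values.max(),
            "degenerate": n == 1,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def summarize_fields(cohort: list[PatientRecord], fields: list[str]) -> pd.DataFrame:
    """Same summary layout for numeric patient fields (labs, days, visits)."""
    if not cohort:
        raise DataError("summarize_fields requires a nonempty cohort")
    n = len(cohort)
    rows = {}
    for f in fields:
        values = np.array([float(getattr(rec, f)) for rec in cohort])
        rows[f] = {
            "n": n,
            "mean": values.mean(),
            "sd": 0.0 if n == 1 else values.std(ddof=1),
            "median": float(np.median(values)),
            "min": values.min(),
            "max": values.max(),
            "degenerate": n == 1,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def _money(x: float) -> str:
    # round-half-even at presentation only
    return f"{float(np.round(x, 2)):,.2f}"


def format_summary(df: pd.DataFrame, title: str = "") -> str:
    """Aligned-text rendering: ``mean ± SD / median (min–max)`` per row."""
    lines = []
    if title:
        lines += [title, "=" * len(title)]
    width = max(len(str(i)) for i in df.index) + 2
    for name, row in df.iterrows():
        stat = (
            f"{_money(row['mean'])} ± {_money(row['sd'])}"
            f"/{_money(row['median'])} ({_money(row['min'])}–{_money(row['max'])})"
        )
        if row.get("degenerate", False):
            stat += "  [n=1: SD not estimable]"
        lines.append(f"{str(name):<{width}}{stat}")
    return "\n".join(lines) + "\n"
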