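"""Conversion of historical local-currency costs to inflation-adjusted USD.

Three-step procedure: (1) a multiplicative factor 1/fx[year] converts a
local-currency amount to same-year US dollars using the annual-average
exchange rate (local units per USD); (2) the amount is multiplied by that
factor; (3) the USD amount is restated in the purchasing power of the
target period (fourth quarter of 2022) via the ratio of US CPI indices.
The order is fixed: FX first, then CPI.

The packaged FX (TRY per USD) and CPI-U tables are example tables shipped
for tests and worked examples; analyses of real invoices should load the
official ECB and BLS series from user-supplied CSVs with the same schema.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd

from .errors import ConversionLookupError, DataError

TARGET_PERIOD = "2022Q4"


@dataclass(frozen=True)
class ConversionTables:
    """Annual-average FX rates and CPI indices with a fixed target period.

    ``fx`` maps calendar year to local-currency units per USD for
    ``fx_currency``; ``cpi`` maps a period label (``"YYYY"`` annual average
    or ``"YYYYQn"``) to the index value.
    """

    fx: Mapping[int, float]
    cpi: Mapping[str, float]
    fx_currency: str = "TRY"
    target_period: str = TARGET_PERIOD

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.fx.values()):
            raise DataError("all FX rates must be positive")
        if any(i <= 0 for i in self.cpi.values()):
            raise DataError("all CPI indices must be positive")
        if self.target_period not in self.cpi:
            raise DataError(
                f"target period {self.target_period} missing from CPI table"
            )


def conversion_factor(year: int, tables: ConversionTables) -> float:
    """Multiplicative factor turning a local amount into same-year USD."""
    try:
        rate = tables.fx[year]
    except KeyError:
        raise ConversionLookupError(
            f"no FX rate for year {year} ({tables.fx_currency} per USD)"
        ) from None
    return 1.0 / rate


def inflate_to_target(usd_amount: float, year: int, tables: ConversionTables) -> float:
    """Restate a same-year USD amount in target-period purchasing power."""
    key = str(year)
    if key not in tables.cpi:
        raise ConversionLookupError(f"no CPI index for period {key}")
    return usd_amount * tables.cpi[tables.target_period] / tables.cpi[key]


def convert_amount(
    amount: float, currency: str, year: int, tables: ConversionTables
) -> float:
    """Full pipeline: local currency in ``year`` → USD in the target period.

    USD amounts skip the FX step; any currency other than USD or the
    tables' local currency is rejected.
    """
    if currency == "USD":
        usd = amount
    elif currency == tables.fx_currency:
        usd = amount * conversion_factor(year, tables)
    else:
        raise ConversionLookupError(
            f"no FX table for currency {currency!r} "
            f"(tables cover {tables.fx_currency})"
        )
    return inflate_to_target(usd, year, tables)


def load_fx(path: str | Path) -> dict[int, float]:
    """Read an FX CSV with exactly the columns ``year, rate``."""
    df = pd.read_csv(path)
    if list(df.columns) != ["year", "rate"]:
        raise DataError(f"{path}: FX table must have columns year,rate")
    if df["rate"].le(0).any() or df["year"].isna().any():
        raise DataError(f"{path}: FX rates must be positive with valid years")
    return {int(y): float(r) for y, r in zip(df["year"], df["rate"])}


def load_cpi(path: str | Path) -> dict[str, float]:
    """Read a CPI CSV with exactly the columns ``period, index``."""
    df = pd.read_csv(path, dtype={"period": str})
    if list(df.columns) != ["period", "index"]:
        raise DataError(f"{path}: CPI table must have columns period,index")
    if df["index"].le(0).any():
        raise DataError(f"{path}: CPI indices must be positive")
    return {str(p): float(i) for p, i in zip(df["period"], df["index"])}


def load_tables(
    fx_path: str | Path, cpi_path: str | Path, fx_currency: str = "TRY"
) -> ConversionTables:
    return ConversionTables(
        fx=load_fx(fx_path), cpi=load_cpi(cpi_path), fx_currency=fx_currency
    )


def packaged_tables() -> ConversionTables:
    """The example TRY/USD FX and CPI-U tables shipped with the package."""
    data = resources.files("handcost") / "data"
    return load_tables(data / "fx_try_usd.csv", data / "cpi_us.csv")
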