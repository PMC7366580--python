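"""Monthly dispensing ledger -> annual realised utilisation.

Emulates the structure of a community drugs-scheme prescription database:
one row per drug per calendar month with the quantity dispensed and the
expenditure valued at the publicly available list price (rebates, fees and
VAT are out of scope). Realised "drug years" are rolling 12-month windows
anchored at the month of reimbursement — the first month with nonzero
dispensing unless a start is declared — not calendar years; a calendar
mode is available for sensitivity checks. Windows that run past the end
of the analysis period are masked as partial rather than silently summed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

LEDGER_COLUMNS = ["drug_id", "month", "quantity_packs", "expenditure_list_price"]


class LedgerError(ValueError):
    """Malformed dispensing ledger (bad month, negative value, ...)."""


@dataclass
class RealisedSeries:
    """Annual realised utilisation for one drug, anchored at launch.

    ``per_year_realised[y]`` sums list-price expenditure over months
    12*y .. 12*y+11 after ``reimbursement_start`` (half-open month
    windows); ``full_year_mask[y]`` is False where the window is not fully
    covered by the analysis period.
    """

    drug_id: str
    reimbursement_start: Optional[pd.Period]
    per_year_realised: list[float] = field(default_factory=list)
    full_year_mask: list[bool] = field(default_factory=list)

    def full_years(self) -> int:
        return int(sum(self.full_year_mask))


def read_dispensing(path: Union[str, Path]) -> pd.DataFrame:
    """Read and validate a monthly dispensing CSV.

    Expects header columns drug_id, month (ISO year-month), quantity_packs,
    expenditure_list_price. Duplicate drug-months are summed. Malformed
    months or negative quantities/expenditures raise :class:`LedgerError`
    naming the offending row (1-based, excluding the header).
    """
    df = pd.read_csv(path, dtype={"drug_id": str, "month": str})
    missing = [c for c in LEDGER_COLUMNS if c not in df.columns]
    if missing:
        raise LedgerError(f"ledger is missing columns: {missing}")
    df = df[LEDGER_COLUMNS]
    if df.empty:
        return df.assign(month=pd.PeriodIndex([], freq="M"))

    months = pd.PeriodIndex(
        pd.to_datetime(df["month"], format="%Y-%m", errors="coerce"), freq="M"
    )
    bad = np.flatnonzero(months.isna())
    if bad.size:
        raise LedgerError(
            f"row {bad[0] + 1}: malformed month {df['month'].iloc[bad[0]]!r} "
            "(expected YYYY-MM)"
        )
    for col in ("quantity_packs", "expenditure_list_price"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(vals.isna() | (vals < 0))
        if bad.size:
            raise LedgerError(
                f"row {bad[0] + 1}: {col} must be a nonnegative number, "
                f"got {df[col].iloc[bad[0]]!r}"
            )
        df[col] = vals
    df = df.assign(month=months)
    return (
        df.groupby(["drug_id", "month"], as_index=False)[
            ["quantity_packs", "expenditure_list_price"]
        ]
        .sum()
        .sort_values(["drug_id", "month"], ignore_index=True)
    )


def write_dispensing(df: pd.DataFrame, path: Union[str, Path]) -> None:
    out = df.copy()
    out["month"] = out["month"].astype(str)
    out.to_csv(path, index=False)


def annual_realised(
    records: pd.DataFrame,
    drug_id: str,
    start_month: Optional[Union[str, pd.Period]] = None,
    horizon: int = 5,
    analysis_end_month: Optional[Union[str, pd.Period]] = None,
    year_mode: str = "anchored",
) -> RealisedSeries:
    """Aggregate one drug's ledger rows into annual realised utilisation.

    Sums list-price expenditure over up to ``horizon`` consecutive
    12-month windows starting from the month of reimbursement (the first
    month with nonzero dispensing when ``start_month`` is not declared).
    Windows extending past ``analysis_end_month`` (default: the last month
    in the ledger) are masked as partial. ``year_mode='calendar'`` anchors
    windows at the January of the launch year instead.

    An unknown drug yields an empty series, not an error — absence from a
    claims database is data, not a malfunction.
    """
    sub = records[records["drug_id"] == drug_id]
    if start_month is not None:
        start = pd.Period(start_month, freq="M")
    else:
        nz = sub[(sub["quantity_packs"] > 0) | (sub["expenditure_list_price"] > 0)]
        if nz.empty:
            return RealisedSeries(drug_id=drug_id, reimbursement_start=None)
        start = nz["month"].min()
    if year_mode == "calendar":
        start = pd.Period(freq="M", year=start.year, month=1)
    elif year_mode != "anchored":
        raise ValueError(f"unknown year_mode {year_mode!r}")

    if analysis_end_month is not None:
        end = pd.Period(analysis_end_month, freq="M")
    elif not records.empty:
        end = records["month"].max()
    else:
        end = start - 1
    if start > end:
        raise ValueError(
            f"start_month {start} is after analysis_end_month {end}"
        )

    realised: list[float] = []
    mask: list[bool] = []
    for y in range(horizon):
        w0, w1 = start + 12 * y, start + 12 * y + 11  # inclusive month span
        if w0 > end:
            break
        window = sub[(sub["month"] >= w0) & (sub["month"] <= w1)]
        realised.append(float(window["expenditure_list_price"].sum()))
        mask.append(w1 <= end)
    return RealisedSeries(
        drug_id=drug_id,
        reimbursement_start=start,
        per_year_realised=realised,
        full_year_mask=mask,
    )
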