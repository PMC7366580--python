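"""Predicted vs realised utilisation: prediction errors and PSA coverage.

The headline comparison is a signed annual percentage,

    error% = (realised - predicted) / predicted * 100,

so a positive value is a model *under*prediction (reality exceeded the
forecast, unbounded above) and a negative value an *over*prediction
(bounded below by -100%, reached only when nothing was dispensed at all).
Drugs are classified by the signs of their yearly errors, with a
strict-majority rule to put mixed drugs on one side of the under/over
ledger.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .psa import CoverageStatus, YearStatus


class InsufficientDataError(ValueError):
    """No unmasked drug-years to classify or summarise."""


@dataclass
class AccuracyRow:
    drug_id: str
    per_year_error_pct: list[Optional[float]]  # None where no full year
    classification: str  # overpredicted_all_years | underpredicted_all_years | mixed
    majority_classification: str  # under | over | tied


def prediction_error_pct(
    predicted: float, realised: float, formula: str = "relative_to_predicted"
) -> float:
    """Signed annual prediction error in percent (positive = underprediction).

    The default formula is (realised - predicted) / predicted * 100. The
    literal "predicted as a percentage of realised" variant is available as
    ``formula='predicted_share_of_realised'`` for sensitivity checks; note
    it is bounded above by 100% and cannot express errors like +1017%.
    """
    if predicted <= 0:
        raise ValueError("prediction error is undefined for predicted <= 0")
    if realised < 0:
        raise ValueError("realised utilisation cannot be negative")
    if formula == "relative_to_predicted":
        return (realised - predicted) / predicted * 100.0
    if formula == "predicted_share_of_realised":
        if realised == 0:
            raise ValueError("predicted_share_of_realised undefined for realised = 0")
        return (realised - predicted) / realised * 100.0
    raise ValueError(f"unknown formula {formula!r}")


def classify_drug(drug_id: str, errors: Sequence[Optional[float]]) -> AccuracyRow:
    """Classify a drug from its yearly signed errors (None = no full year).

    All unmasked years negative -> overpredicted_all_years; all positive ->
    underpredicted_all_years; otherwise mixed. The majority label follows
    the sign held by a strict majority of unmasked years (zeros count to
    neither side); 'tied' when neither side has one.
    """
    vals = [e for e in errors if e is not None]
    if not vals:
        raise InsufficientDataError(f"{drug_id}: no unmasked years to classify")
    n_under = sum(e > 0 for e in vals)
    n_over = sum(e < 0 for e in vals)
    if n_over == len(vals):
        cls = "overpredicted_all_years"
    elif n_under == len(vals):
        cls = "underpredicted_all_years"
    else:
        cls = "mixed"
    if n_under > n_over:
        majority = "under"
    elif n_over > n_under:
        majority = "over"
    else:
        majority = "tied"
    return AccuracyRow(
        drug_id=drug_id,
        per_year_error_pct=list(errors),
        classification=cls,
        majority_classification=majority,
    )


def accuracy_table(
    rows: Iterable[tuple[str, Sequence[Optional[float]]]]
) -> list[AccuracyRow]:
    return [classify_drug(d, e) for d, e in rows]


def summarize_extremes(rows: Iterable[AccuracyRow]) -> tuple[float, float]:
    """(most negative, most positive) error % over all drugs and years."""
    vals = [e for r in rows for e in r.per_year_error_pct if e is not None]
    if not vals:
        raise InsufficientDataError("no unmasked drug-years to summarise")
    return (float(min(vals)), float(max(vals)))


def coverage_summary(statuses: Iterable[CoverageStatus]) -> int:
    """Count drugs whose every available year sits inside the PSA bounds."""
    statuses = list(statuses)
    if not statuses:
        raise InsufficientDataError("empty coverage table")
    return sum(s.all_available_inside() for s in statuses)


def accuracy_frame(rows: Iterable[AccuracyRow], horizon: int = 5) -> pd.DataFrame:
    """Tidy table of yearly errors and classifications, one row per drug."""
    recs = []
    for r in rows:
        rec = {"drug_id": r.drug_id}
        for y in range(horizon):
            e = r.per_year_error_pct[y] if y < len(r.per_year_error_pct) else None
            rec[f"year_{y + 1}_error_pct"] = np.nan if e is None else e
        rec["classification"] = r.classification
        rec["majority"] = r.majority_classification
        recs.append(rec)
    return pd.DataFrame(recs)
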