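"""End-to-end validation of a portfolio: predicted vs realised vs PSA.

Glue over the module surfaces: for each drug, evaluate the deterministic
gross budget impact, aggregate its dispensing ledger into annual realised
utilisation from the month of reimbursement, compute yearly prediction
errors, run the PSA and classify coverage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import pandas as pd

from .accuracy import AccuracyRow, classify_drug, prediction_error_pct
from .ledger import RealisedSeries, annual_realised
from .model_core import ModelSpec, gross_budget_impact
from .psa import CoverageStatus, PsaConfig, classify_coverage, run_psa


@dataclass
class DrugValidation:
    drug_id: str
    predicted: list[float]
    realised: RealisedSeries
    accuracy: AccuracyRow
    coverage: CoverageStatus


def validate_drug(
    spec: ModelSpec,
    records: pd.DataFrame,
    psa_config: Optional[PsaConfig] = None,
    start_month: Optional[Union[str, pd.Period]] = None,
    analysis_end_month: Optional[Union[str, pd.Period]] = None,
) -> DrugValidation:
    predicted = gross_budget_impact(spec).per_year_cost
    realised = annual_realised(
        records,
        spec.drug_id,
        start_month=start_month,
        horizon=spec.horizon_years,
        analysis_end_month=analysis_end_month,
    )
    errors: list[Optional[float]] = []
    for y in range(spec.horizon_years):
        full = y < len(realised.per_year_realised) and realised.full_year_mask[y]
        errors.append(
            prediction_error_pct(predicted[y], realised.per_year_realised[y])
            if full
            else None
        )
    accuracy = classify_drug(spec.drug_id, errors)
    psa = run_psa(spec, psa_config)
    coverage = classify_coverage(psa, realised)
    return DrugValidation(
        drug_id=spec.drug_id,
        predicted=predicted,
        realised=realised,
        accuracy=accuracy,
        coverage=coverage,
    )


def validate_portfolio(
    specs: Sequence[ModelSpec],
    records: pd.DataFrame,
    psa_config: Optional[PsaConfig] = None,
    **kwargs,
) -> list[DrugValidation]:
    return [validate_drug(s, records, psa_config, **kwargs) for s in specs]
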