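"""Bundled reference tables from a national HTA agency retrospective.

Twelve anonymised single-indication drugs (A-L) whose submitted gross
budget-impact models were recreated and compared against community
claims-scheme dispensing at list price: the yearly signed prediction
errors, the per-category parameter counts and modelling-feature flags of
each model, the yearly inside/outside-PSA-bounds statuses, and the
selection flow that reduced 113 assessments to the 12 analysed.

These are published summary tables, not raw data — the underlying models
and claims are confidential — so they serve as worked-example fixtures:
the census, accuracy and coverage operations recompute the retrospective's
headline counts from them. Note one internal quirk, preserved as printed:
drug H has three available prediction-error years but four coverage
statuses.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .accuracy import AccuracyRow, accuracy_table
from .psa import CoverageStatus, YearStatus

HORIZON = 5


def _load(name: str) -> pd.DataFrame:
    with resources.files("biaval.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_prediction_errors() -> pd.DataFrame:
    """Long table (drug_id, year, error_pct); positive = underprediction."""
    return _load("prediction_errors.csv")


def load_parameter_counts() -> pd.DataFrame:
    """Per-drug parameter counts by category (census-row layout)."""
    return _load("parameter_counts.csv")


def load_modelling_features() -> pd.DataFrame:
    """Per-drug boolean flags for the six optional modelling features."""
    return _load("modelling_features.csv")


def load_psa_coverage() -> pd.DataFrame:
    """Long table (drug_id, year, status) of PSA coverage outcomes."""
    return _load("psa_coverage.csv")


def load_selection_flow() -> pd.DataFrame:
    """Selection flow counts: identified, per-reason exclusions, included."""
    return _load("selection_flow.csv")


def reference_accuracy_rows() -> list[AccuracyRow]:
    """The prediction-error table as classified AccuracyRow objects."""
    df = load_prediction_errors()
    rows = []
    for drug, grp in df.groupby("drug_id", sort=True):
        errors: list[float | None] = [None] * HORIZON
        for _, r in grp.iterrows():
            errors[int(r["year"]) - 1] = float(r["error_pct"])
        rows.append((str(drug), errors))
    return accuracy_table(rows)


def reference_coverage() -> list[CoverageStatus]:
    """The coverage table as CoverageStatus objects (N/A where unprinted)."""
    df = load_psa_coverage()
    out = []
    for drug, grp in df.groupby("drug_id", sort=True):
        per_year = [YearStatus.NOT_AVAILABLE] * HORIZON
        for _, r in grp.iterrows():
            per_year[int(r["year"]) - 1] = YearStatus(r["status"])
        out.append(CoverageStatus(drug_id=str(drug), per_year=per_year))
    return out
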