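"""HTA selection rules and parameter/feature censuses.

A registry of health technology assessments is filtered down to the
analysable set: a usable submission must come with a budget-impact model,
concern a single indication (community dispensing data carry no indication
field, so multi-indication drugs cannot be attributed), have been
reimbursed for at least one full year, and be observable in the community
claims database at all (hospital-only drugs and hepatitis C indications
are not captured). Each excluded record is tallied under exactly one
reason, assigned first-match in a fixed order; the surviving set is
independent of that order because every rule depends only on the record.

The censuses count, per included drug, the number of model parameters in
each of the four categories and which of the six optional modelling
features the model includes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .model_core import FeatureFlags, ModelSpec

#: Fixed first-match order in which exclusion reasons are assigned.
EXCLUSION_ORDER = (
    "no_bim",
    "multiple_indications",
    "not_reimbursed_full_year",
    "hospital_only",
    "hepatitis_c",
)

FEATURE_FIELDS = (
    "incidence",
    "prevalence",
    "population_growth",
    "adherence",
    "discontinuation",
    "duration_of_treatment",
)

CATEGORY_FIELDS = ("population", "market_share", "dosage", "acquisition_cost")

#: Months of reimbursement required to count as "a full year".
FULL_YEAR_MONTHS = 12


class HtaRecord(BaseModel):
    model_config = ConfigDict(extra="forbid")

    hta_id: str
    has_budget_impact_model: bool = True
    n_indications: int = Field(default=1, ge=1)
    reimbursed: bool = True
    months_reimbursed: int = Field(default=0, ge=0)
    hospital_only: bool = False
    hepatitis_c_indication: bool = False

    @model_validator(mode="after")
    def _no_phantom_months(self):
        if not self.reimbursed and self.months_reimbursed != 0:
            raise ValueError("months_reimbursed must be 0 when not reimbursed")
        return self

    def exclusion_reason(self) -> str | None:
        """First matching exclusion reason, or None if includable."""
        if not self.has_budget_impact_model:
            return "no_bim"
        if self.n_indications > 1:
            return "multiple_indications"
        if not self.reimbursed or self.months_reimbursed < FULL_YEAR_MONTHS:
            return "not_reimbursed_full_year"
        if self.hospital_only:
            return "hospital_only"
        if self.hepatitis_c_indication:
            return "hepatitis_c"
        return None


@dataclass
class ExclusionTally:
    counts: dict[str, int]
    n_included: int
    n_total: int


def apply_exclusions(registry: Sequence[HtaRecord]) -> tuple[list[HtaRecord], ExclusionTally]:
    """Filter a registry; return the included records and a reason tally.

    Every record is counted exactly once: under its first matching
    exclusion reason (in :data:`EXCLUSION_ORDER`) or as included, so
    n_included + sum(reason counts) = n_total always.
    """
    if not registry:
        raise ValueError("registry is empty")
    counts = {r: 0 for r in EXCLUSION_ORDER}
    included = []
    for rec in registry:
        reason = rec.exclusion_reason()
        if reason is None:
            included.append(rec)
        else:
            counts[reason] += 1
    tally = ExclusionTally(counts=counts, n_included=len(included), n_total=len(registry))
    return included, tally


def read_registry(path) -> list[HtaRecord]:
    """Read an HTA registry CSV (one column per HtaRecord field)."""
    df = pd.read_csv(path, dtype={"hta_id": str})
    return [HtaRecord.model_validate(row) for row in df.to_dict(orient="records")]


def write_registry(registry: Iterable[HtaRecord], path) -> None:
    pd.DataFrame([r.model_dump() for r in registry]).to_csv(path, index=False)


def exclusion_flow_frame(tally: ExclusionTally) -> pd.DataFrame:
    """The selection flow as a table (identified -> per-reason -> included)."""
    rows = [{"stage": "identified", "n": tally.n_total}]
    rows += [{"stage": f"excluded_{r}", "n": tally.counts[r]} for r in EXCLUSION_ORDER]
    rows.append({"stage": "included", "n": tally.n_included})
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# censuses
# ----------------------------------------------------------------------

def census_rows(specs: Sequence[ModelSpec]) -> pd.DataFrame:
    """Per-drug parameter counts by category plus feature flags.

    One row per spec: n_population, n_market_share, n_dosage,
    n_acquisition_cost (counted from the spec's flattened Parameter
    records) and the six boolean feature columns.
    """
    if not specs:
        raise ValueError("no specs to census")
    recs = []
    for spec in specs:
        counts = {c: 0 for c in CATEGORY_FIELDS}
        for p in spec.parameters():
            counts[p.category] += 1
        rec = {"drug_id": spec.drug_id}
        rec.update({f"n_{c}": counts[c] for c in CATEGORY_FIELDS})
        rec.update({f: getattr(spec.features, f) for f in FEATURE_FIELDS})
        recs.append(rec)
    return pd.DataFrame(recs)


def summarize_parameter_census(rows: pd.DataFrame) -> pd.DataFrame:
    """Min/max/mode of the per-category parameter counts over drugs."""
    out = []
    for c in CATEGORY_FIELDS:
        col = rows[f"n_{c}"]
        out.append(
            {
                "category": c,
                "min": int(col.min()),
                "max": int(col.max()),
                "mode": int(col.mode().iloc[0]),
            }
        )
    return pd.DataFrame(out)


def parameter_census(specs: Sequence[ModelSpec]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(per-drug census rows, per-category min/max/mode summary)."""
    rows = census_rows(specs)
    return rows, summarize_parameter_census(rows)


def feature_counts(rows: pd.DataFrame) -> pd.Series:
    """How many drugs include each optional modelling feature."""
    return rows[list(FEATURE_FIELDS)].sum().astype(int)


def feature_census(specs: Sequence[ModelSpec]) -> pd.Series:
    return feature_counts(census_rows(specs))
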