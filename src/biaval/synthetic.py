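"""Synthetic inputs with the statistical structure the pipeline assumes.

Real applicant submissions and claims extracts are confidential, so every
input the validation pipeline needs can be generated here instead:

* applicant-style :class:`~biaval.model_core.ModelSpec`s whose
  parameter-count and modelling-feature profiles match the observed
  distribution across submitted models (see :class:`SpecProfile`);
* monthly dispensing ledgers equal to each model's own predictions
  perturbed by a configurable multiplicative forecast-error model
  (:class:`ErrorModel`) — the error is annual and lognormal, because the
  validation comparisons are annual and utilisation errors are
  scale-multiplicative; the monthly spread is presentation only;
* HTA registries with prescribed exclusion-reason counts.

With sigma = 0 and bias = 1 the generated "reality" equals the model's
prediction exactly, which gives the pipeline its end-to-end null test:
0% error every full year and full PSA coverage.
"""

from __future__ import annotations

from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .census import EXCLUSION_ORDER, HtaRecord
from .model_core import (
    FeatureFlags,
    ModelSpec,
    Parameter,
    effective_unit_price,
    gross_budget_impact,
)

_PACK_SIZES = (7.0, 14.0, 28.0, 30.0, 56.0, 60.0, 90.0, 100.0)


class ErrorModel(BaseModel):
    """Annual multiplicative forecast error: realised = predicted x bias x e,
    e ~ lognormal(0, sigma). sigma = 0 and bias = 1 reproduce the
    prediction exactly; bias b with sigma 0 gives a (b-1)x100% error in
    every year."""

    model_config = ConfigDict(extra="forbid")

    sigma: float = Field(default=0.5, ge=0)
    bias: float = Field(default=1.0, gt=0)
    seed: int = 0


class CountRange(BaseModel):
    model_config = ConfigDict(extra="forbid")
    low: int = Field(ge=0)
    high: int = Field(ge=0)

    @model_validator(mode="after")
    def _ordered(self):
        if self.low > self.high:
            raise ValueError("count range must have low <= high")
        return self


class SpecProfile(BaseModel):
    """Distributional profile a generated spec portfolio should follow.

    Defaults reproduce the observed census across twelve submitted models:
    parameter counts of 3-91 (population), 5-30 (market share, with five —
    one per horizon year — the most common), 1-4 (dosage) and 1-3
    (acquisition cost), and feature marginals prevalence 12/12, population
    growth 8/12, incidence 6/12, duration of treatment 3/12,
    discontinuation 2/12, adherence 1/12.
    """

    model_config = ConfigDict(extra="forbid")

    population_count: CountRange = CountRange(low=3, high=91)
    market_share_count: CountRange = CountRange(low=5, high=30)
    dosage_count: CountRange = CountRange(low=1, high=4)
    acquisition_cost_count: CountRange = CountRange(low=1, high=3)

    p_incidence: float = Field(default=6 / 12, ge=0, le=1)
    p_prevalence: float = Field(default=1.0, ge=0, le=1)
    p_population_growth: float = Field(default=8 / 12, ge=0, le=1)
    p_adherence: float = Field(default=1 / 12, ge=0, le=1)
    p_discontinuation: float = Field(default=2 / 12, ge=0, le=1)
    p_duration: float = Field(default=3 / 12, ge=0, le=1)

    #: probability the market-share count is exactly one-per-year
    p_share_count_minimal: float = Field(default=2 / 3, ge=0, le=1)

    horizon_years: int = Field(default=5, ge=1)
    seed: int = 0


def _loguniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def _draw_count(rng: np.random.Generator, cr: CountRange, floor: int) -> int:
    lo = max(cr.low, floor)
    hi = max(cr.high, lo)
    return int(rng.integers(lo, hi + 1))


def generate_spec(
    profile: SpecProfile,
    drug_id: str = "SYN-A",
    seed: Optional[int] = None,
) -> ModelSpec:
    """Draw one applicant-style model spec from the profile.

    Feature flags come from the profile's marginals (with prevalence
    forced on if neither source population was drawn); numeric values from
    broad launch-realistic ranges (prevalent pools 100-100 000 persons,
    uptake ramping from ~1-10% to at most 50% over the horizon, pack list
    prices 10-10 000); and per-category parameter counts inside the
    profile's ranges, realised as extra multiplicative factor parameters
    beyond the engine's structural fields. Reproducible for a fixed seed
    (defaults to the profile's).
    """
    rng = np.random.default_rng(profile.seed if seed is None else seed)
    h = profile.horizon_years

    flags = FeatureFlags.model_construct(
        incidence=bool(rng.random() < profile.p_incidence),
        prevalence=bool(rng.random() < profile.p_prevalence),
        population_growth=bool(rng.random() < profile.p_population_growth),
        adherence=bool(rng.random() < profile.p_adherence),
        discontinuation=bool(rng.random() < profile.p_discontinuation),
        duration_of_treatment=bool(rng.random() < profile.p_duration),
    )
    if not (flags.incidence or flags.prevalence):
        flags = flags.model_copy(update={"prevalence": True})

    share_start = rng.uniform(0.01, 0.10)
    share_end = rng.uniform(share_start, 0.50)
    market_share = np.linspace(share_start, share_end, h).tolist()

    n_pop = _draw_count(rng, profile.population_count,
                        1 + flags.incidence + flags.population_growth)
    if rng.random() < profile.p_share_count_minimal:
        n_share = max(profile.market_share_count.low, h)
    else:
        n_share = _draw_count(rng, profile.market_share_count, h)
    n_dose = _draw_count(rng, profile.dosage_count, 2 + flags.adherence)
    n_cost = _draw_count(rng, profile.acquisition_cost_count, 1)

    def factors(n: int, category: str, lo: float, hi: float, stem: str):
        return [
            Parameter(name=f"{stem}_{i + 1}", category=category,
                      value=float(rng.uniform(lo, hi)))
            for i in range(n)
        ]

    base_pop = 1 + flags.incidence + flags.population_growth
    base_share = h
    base_dose = 2 + flags.adherence

    # Applicant population blocks work top-down (a large source population
    # cut by many eligibility fractions), so draw the year-1 eligible
    # population target and back-solve the source pool through the factors.
    pop_factors = factors(n_pop - base_pop, "population", 0.50, 1.00,
                          "eligibility_fraction")
    eligible_target = _loguniform(rng, 100, 100_000)
    source = eligible_target / float(np.prod([p.value for p in pop_factors]))
    if flags.prevalence and flags.incidence:
        w = float(rng.uniform(0.5, 0.95))
    else:
        w = 1.0 if flags.prevalence else 0.0
    return ModelSpec(
        drug_id=drug_id,
        horizon_years=h,
        features=flags,
        prevalent_pool=source * w,
        incident_inflow=source * (1.0 - w),
        growth_rate=float(rng.uniform(0.0, 0.10)) if flags.population_growth else 0.0,
        market_share=market_share,
        adherence=float(rng.uniform(0.70, 0.95)) if flags.adherence else 1.0,
        discontinuation_rate=(
            float(rng.uniform(0.05, 0.30)) if flags.discontinuation else 0.0
        ),
        max_duration_years=(
            int(rng.integers(1, h + 1)) if flags.duration_of_treatment else None
        ),
        units_per_day=_loguniform(rng, 0.25, 4.0),
        pack_size=float(rng.choice(_PACK_SIZES)),
        list_price=_loguniform(rng, 10, 10_000),
        extra_population_factors=pop_factors,
        extra_share_factors=factors(
            n_share - base_share, "market_share", 0.90, 1.00, "switching_fraction"
        ),
        extra_dosage_factors=factors(
            n_dose - base_dose, "dosage", 0.90, 1.10, "dose_adjustment"
        ),
        extra_cost_factors=factors(
            n_cost - 1, "acquisition_cost", 0.95, 1.05, "cost_adjustment"
        ),
    )


def generate_portfolio(
    profile: SpecProfile, n_drugs: int, id_prefix: str = "SYN"
) -> list[ModelSpec]:
    """Draw ``n_drugs`` independent specs with substream seeds."""
    ss = np.random.SeedSequence(profile.seed).spawn(n_drugs)
    return [
        generate_spec(profile, drug_id=f"{id_prefix}-{i + 1:02d}",
                      seed=int(s.generate_state(1)[0] & 0x7FFFFFFF))
        for i, s in enumerate(ss)
    ]


def _monthly_weights(ramp: str) -> np.ndarray:
    if ramp == "linear":
        w = np.arange(1, 13, dtype=float)
    elif ramp == "flat":
        w = np.ones(12)
    else:
        raise ValueError(f"unknown ramp {ramp!r}")
    return w / w.sum()


def generate_dispensing(
    spec: ModelSpec,
    error: ErrorModel,
    start_month: Union[str, pd.Period] = "2012-01",
    months_available: int = 60,
    ramp: str = "linear",
) -> pd.DataFrame:
    """Simulate a monthly dispensing ledger for one drug.

    True annual utilisation is the model's own per-year gross cost times
    the error model's bias and a per-year lognormal(0, sigma) draw. Each
    year's total is spread over its 12 months — linearly ramping from
    launch in year 1 (uptake builds over the first year), flat thereafter —
    and the series is truncated at ``months_available``. Monthly
    expenditures sum to the perturbed annual totals.
    """
    if months_available < 1:
        raise ValueError("months_available must be >= 1")
    rng = np.random.default_rng(error.seed)
    start = pd.Period(start_month, freq="M")
    cost = np.asarray(gross_budget_impact(spec).per_year_cost)
    noise = np.exp(error.sigma * rng.standard_normal(len(cost)))
    annual = cost * error.bias * noise
    unit_price = effective_unit_price(spec)

    rows = []
    for y, total in enumerate(annual):
        weights = _monthly_weights(ramp if y == 0 else "flat")
        for m in range(12):
            idx = 12 * y + m
            if idx >= months_available:
                break
            spend = float(total * weights[m])
            rows.append(
                {
                    "drug_id": spec.drug_id,
                    "month": start + idx,
                    "quantity_packs": spend / unit_price,
                    "expenditure_list_price": spend,
                }
            )
    return pd.DataFrame(rows, columns=["drug_id", "month", "quantity_packs",
                                       "expenditure_list_price"])


def generate_registry(
    total: int,
    reason_counts: dict[str, int],
    seed: int = 0,
) -> list[HtaRecord]:
    """Build a registry with prescribed per-reason exclusion counts.

    Each excluded record carries exactly one triggering attribute, so the
    first-match tally reproduces the requested counts and the remaining
    ``total - sum(counts)`` records are includable.
    """
    unknown = set(reason_counts) - set(EXCLUSION_ORDER)
    if unknown:
        raise ValueError(f"unknown exclusion reasons: {sorted(unknown)}")
    counts = {r: int(reason_counts.get(r, 0)) for r in EXCLUSION_ORDER}
    if any(c < 0 for c in counts.values()):
        raise ValueError("reason counts must be nonnegative")
    n_excluded = sum(counts.values())
    if n_excluded > total:
        raise ValueError(
            f"requested {n_excluded} exclusions from a registry of {total}"
        )
    rng = np.random.default_rng(seed)

    def base(i: int) -> dict:
        return {
            "hta_id": f"HTA-{i + 1:03d}",
            "has_budget_impact_model": True,
            "n_indications": 1,
            "reimbursed": True,
            "months_reimbursed": int(rng.integers(12, 61)),
            "hospital_only": False,
            "hepatitis_c_indication": False,
        }

    records = []
    i = 0
    for reason, n in counts.items():
        for _ in range(n):
            rec = base(i)
            if reason == "no_bim":
                rec["has_budget_impact_model"] = False
            elif reason == "multiple_indications":
                rec["n_indications"] = int(rng.integers(2, 5))
            elif reason == "not_reimbursed_full_year":
                if rng.random() < 0.5:
                    rec["reimbursed"] = False
                    rec["months_reimbursed"] = 0
                else:
                    rec["months_reimbursed"] = int(rng.integers(1, 12))
            elif reason == "hospital_only":
                rec["hospital_only"] = True
            elif reason == "hepatitis_c":
                rec["hepatitis_c_indication"] = True
            records.append(HtaRecord(**rec))
            i += 1
    for _ in range(total - n_excluded):
        records.append(HtaRecord(**base(i)))
        i += 1
    rng.shuffle(records)  # registry order carries no information
    return records
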