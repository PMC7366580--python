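"""Monte-Carlo probabilistic sensitivity analysis (PSA) over a ModelSpec.

Every uncertain parameter is perturbed independently around its point value
on a +/- `range_fraction` support (default 20%), by default with a uniform
distribution — a deliberately flat choice given how little is known about
where the truth sits in the interval. The agreed list price is the one
parameter that is never varied unless explicitly requested. 1000 draws are
taken by default and summarised by the element-wise minimum, mean and
maximum of the simulated annual costs; realised utilisation is then
classified per year as inside or outside the [min, max] envelope.

Draws use deterministic per-draw substreams derived from one global seed,
so draw i is identical whether 10 or 10 000 simulations are requested.
"""

from __future__ import annotations

from enum import Enum
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import stats

from .model_core import ModelSpec, gross_budget_impact


class PsaConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_simulations: int = Field(default=1000, ge=1)
    range_fraction: float = Field(default=0.20, ge=0)
    distribution: Literal["uniform", "triangular", "normal_truncated"] = "uniform"
    seed: int = 0
    vary_list_price: bool = False
    #: "minmax" mirrors the reference analysis (extremes of the draws);
    #: "percentile" gives central 100*(1-alpha)% bounds instead.
    bound_type: Literal["minmax", "percentile"] = "minmax"
    percentile_alpha: float = Field(default=0.05, gt=0, lt=1)

    @model_validator(mode="after")
    def _positive_support(self):
        if self.range_fraction >= 1 and self.distribution in ("uniform", "triangular"):
            raise ValueError(
                "range_fraction must be < 1 to keep the sampling support positive"
            )
        return self


class PsaResult(BaseModel):
    model_config = ConfigDict(extra="forbid", arbitrary_types_allowed=True)

    drug_id: str
    per_year_draws: np.ndarray  # (n_simulations, horizon)
    per_year_min: list[float]
    per_year_max: list[float]
    per_year_mean: list[float]
    config: PsaConfig
    seed: int


class YearStatus(str, Enum):
    INSIDE = "inside_psa_bounds"
    OUTSIDE = "outside_psa_bounds"
    NOT_AVAILABLE = "not_available"


class CoverageStatus(BaseModel):
    model_config = ConfigDict(extra="forbid")

    drug_id: str
    per_year: list[YearStatus]

    def all_available_inside(self) -> bool:
        """True when every year with data is inside the PSA bounds."""
        available = [s for s in self.per_year if s is not YearStatus.NOT_AVAILABLE]
        return bool(available) and all(s is YearStatus.INSIDE for s in available)


# ----------------------------------------------------------------------

def _draw_factor(rng: np.random.Generator, dist: str, r: float, size: int) -> np.ndarray:
    """Multiplicative perturbation factors on [1-r, 1+r]."""
    if r == 0:
        return np.ones(size)
    if dist == "uniform":
        return rng.uniform(1.0 - r, 1.0 + r, size=size)
    if dist == "triangular":
        return rng.triangular(1.0 - r, 1.0, 1.0 + r, size=size)
    if dist == "normal_truncated":
        # sd chosen so the +/-r support sits at two standard deviations
        sd = r / 2.0
        return stats.truncnorm.rvs(-r / sd, r / sd, loc=1.0, scale=sd,
                                   size=size, random_state=rng)
    raise ValueError(f"unknown distribution {dist!r}")


def _clamp(x: float, lo: float, hi: float) -> float:
    return min(max(x, lo), hi)


def sample_spec(spec: ModelSpec, config: PsaConfig, draw_index: int) -> ModelSpec:
    """Draw one perturbed spec for Monte-Carlo draw ``draw_index``.

    Every parameter flagged for PSA variation is independently multiplied
    by a factor drawn on [1 - range_fraction, 1 + range_fraction]; per-year
    market-share entries are drawn independently. Fractions are clamped
    back to their legal interval afterwards (a share of 0.95 varied by
    +20% is capped at 1.0). The list price is left untouched unless
    ``vary_list_price`` is set.
    """
    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, draw_index])
    r = config.range_fraction
    dist = config.distribution

    n_scalar = 7
    n_share = len(spec.market_share)
    extras = (spec.extra_population_factors, spec.extra_share_factors,
              spec.extra_dosage_factors, spec.extra_cost_factors)
    n_extra = sum(len(e) for e in extras)
    f = _draw_factor(rng, dist, r, n_scalar + n_share + n_extra)
    it = iter(f)

    update: dict = {
        "prevalent_pool": spec.prevalent_pool * next(it),
        "incident_inflow": spec.incident_inflow * next(it),
        "growth_rate": spec.growth_rate * next(it),
        "units_per_day": spec.units_per_day * next(it),
        "pack_size": spec.pack_size * next(it),
        "adherence": _clamp(spec.adherence * next(it), 1e-12, 1.0),
        "discontinuation_rate": _clamp(
            spec.discontinuation_rate * next(it), 0.0, 1.0 - 1e-12
        ),
        "market_share": [
            _clamp(s * next(it), 0.0, 1.0) for s in spec.market_share
        ],
    }
    # neutral values of disabled features stay neutral (0 * factor = 0,
    # clamped adherence of 1 can only shrink — restore it explicitly)
    if not spec.features.adherence:
        update["adherence"] = 1.0
    if config.vary_list_price:
        update["list_price"] = spec.list_price * _draw_factor(rng, dist, r, 1)[0]

    for field, params in zip(
        ("extra_population_factors", "extra_share_factors",
         "extra_dosage_factors", "extra_cost_factors"),
        extras,
    ):
        if not params:
            continue
        fraction = field in ("extra_population_factors", "extra_share_factors")
        new = []
        for p in params:
            v = p.value * next(it) if p.psa_vary else p.value
            if fraction:
                v = _clamp(v, 0.0, 1.0)
            new.append(p.model_copy(update={"value": v}))
        update[field] = new

    return spec.model_copy(update=update)


def run_psa(spec: ModelSpec, config: Optional[PsaConfig] = None) -> PsaResult:
    """Propagate +/-range_fraction parameter uncertainty through the model.

    Evaluates the gross budget impact on ``n_simulations`` independently
    sampled specs and records the element-wise min/mean/max of the annual
    costs (or central percentiles when ``bound_type='percentile'``).
    Reproducible for a fixed seed.
    """
    config = config or PsaConfig()
    draws = np.empty((config.n_simulations, spec.horizon_years))
    for i in range(config.n_simulations):
        draws[i] = gross_budget_impact(sample_spec(spec, config, i)).per_year_cost
    if config.bound_type == "percentile":
        a = config.percentile_alpha
        lo = np.quantile(draws, a / 2, axis=0)
        hi = np.quantile(draws, 1 - a / 2, axis=0)
    else:
        lo = draws.min(axis=0)
        hi = draws.max(axis=0)
    return PsaResult(
        drug_id=spec.drug_id,
        per_year_draws=draws,
        per_year_min=lo.tolist(),
        per_year_max=hi.tolist(),
        per_year_mean=draws.mean(axis=0).tolist(),
        config=config,
        seed=config.seed,
    )


def classify_coverage(psa: PsaResult, realised) -> CoverageStatus:
    """Classify each year's realised utilisation against the PSA envelope.

    Years with a full realised value r are 'inside_psa_bounds' iff
    min <= r <= max (closed interval: sitting exactly on a bound counts as
    captured); otherwise 'outside_psa_bounds'. Years without a full
    12-month realised window are 'not_available'.
    """
    if realised.drug_id != psa.drug_id:
        raise ValueError(
            f"drug mismatch: PSA is for {psa.drug_id!r}, "
            f"realised series for {realised.drug_id!r}"
        )
    horizon = len(psa.per_year_min)
    out = []
    for y in range(horizon):
        if y >= len(realised.per_year_realised) or not realised.full_year_mask[y]:
            out.append(YearStatus.NOT_AVAILABLE)
            continue
        r = realised.per_year_realised[y]
        inside = psa.per_year_min[y] <= r <= psa.per_year_max[y]
        out.append(YearStatus.INSIDE if inside else YearStatus.OUTSIDE)
    return CoverageStatus(drug_id=psa.drug_id, per_year=out)
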