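import pytest

from biaval import FeatureFlags, ModelSpec

#: pack size making one unit/day equal exactly 12 packs per patient-year
TWELVE_PACKS = 365.25 / 12


def make_spec(**overrides) -> ModelSpec:
    """A minimal valid prevalence-only spec; override freely."""
    fields = dict(
        drug_id="X",
        features=FeatureFlags(prevalence=True),
        prevalent_pool=1000.0,
        market_share=[0.1] * 5,
        units_per_day=1.0,
        pack_size=TWELVE_PACKS,
        list_price=100.0,
    )
    fields.update(overrides)
    return ModelSpec(**fields)


@pytest.fixture
def toy_spec() -> ModelSpec:
    """Pool 1000, 10% share, 12 packs/patient-year, price 100."""
    return make_spec()
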