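#!/usr/bin/env python
"""Generate a synthetic study: 12 applicant-style budget-impact models,
their monthly dispensing ledgers under a sigma=0.5 multiplicative forecast
error, and an HTA registry with the reference selection-flow counts.

Writes results/synth/specs/*.json, results/synth/ledger.csv and
results/synth/registry.csv. Downstream drivers regenerate what they need
from seeds, so running this first is informative, not required.
"""

import sys
from pathlib import Path

import pandas as pd

from biaval import ErrorModel, SpecProfile, generate_dispensing, generate_portfolio, generate_registry
from biaval.census import write_registry
from biaval.ledger import write_dispensing

SEED = 20160101
SIGMA = 0.5
OUT = Path(__file__).resolve().parents[1] / "results" / "synth"


def main() -> None:
    profile = SpecProfile(seed=SEED)
    specs = generate_portfolio(profile, 12)
    (OUT / "specs").mkdir(parents=True, exist_ok=True)
    ledgers = []
    for i, spec in enumerate(specs):
        spec.to_json(OUT / "specs" / f"{spec.drug_id}.json")
        err = ErrorModel(sigma=SIGMA, bias=1.0, seed=SEED + i)
        ledgers.append(generate_dispensing(spec, err, months_available=60))
    ledger = pd.concat(ledgers, ignore_index=True)
    write_dispensing(ledger, OUT / "ledger.csv")

    registry = generate_registry(
        113,
        {"no_bim": 21, "multiple_indications": 37, "not_reimbursed_full_year": 28,
         "hospital_only": 10, "hepatitis_c": 5},
        seed=SEED,
    )
    write_registry(registry, OUT / "registry.csv")

    print(f"wrote {len(specs)} model specs, {len(ledger)} ledger rows and "
          f"a registry of {len(registry)} HTAs under {OUT}")


if __name__ == "__main__":
    sys.exit(main())
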