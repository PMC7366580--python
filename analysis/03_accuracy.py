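#!/usr/bin/env python
"""Prediction accuracy of the reference budget-impact models.

Classifies each of the 12 drugs from its yearly signed prediction errors
(positive = underprediction) and reports the portfolio extremes and the
strict-majority under/over split.

Writes results/tables/accuracy_classification.csv and accuracy_summary.csv.
"""

import sys
from pathlib import Path

import pandas as pd

from biaval import summarize_extremes
from biaval.accuracy import accuracy_frame
from biaval.datasets import reference_accuracy_rows

OUT = Path(__file__).resolve().parents[1] / "results" / "tables"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rows = reference_accuracy_rows()
    table = accuracy_frame(rows)
    table.to_csv(OUT / "accuracy_classification.csv", index=False)
    print(table.to_string(index=False))

    lo, hi = summarize_extremes(rows)
    maj = table["majority"].value_counts()
    summary = pd.DataFrame(
        [
            {"quantity": "most_negative_error_pct (worst overprediction)", "value": lo},
            {"quantity": "most_positive_error_pct (worst underprediction)", "value": hi},
            {"quantity": "drugs_overpredicted_all_years",
             "value": (table["classification"] == "overpredicted_all_years").sum()},
            {"quantity": "drugs_underpredicted_all_years",
             "value": (table["classification"] == "underpredicted_all_years").sum()},
            {"quantity": "majority_under", "value": maj.get("under", 0)},
            {"quantity": "majority_over", "value": maj.get("over", 0)},
        ]
    )
    summary.to_csv(OUT / "accuracy_summary.csv", index=False)
    print(f"\nerrors span {lo:+.0f}% to {hi:+.0f}%; "
          f"{maj.get('under', 0)} drugs mostly underpredicted, "
          f"{maj.get('over', 0)} mostly overpredicted")


if __name__ == "__main__":
    sys.exit(main())
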