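#!/usr/bin/env python
"""Build the three per-cancer cellular training sets and validate the cell
classifier by stratified 10-fold cross-validation.

Writes results/cv_report.csv (overall and per-class accuracy per cancer
type) and results/training_sets/<type>.csv.
"""

import sys
from pathlib import Path

import pandas as pd

from tilquant import cross_validate
from tilquant.io import write_training_set
from tilquant.pipeline import build_training_set

OUT = Path("results")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main() -> None:
    (OUT / "training_sets").mkdir(parents=True, exist_ok=True)
    rows = []
    for ct in ["AEGJ", "GAC", "ESCC"]:
        ts = build_training_set(ct, n_per_class=80, seed=SEED)
        write_training_set(ts, OUT / "training_sets" / f"{ct}.csv")
        rep = cross_validate(ts, k=10, seed=SEED)
        row = {
            "cancer_type": ct,
            "n_cells": len(ts.records),
            "overall_accuracy_pct": rep.overall_accuracy,
            **{f"{c}_accuracy_pct": a for c, a in rep.per_class_accuracy.items()},
        }
        rows.append(row)
        print(
            f"{ct}: n={row['n_cells']} overall={rep.overall_accuracy:.2f}%  "
            + "  ".join(f"{c}={a:.1f}%" for c, a in rep.per_class_accuracy.items())
        )
    pd.DataFrame(rows).to_csv(OUT / "cv_report.csv", index=False)
    print(f"wrote {OUT/'cv_report.csv'}")


if __name__ == "__main__":
    main()
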