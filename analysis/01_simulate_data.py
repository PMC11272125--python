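#!/usr/bin/env python
"""Simulate the study's raw materials: H&E-like tumor-section images with
ground-truth nuclei, and a patient cohort whose survival depends on TIL %.

Writes to results/data/: one benchmark slide (PNG + ground-truth CSV) at
three lymphocyte-infiltration levels, and a simulated cohort CSV.
"""

import sys
from pathlib import Path

import imageio.v3 as iio
import pandas as pd

from tilquant import CohortSpec, SlideSpec, generate_cohort, generate_slide
from tilquant.io import write_cohort

OUT = Path("results/data")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    levels = {"low": 0.05, "medium": 0.20, "high": 0.40}
    rows = []
    for name, lf in levels.items():
        spec = SlideSpec(
            width_px=800,
            height_px=800,
            n_nuclei=130,
            class_fractions=(0.6 * (1 - lf), lf, 0.4 * (1 - lf)),
            seed=SEED * 100 + len(name),
        )
        img, gt = generate_slide(spec)
        iio.imwrite(OUT / f"slide_{name}_til.png", img)
        truth = pd.DataFrame(
            {
                "label_id": range(1, len(gt.true_labels) + 1),
                "class": gt.true_labels,
                "row": [c[0] for c in gt.centroids],
                "col": [c[1] for c in gt.centroids],
            }
        )
        truth.to_csv(OUT / f"slide_{name}_til.truth.csv", index=False)
        rows.append({"slide": name, "n_nuclei": 130, "true_til_pct": gt.true_til_proportion})
        print(f"slide_{name}_til.png: true TIL = {gt.true_til_proportion:.2f}%")

    pd.DataFrame(rows).to_csv(OUT / "slides_manifest.csv", index=False)

    cohort = generate_cohort(CohortSpec(n_patients=1200, seed=SEED))
    write_cohort(cohort, OUT / "cohort.csv")
    print(
        f"cohort.csv: n={len(cohort)}, median TIL {cohort['til_pct'].median():.2f}%, "
        f"event fraction {cohort['event'].mean():.3f}"
    )


if __name__ == "__main__":
    main()
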