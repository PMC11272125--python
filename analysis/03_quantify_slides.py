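#!/usr/bin/env python
"""Quantify TIL proportion on a batch of synthetic slides and compare the
estimates with the generator's ground truth.

Uses the AEGJ training set from step 02 (rebuilds it if absent).  Writes
results/slide_results.csv with per-slide counts, estimated and true TIL %,
plus segmentation precision/recall.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from tilquant import SlideSpec, generate_slide, quantify_slide, train_classifier
from tilquant.io import read_training_set
from tilquant.pipeline import build_training_set, segmentation_precision_recall
from tilquant.segmentation import segment_slide

OUT = Path("results")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    ts_path = OUT / "training_sets" / "AEGJ.csv"
    if ts_path.exists():
        ts = read_training_set(ts_path)
    else:
        ts = build_training_set("AEGJ", n_per_class=80, seed=SEED)
    model = train_classifier(ts, seed=SEED)

    rng = np.random.default_rng(SEED)
    rows = []
    for s in range(9):
        lf = [0.05, 0.2, 0.4][s % 3]
        spec = SlideSpec(
            width_px=700,
            height_px=700,
            n_nuclei=100,
            class_fractions=(0.6 * (1 - lf), lf, 0.4 * (1 - lf)),
            seed=int(rng.integers(2**31)),
        )
        img, gt = generate_slide(spec)
        res = quantify_slide(img, model, slide_id=f"slide{s:02d}")
        precision, recall = segmentation_precision_recall(
            segment_slide(img), gt.true_mask
        )
        rows.append(
            {
                "slide_id": res.slide_id,
                "true_til_pct": gt.true_til_proportion,
                "til_pct": res.til_proportion,
                "abs_error_pct": abs(res.til_proportion - gt.true_til_proportion),
                "precision": precision,
                "recall": recall,
                **{f"n_{k}": v for k, v in res.counts.items()},
            }
        )
        print(
            f"{res.slide_id}: true {gt.true_til_proportion:5.2f}%  "
            f"estimated {res.til_proportion:5.2f}%  P={precision:.3f} R={recall:.3f}"
        )
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "slide_results.csv", index=False)
    print(
        f"mean |error| = {df['abs_error_pct'].mean():.2f} points over {len(df)} slides; "
        f"wrote {OUT/'slide_results.csv'}"
    )


if __name__ == "__main__":
    main()
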