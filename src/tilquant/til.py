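"""Slide-level TIL quantification and the high/low median split.

The TIL proportion of a section is the percentage of classified
lymphocytes among all detected cells:  pi = 100 * L / (C + L + S).
Counts are summed over all tiles of the section before dividing.  For
survival analysis a cohort's sections are dichotomised at the cohort
median of pi (ties to the low group).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .classification import ClassifierModel, classify_cells
from .features import DEFAULT_NEIGHBOR_RADIUS, extract_features
from .segmentation import (
    DegenerateImageError,
    SegmentationParams,
    lightness_complement,
    segment_slide,
)
from .synthetic import CLASS_NAMES


class UndefinedProportionError(ValueError):
    """No cells were detected, so the TIL proportion is undefined."""


@dataclass(frozen=True)
class SlideResult:
    """Per-slide class counts and TIL proportion (percent)."""

    slide_id: str
    counts: dict[str, int]
    til_proportion: float

    def __post_init__(self) -> None:
        total = sum(self.counts.values())
        expect = 100.0 * self.counts.get("lymphocyte", 0) / total if total else None
        if expect is not None and abs(expect - self.til_proportion) > 1e-9:
            raise ValueError("til_proportion inconsistent with counts")


@dataclass(frozen=True)
class TILGroups:
    """Median cutoff (percent) and the high/low assignment per slide."""

    cutoff: float
    assignment: dict[str, str]  # slide_id -> "high" | "low"


def til_proportion(counts: dict[str, int]) -> float:
    """pi = 100 * lymphocytes / total detected cells."""
    total = sum(counts.values())
    if total <= 0:
        raise UndefinedProportionError("no cells detected")
    return 100.0 * counts.get("lymphocyte", 0) / total


def quantify_slide(
    img: np.ndarray,
    model: ClassifierModel,
    params: SegmentationParams | None = None,
    slide_id: str = "",
    neighbor_radius_px: float = DEFAULT_NEIGHBOR_RADIUS,
) -> SlideResult:
    """Segment, featurise and classify a section; return counts and pi.

    Deterministic: same image and model give the same result.
    """
    params = params or SegmentationParams()
    labels = segment_slide(img, params)
    if labels.max() == 0:
        raise UndefinedProportionError(f"no cells detected on slide {slide_id!r}")
    gray = lightness_complement(img)
    cells = extract_features(
        labels, gray, slide_id=slide_id, neighbor_radius_px=neighbor_radius_px
    )
    labelled = classify_cells(model, cells)
    counts = {c: 0 for c in CLASS_NAMES}
    for rec in labelled:
        counts[rec.label] += 1
    return SlideResult(slide_id=slide_id, counts=counts, til_proportion=til_proportion(counts))


def median_split(pi_values: dict[str, float] | list[float]) -> TILGroups:
    """Dichotomise TIL proportions at the cohort median.

    The cutoff is the sample median (midpoint convention for even n);
    values <= cutoff go to "low", values > cutoff to "high".  If every
    value is identical the split is degenerate (all low) and a warning is
    issued.
    """
    if isinstance(pi_values, dict):
        ids = list(pi_values.keys())
        vals = np.array([pi_values[i] for i in ids], dtype=float)
    else:
        vals = np.asarray(pi_values, dtype=float)
        ids = [str(i) for i in range(len(vals))]
    if len(vals) < 2:
        raise ValueError("need >= 2 slides to split")
    cutoff = float(np.median(vals))
    if np.all(vals == vals[0]):
        warnings.warn("all TIL proportions identical: degenerate split (all low)")
    assignment = {
        i: ("high" if v > cutoff else "low") for i, v in zip(ids, vals)
    }
    return TILGroups(cutoff=cutoff, assignment=assignment)
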