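"""End-to-end glue: building labelled training sets from synthetic slides
and running the full synthetic study.

Training sets are built the way they are in practice: the segmentation
circles cells, an annotator names each circled cell, and the features of
the *circled* (not idealised) regions become the labelled records.  Here
the generator's ground truth plays the annotator: each segmented region is
labelled by the nearest true nucleus centroid.  This keeps the training
and prediction feature distributions identical — including tile-seam
fragments and watershed imperfections.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .classification import TrainingSet
from .features import DEFAULT_NEIGHBOR_RADIUS, CellRecord, extract_features
from .segmentation import SegmentationParams, lightness_complement, segment_slide
from .synthetic import GroundTruth, generate_training_slide_set

MATCH_RADIUS_PX = 6.0  # a segmented centroid further than this from every
# true centroid is left unlabelled (and excluded from training)


def annotate_records(
    records: list[CellRecord], truth: GroundTruth, match_radius_px: float = MATCH_RADIUS_PX
) -> list[CellRecord]:
    """Label each record with the class of the nearest true nucleus."""
    if not truth.centroids:
        return []
    tree = cKDTree(np.asarray(truth.centroids))
    out = []
    for rec in records:
        d, i = tree.query(rec.centroid)
        if d <= match_radius_px:
            rec.label = truth.true_labels[i]
            out.append(rec)
    return out


def training_set_from_slide(
    img: np.ndarray,
    truth: GroundTruth,
    cancer_type: str,
    params: SegmentationParams | None = None,
    neighbor_radius_px: float = DEFAULT_NEIGHBOR_RADIUS,
) -> TrainingSet:
    """Segment a slide and label the segmented cells from ground truth."""
    params = params or SegmentationParams()
    labels = segment_slide(img, params)
    gray = lightness_complement(img)
    records = extract_features(
        labels, gray, slide_id="training", neighbor_radius_px=neighbor_radius_px
    )
    return TrainingSet(cancer_type, annotate_records(records, truth))


def build_training_set(
    cancer_type: str,
    n_per_class: int = 200,
    seed: int = 0,
    params: SegmentationParams | None = None,
) -> TrainingSet:
    """Generate a balanced training slide and turn it into a TrainingSet."""
    img, truth = generate_training_slide_set(cancer_type, n_per_class, seed)
    return training_set_from_slide(img, truth, cancer_type, params)


def segmentation_precision_recall(
    pred: np.ndarray, true_mask: np.ndarray, iou_threshold: float = 0.5
) -> tuple[float, float]:
    """Object-level precision/recall of a label map against ground truth.

    A predicted nucleus matches a true nucleus when their IoU reaches the
    threshold; each prediction may match at most one truth and vice versa
    (greedy on IoU, which is unambiguous at threshold >= 0.5).
    """
    pred = np.asarray(pred)
    true_mask = np.asarray(true_mask)
    n_pred = int(pred.max())
    n_true = int(true_mask.max())
    if n_pred == 0 or n_true == 0:
        return (0.0 if n_pred else 1.0), (0.0 if n_true else 1.0)

    both = (pred > 0) | (true_mask > 0)
    pairs = true_mask[both].astype(np.int64) * (n_pred + 1) + pred[both]
    pair_ids, pair_counts = np.unique(pairs, return_counts=True)
    t_ids, p_ids = pair_ids // (n_pred + 1), pair_ids % (n_pred + 1)

    area_t = np.bincount(true_mask.ravel(), minlength=n_true + 1)
    area_p = np.bincount(pred.ravel(), minlength=n_pred + 1)

    matched_t: set[int] = set()
    matched_p: set[int] = set()
    overlap = (t_ids > 0) & (p_ids > 0)
    for t, p, inter in zip(t_ids[overlap], p_ids[overlap], pair_counts[overlap]):
        union = area_t[t] + area_p[p] - inter
        if inter / union >= iou_threshold and t not in matched_t and p not in matched_p:
            matched_t.add(int(t))
            matched_p.add(int(p))
    tp = len(matched_t)
    return tp / n_pred, tp / n_true


def per_cell_accuracy(
    records: list[CellRecord], truth: GroundTruth, match_radius_px: float = MATCH_RADIUS_PX
) -> float:
    """Fraction of classified cells whose label matches the nearest true
    nucleus; cells with no true nucleus within the match radius are skipped."""
    tree = cKDTree(np.asarray(truth.centroids))
    ok = tot = 0
    for rec in records:
        d, i = tree.query(rec.centroid)
        if d <= match_radius_px:
            tot += 1
            ok += rec.label == truth.true_labels[i]
    return ok / tot if tot else float("nan")
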