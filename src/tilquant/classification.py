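"""Three-class cell classification and its validation procedures.

A margin-based kernel classifier (RBF support-vector machine over
standardised features) separates cancer cells, lymphocytes and stromal
cells from the 43-feature representation.  Validation mirrors the three
checks used when such classifiers are deployed on H&E sections:
stratified cross-validation within the training set, concordance of
automated counts with manual counts, and a Jonckheere–Terpstra trend test
of automated TIL proportion across ordered manual infiltration grades.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import N_FEATURES, CellRecord, records_to_matrix
from .synthetic import CLASS_NAMES

CANCER_TYPES = ("AEGJ", "GAC", "ESCC")


class MissingClassError(ValueError):
    """A training set lacks one of the three cell classes."""


class RegistryMismatchError(ValueError):
    """Feature vectors do not match the classifier's registry."""


@dataclass
class TrainingSet:
    """Labelled cell records for one cancer type."""

    cancer_type: str
    records: list[CellRecord]

    def __post_init__(self) -> None:
        if any(r.label is None for r in self.records):
            raise ValueError("every training record must be labelled")
        present = {r.label for r in self.records}
        missing = set(CLASS_NAMES) - present
        if missing:
            raise MissingClassError(f"classes absent from training set: {missing}")

    @property
    def X(self) -> np.ndarray:
        return records_to_matrix(self.records)

    @property
    def y(self) -> np.ndarray:
        return np.array([r.label for r in self.records])


@dataclass
class ClassifierModel:
    """A fitted cell classifier plus the metadata needed to reuse it."""

    cancer_type: str
    pipeline: Pipeline
    seed: int
    hyperparams: dict = field(default_factory=dict)
    registry_version: str = "1.0"

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim != 2 or X.shape[1] != N_FEATURES:
            raise RegistryMismatchError(
                f"expected (n, {N_FEATURES}) feature matrix, got {X.shape}"
            )
        return self.pipeline.predict(X)


@dataclass
class ValidationReport:
    """Classifier validation summary: accuracies (%), concordance, trend."""

    overall_accuracy: float
    per_class_accuracy: dict[str, float]
    concordance_overall: Optional[float] = None
    concordance_per_class: Optional[dict[str, float]] = None
    trend_statistic: Optional[float] = None
    trend_p: Optional[float] = None


def _make_pipeline(hyperparams: dict, seed: int) -> Pipeline:
    hp = {"C": 1.0, "gamma": 1.0 / N_FEATURES, "kernel": "rbf"}
    hp.update(hyperparams or {})
    return Pipeline(
        [
            ("scale", StandardScaler()),
            ("svm", SVC(random_state=seed, **hp)),
        ]
    )


def train_classifier(
    ts: TrainingSet, hyperparams: dict | None = None, seed: int = 0
) -> ClassifierModel:
    """Fit the cell classifier on a labelled training set.

    Features are standardised with training-set means/SDs inside the model,
    so prediction-time inputs are raw 43-vectors.
    """
    pipe = _make_pipeline(hyperparams or {}, seed)
    pipe.fit(ts.X, ts.y)
    return ClassifierModel(
        cancer_type=ts.cancer_type,
        pipeline=pipe,
        seed=seed,
        hyperparams=dict(hyperparams or {}),
    )


def cross_validate(
    ts: TrainingSet, k: int = 10, seed: int = 0, hyperparams: dict | None = None
) -> ValidationReport:
    """Stratified k-fold cross-validation of the cell classifier.

    Overall accuracy pools correct/total over held-out folds; per-class
    accuracy is the recall of each class over the pooled held-out
    predictions.  All accuracies are percentages.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    X, y = ts.X, ts.y
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} members; cannot stratify into {k} folds"
        )
    # canonical ordering before fold assignment makes the accuracy a
    # function of the record multiset, not of record order
    order = np.lexsort((*X.T, y))
    Xs, ys = X[order], y[order]
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    pred_sorted = np.empty_like(ys)
    for train_idx, test_idx in skf.split(Xs, ys):
        pipe = _make_pipeline(hyperparams or {}, seed)
        pipe.fit(Xs[train_idx], ys[train_idx])
        pred_sorted[test_idx] = pipe.predict(Xs[test_idx])
    pred = np.empty_like(y)
    pred[order] = pred_sorted
    overall = 100.0 * float((pred == y).mean())
    per_class = {
        c: 100.0 * float((pred[y == c] == c).mean()) for c in classes
    }
    return ValidationReport(overall_accuracy=overall, per_class_accuracy=per_class)


def classify_cells(
    model: ClassifierModel, cells: Sequence[CellRecord]
) -> list[CellRecord]:
    """Assign a class to every cell; returns new records with labels set."""
    if not cells:
        return []
    if any(c.registry_version != model.registry_version for c in cells):
        raise RegistryMismatchError("cells and model use different feature registries")
    X = records_to_matrix(cells)
    labels = model.predict(X)
    out = []
    for rec, lab in zip(cells, labels):
        out.append(
            CellRecord(
                cell_id=rec.cell_id,
                slide_id=rec.slide_id,
                tile_index=rec.tile_index,
                centroid=rec.centroid,
                features=rec.features,
                label=str(lab),
            )
        )
    return out


def concordance_with_manual(
    auto_counts: Sequence[dict[str, int]],
    manual_counts: Sequence[dict[str, int]],
    method: str = "pearson",
) -> tuple[float, dict[str, float]]:
    """Correlate automated vs. manual per-sample class *proportions*.

    Returns ``(overall_r, per_class_r)`` where overall pools all classes'
    proportion pairs and per-class correlates each class separately.
    ``method`` is ``"pearson"`` (default) or ``"spearman"``.
    """
    if len(auto_counts) != len(manual_counts):
        raise ValueError("paired samples required")
    if len(auto_counts) < 3:
        raise ValueError("need >= 3 paired samples")

    def _props(counts: dict[str, int]) -> dict[str, float]:
        total = sum(counts.values())
        if total == 0:
            raise ValueError("sample with zero total count")
        return {c: counts.get(c, 0) / total for c in CLASS_NAMES}

    auto = [_props(c) for c in auto_counts]
    manual = [_props(c) for c in manual_counts]

    def _corr(x: np.ndarray, y: np.ndarray) -> float:
        if np.std(x) == 0 or np.std(y) == 0:
            raise ValueError("undefined correlation: zero variance")
        if method == "spearman":
            return float(stats.spearmanr(x, y).statistic)
        return float(stats.pearsonr(x, y).statistic)

    per_class = {}
    for c in CLASS_NAMES:
        per_class[c] = _corr(
            np.array([a[c] for a in auto]), np.array([m[c] for m in manual])
        )
    all_auto = np.array([a[c] for a in auto for c in CLASS_NAMES])
    all_manual = np.array([m[c] for m in manual for c in CLASS_NAMES])
    return _corr(all_auto, all_manual), per_class


# --------------------------------------------------------------------------
# Jonckheere–Terpstra trend test
# --------------------------------------------------------------------------

def _jt_statistic(groups: Sequence[np.ndarray]) -> float:
    """JT = sum over ordered pairs (i<j) of Mann–Whitney counts, ties as 1/2."""
    jt = 0.0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            a, b = groups[i], groups[j]
            gt = (b[None, :] > a[:, None]).sum()
            eq = (b[None, :] == a[:, None]).sum()
            jt += gt + 0.5 * eq
    return float(jt)


def _jt_null_moments(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """Null mean and tie-corrected variance of the JT statistic."""
    ns = np.array([len(g) for g in groups], dtype=float)
    n = ns.sum()
    pooled = np.concatenate(groups)
    _, tie_counts = np.unique(pooled, return_counts=True)
    t = tie_counts.astype(float)

    mean = (n**2 - (ns**2).sum()) / 4.0
    term1 = (
        n * (n - 1) * (2 * n + 5)
        - (ns * (ns - 1) * (2 * ns + 5)).sum()
        - (t * (t - 1) * (2 * t + 5)).sum()
    ) / 72.0
    term2 = (
        (ns * (ns - 1) * (ns - 2)).sum()
        * (t * (t - 1) * (t - 2)).sum()
        / (36.0 * n * (n - 1) * (n - 2))
    )
    term3 = (ns * (ns - 1)).sum() * (t * (t - 1)).sum() / (8.0 * n * (n - 1))
    return mean, term1 + term2 + term3


def _jt_exact_p(groups: Sequence[np.ndarray], observed: float) -> float:
    """Two-sided exact p by full enumeration of group assignments."""
    pooled = np.concatenate(groups)
    sizes = [len(g) for g in groups]
    n = len(pooled)
    idx = list(range(n))
    mean, _ = _jt_null_moments(groups)
    obs_dev = abs(observed - mean)

    extreme = 0
    total = 0

    def _recurse(remaining: list[int], gi: int, chosen: list[np.ndarray]) -> None:
        nonlocal extreme, total
        if gi == len(sizes) - 1:
            groups_perm = chosen + [pooled[remaining]]
            stat = _jt_statistic(groups_perm)
            total += 1
            if abs(stat - mean) >= obs_dev - 1e-12:
                extreme += 1
            return
        for comb in itertools.combinations(remaining, sizes[gi]):
            rest = [r for r in remaining if r not in comb]
            _recurse(rest, gi + 1, chosen + [pooled[list(comb)]])

    _recurse(idx, 0, [])
    return extreme / total


def jonckheere_terpstra(
    samples: Sequence[Sequence[float]],
    alternative: str = "two-sided",
    exact_max_n: int = 12,
) -> tuple[float, float]:
    """Jonckheere–Terpstra test for a monotone trend across ordered groups.

    ``samples`` is a list of groups in their stated order.  Returns
    ``(JT, p)``.  The p-value is exact (full permutation enumeration) when
    the pooled sample size is <= ``exact_max_n``, otherwise a normal
    approximation with tie-corrected variance is used.  When every pooled
    observation is identical the statistic carries no trend information and
    p = 1 is returned.
    """
    groups = [np.asarray(g, dtype=float) for g in samples]
    if len(groups) < 2:
        raise ValueError("need >= 2 ordered groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("every group must be nonempty")

    jt = _jt_statistic(groups)
    mean, var = _jt_null_moments(groups)
    if var <= 0:  # all observations tied: no trend information
        return jt, 1.0

    n = sum(len(g) for g in groups)
    if n <= exact_max_n:
        p_two = _jt_exact_p(groups, jt)
        if alternative == "two-sided":
            return jt, p_two
        # one-sided exact from directional enumeration
        p_two_dir = _jt_exact_one_sided(groups, jt, alternative)
        return jt, p_two_dir

    # continuity correction: JT moves in half-integer steps
    sd = math.sqrt(var)
    if alternative == "two-sided":
        z = max(abs(jt - mean) - 0.5, 0.0) / sd
        p = 2.0 * stats.norm.sf(z)
    elif alternative == "increasing":
        p = float(stats.norm.sf((jt - mean - 0.5) / sd))
    elif alternative == "decreasing":
        p = float(stats.norm.cdf((jt - mean + 0.5) / sd))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return jt, min(float(p), 1.0)


def _jt_exact_one_sided(
    groups: Sequence[np.ndarray], observed: float, alternative: str
) -> float:
    pooled = np.concatenate(groups)
    sizes = [len(g) for g in groups]
    stats_all: list[float] = []

    def _recurse(remaining: list[int], gi: int, chosen: list[np.ndarray]) -> None:
        if gi == len(sizes) - 1:
            stats_all.append(_jt_statistic(chosen + [pooled[remaining]]))
            return
        for comb in itertools.combinations(remaining, sizes[gi]):
            rest = [r for r in remaining if r not in comb]
            _recurse(rest, gi + 1, chosen + [pooled[list(comb)]])

    _recurse(list(range(len(pooled))), 0, [])
    arr = np.array(stats_all)
    if alternative == "increasing":
        return float((arr >= observed - 1e-12).mean())
    return float((arr <= observed + 1e-12).mean())
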