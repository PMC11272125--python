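"""File formats, the cohort exclusion flow, and run configuration.

Training-set CSVs use the dialect ``cancer_type,label,f01..f43`` with
labels in {cancer, lymphocyte, stroma}; a column-mapping shim adapts
external training sets whose feature columns are named differently.
Cohort CSVs carry per-patient covariates, TIL %, follow-up time (years)
and the event indicator.  All writes round-trip losslessly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .features import FEATURE_NAMES, N_FEATURES, CellRecord
from .classification import TrainingSet
from .synthetic import CLASS_NAMES

FEATURE_COLUMNS = [f"f{i + 1:02d}" for i in range(N_FEATURES)]


class ParseError(ValueError):
    """A file violates its documented schema; the message names row/column."""


# --------------------------------------------------------------------------
# exclusion flow
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ExclusionFlow:
    """Ordered exclusion rules; a record is excluded by the FIRST that matches.

    Each rule is (name, flag column); a truthy flag excludes the record.
    Default flow: low-quality image first, then missing survival time.
    """

    rules: tuple[tuple[str, str], ...] = (
        ("low_quality_image", "low_quality_image"),
        ("missing_survival", "missing_survival"),
    )


def apply_exclusions(
    registry: pd.DataFrame, flow: ExclusionFlow | None = None
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the exclusion flow to a case registry.

    Returns the retained table and per-rule exclusion counts (plus
    ``"retained"``).  Counts always satisfy
    ``sum(excluded) + retained == len(registry)``.
    """
    flow = flow or ExclusionFlow()
    for _, col in flow.rules:
        if col not in registry.columns:
            raise ParseError(f"registry missing flag column {col!r}")
    excluded = pd.Series(False, index=registry.index)
    counts: dict[str, int] = {}
    for name, col in flow.rules:
        hits = registry[col].astype(bool) & ~excluded
        counts[name] = int(hits.sum())
        excluded |= hits
    retained = registry.loc[~excluded].copy()
    counts["retained"] = int(len(retained))
    return retained, counts


# --------------------------------------------------------------------------
# training sets
# --------------------------------------------------------------------------

def write_training_set(ts: TrainingSet, path: str | Path) -> None:
    rows = []
    for r in ts.records:
        row = {"cancer_type": ts.cancer_type, "label": r.label}
        row.update(dict(zip(FEATURE_COLUMNS, r.features)))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_training_set(
    path: str | Path, column_map: Optional[Mapping[str, str]] = None
) -> TrainingSet:
    """Read a training-set CSV; ``column_map`` renames external columns
    (external name -> canonical ``cancer_type``/``label``/``f01``..``f43``)."""
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in ["cancer_type", "label", *FEATURE_COLUMNS] if c not in df.columns]
    if missing:
        raise ParseError(f"training set {path} missing columns: {missing}")
    bad = set(df["label"]) - set(CLASS_NAMES)
    if bad:
        row = df.index[df["label"].isin(bad)][0]
        raise ParseError(f"unknown label {bad} at row {row}")
    feats = df[FEATURE_COLUMNS].to_numpy(dtype=float)
    if not np.all(np.isfinite(feats)):
        r, c = np.argwhere(~np.isfinite(feats))[0]
        raise ParseError(
            f"non-finite feature at row {r}, column {FEATURE_COLUMNS[c]}"
        )
    ct = str(df["cancer_type"].iloc[0])
    records = [
        CellRecord(
            cell_id=i,
            slide_id="training",
            tile_index=0,
            centroid=(0.0, 0.0),
            features=feats[i],
            label=str(df["label"].iloc[i]),
        )
        for i in range(len(df))
    ]
    return TrainingSet(cancer_type=ct, records=records)


# --------------------------------------------------------------------------
# cohort tables
# --------------------------------------------------------------------------

def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "time" in df.columns and (df["time"] < 0).any():
        row = df.index[df["time"] < 0][0]
        raise ParseError(f"negative follow-up time at row {row}")
    if "event" in df.columns and not df["event"].isin([0, 1]).all():
        row = df.index[~df["event"].isin([0, 1])][0]
        raise ParseError(f"event indicator not in {{0,1}} at row {row}")
    if "til_pct" in df.columns:
        bad = df["til_pct"].notna() & ~df["til_pct"].between(0, 100)
        if bad.any():
            raise ParseError(f"TIL % out of [0,100] at row {df.index[bad][0]}")
    return df


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run; fully serialisable."""

    seed: int = 0
    grid: tuple[int, int] = (10, 10)
    opening_radius_px: int = 1
    min_nucleus_area_px: int = 9
    hmax_suppression: float = 2.0
    neighbor_radius_px: float = 50.0
    svm_c: float = 1.0
    svm_gamma: float = 1.0 / N_FEATURES
    k_folds: int = 10
    output_dir: str = "results"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid"] = list(d["grid"])
        return d

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "grid" in data:
            data["grid"] = tuple(data["grid"])
        return cls(**data)

    def dump(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def write_json(obj, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serialisable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default) + "\n")
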