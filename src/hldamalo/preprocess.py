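"""Preparation of Cleveland-schema heart-disease records.

Four steps precede classification: band-matched imputation of missing
attributes, redundancy removal (duplicate rows, constant columns),
separation of patients into the four chest-pain groups, and min–max
scaling of the continuous attributes.

Records use the standard 14-attribute Cleveland layout.  Imputation fills
a missing field from records that agree with the patient on age decade and
on blood-pressure and cholesterol quintile bands: the majority value for a
discrete field, the median for a continuous one, with a global fallback
when no banded match exists.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, fields as dc_fields, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ClevelandRecord",
    "ATTRIBUTES",
    "CONTINUOUS",
    "DISCRETE_DOMAINS",
    "MinMaxScaler",
    "RedundancyReport",
    "impute_missing",
    "remove_redundant",
    "separate_by_chest_pain",
    "scale_minmax",
    "records_to_frame",
    "frame_to_records",
]

logger = logging.getLogger(__name__)

ATTRIBUTES = (
    "age", "sex", "cp", "trestbps", "chol", "fbs", "restecg",
    "thalach", "exang", "oldpeak", "slope", "ca", "thal", "class_",
)
CONTINUOUS = ("age", "trestbps", "chol", "thalach", "oldpeak")
DISCRETE_DOMAINS = {
    "sex": {0, 1},
    "cp": {1, 2, 3, 4},
    "fbs": {0, 1},
    "restecg": {0, 1, 2},
    "exang": {0, 1},
    "slope": {1, 2, 3},
    "ca": {0, 1, 2, 3},
    "thal": {3, 6, 7},
    "class_": {0, 1, 2, 3, 4},
}

CHEST_PAIN_GROUPS = {1: "typical", 2: "atypical", 3: "non-anginal", 4: "asymptomatic"}


@dataclass(frozen=True)
class ClevelandRecord:
    """One patient row; ``None`` marks a missing attribute."""

    age: Optional[float] = None
    sex: Optional[int] = None
    cp: Optional[int] = None
    trestbps: Optional[float] = None
    chol: Optional[float] = None
    fbs: Optional[int] = None
    restecg: Optional[int] = None
    thalach: Optional[float] = None
    exang: Optional[int] = None
    oldpeak: Optional[float] = None
    slope: Optional[int] = None
    ca: Optional[int] = None
    thal: Optional[int] = None
    class_: Optional[int] = None

    def __post_init__(self) -> None:
        for name, domain in DISCRETE_DOMAINS.items():
            v = getattr(self, name)
            if v is not None and v not in domain:
                raise ValueError(f"{name}={v!r} outside domain {sorted(domain)}")
        for name in CONTINUOUS:
            v = getattr(self, name)
            if v is not None and not np.isfinite(v):
                raise ValueError(f"{name} must be finite when present")

    def missing_fields(self) -> tuple[str, ...]:
        return tuple(f.name for f in dc_fields(self) if getattr(self, f.name) is None)

    def is_complete(self) -> bool:
        return not self.missing_fields()


@dataclass(frozen=True)
class RedundancyReport:
    duplicate_rows_removed: int
    constant_columns_removed: tuple[str, ...]


def records_to_frame(records: Sequence[ClevelandRecord]) -> pd.DataFrame:
    """Records as a DataFrame with NaN for missing entries."""
    rows = [{a: getattr(r, a) for a in ATTRIBUTES} for r in records]
    return pd.DataFrame(rows, columns=list(ATTRIBUTES)).astype(float)


def frame_to_records(frame: pd.DataFrame) -> list[ClevelandRecord]:
    out = []
    for _, row in frame.iterrows():
        kwargs = {}
        for a in ATTRIBUTES:
            v = row[a]
            if pd.isna(v):
                kwargs[a] = None
            elif a in CONTINUOUS:
                kwargs[a] = float(v)
            else:
                kwargs[a] = int(v)
        out.append(ClevelandRecord(**kwargs))
    return out


def _age_band(age: Optional[float]) -> Optional[int]:
    return None if age is None else int(age // 10)


def _quintile_edges(values: np.ndarray) -> np.ndarray:
    return np.quantile(values, [0.2, 0.4, 0.6, 0.8])


def _band(value: Optional[float], edges: np.ndarray) -> Optional[int]:
    return None if value is None else int(np.searchsorted(edges, value, side="right"))


def impute_missing(records: Sequence[ClevelandRecord]) -> list[ClevelandRecord]:
    """Fill missing fields from records matching on age decade and
    blood-pressure/cholesterol quintile bands.

    Discrete fields take the majority value among matching records (lowest
    value on ties); continuous fields take the median.  When no banded
    match observes the field, the global majority/median is used and the
    fallback is logged.  Observed values are never altered, so the
    operation is idempotent.
    """
    frame = records_to_frame(records)
    for col in ATTRIBUTES:
        if frame[col].isna().all():
            raise ValueError(f"attribute {col!r} is missing in every record")

    bp_edges = _quintile_edges(frame["trestbps"].dropna().to_numpy())
    chol_edges = _quintile_edges(frame["chol"].dropna().to_numpy())

    def key(rec: ClevelandRecord):
        return (
            _age_band(rec.age),
            _band(rec.trestbps, bp_edges),
            _band(rec.chol, chol_edges),
        )

    keys = [key(r) for r in records]

    out: list[ClevelandRecord] = []
    for i, rec in enumerate(records):
        missing = rec.missing_fields()
        if not missing:
            out.append(rec)
            continue
        fills = {}
        for name in missing:
            donors = [
                getattr(other, name)
                for j, other in enumerate(records)
                if j != i
                and getattr(other, name) is not None
                and None not in keys[j]
                and keys[j] == keys[i]
            ]
            if not donors:
                donors = [
                    getattr(other, name)
                    for j, other in enumerate(records)
                    if j != i and getattr(other, name) is not None
                ]
                logger.info(
                    "no banded match for field %s of record %d; global fallback", name, i
                )
            if name in CONTINUOUS:
                fills[name] = float(np.median(donors))
            else:
                vals, counts = np.unique(donors, return_counts=True)
                fills[name] = int(vals[np.argmax(counts)])
        out.append(replace(rec, **fills))
    return out


def remove_redundant(
    records: Sequence[ClevelandRecord],
) -> tuple[list[ClevelandRecord], RedundancyReport]:
    """Drop exact duplicate rows and constant-valued columns (reported, not
    deleted from the schema: constant columns are listed so downstream
    feature selection can ignore them)."""
    seen: set[tuple] = set()
    kept: list[ClevelandRecord] = []
    dupes = 0
    for rec in records:
        sig = tuple(getattr(rec, a) for a in ATTRIBUTES)
        if sig in seen:
            dupes += 1
            continue
        seen.add(sig)
        kept.append(rec)
    constant = []
    if kept:
        frame = records_to_frame(kept)
        for col in ATTRIBUTES:
            observed = frame[col].dropna()
            if len(observed) > 0 and observed.nunique() == 1 and len(kept) > 1:
                constant.append(col)
    return kept, RedundancyReport(
        duplicate_rows_removed=dupes,
        constant_columns_removed=tuple(constant),
    )


def separate_by_chest_pain(
    records: Sequence[ClevelandRecord],
) -> dict[int, list[ClevelandRecord]]:
    """Partition records into the four chest-pain groups (typical=1,
    atypical=2, non-anginal=3, asymptomatic=4); disjoint and exhaustive."""
    groups: dict[int, list[ClevelandRecord]] = {1: [], 2: [], 3: [], 4: []}
    for rec in records:
        if rec.cp not in groups:
            raise ValueError(f"chest-pain type {rec.cp!r} outside {{1..4}} (impute first)")
        groups[rec.cp].append(rec)
    return groups


class MinMaxScaler:
    """Per-column affine map of continuous features onto [0, 1], fitted on
    training data; constant columns map to 0.  Applying the scaler to data
    outside the fitted range clips with a warning, and the inverse
    transform undoes the affine map exactly for in-range data."""

    def __init__(self) -> None:
        self.min_: np.ndarray | None = None
        self.max_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "MinMaxScaler":
        X = np.asarray(X, dtype=float)
        self.min_ = X.min(axis=0)
        self.max_ = X.max(axis=0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.min_ is None:
            raise RuntimeError("scaler is not fitted")
        X = np.asarray(X, dtype=float)
        span = self.max_ - self.min_
        scaled = np.where(span > 0, (X - self.min_) / np.where(span > 0, span, 1.0), 0.0)
        if np.any(scaled < 0) or np.any(scaled > 1):
            warnings.warn("values outside the fitted range were clipped to [0, 1]")
            scaled = np.clip(scaled, 0.0, 1.0)
        return scaled

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        if self.min_ is None:
            raise RuntimeError("scaler is not fitted")
        Z = np.asarray(Z, dtype=float)
        span = self.max_ - self.min_
        return np.where(span > 0, Z * span + self.min_, self.min_)


def scale_minmax(X: np.ndarray) -> tuple[np.ndarray, MinMaxScaler]:
    """Fit a min–max scaler on ``X`` and return the scaled matrix with the
    reusable scaler."""
    scaler = MinMaxScaler()
    return scaler.fit_transform(X), scaler
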