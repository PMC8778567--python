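"""Readers and writers for the Cleveland CSV dialect, vitals streams,
metric reports and serialized models.

The canonical Cleveland file is headerless, comma-separated, 14 columns,
with ``?`` for a missing entry; the reader also accepts a headered form
(auto-detected by sniffing whether the first cell parses as a number) and
the writer always emits headers.  Undefined metrics are written as ``NA``,
never as 0.
"""

from __future__ import annotations

import csv
import json
import math
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .lda import LDAModel
from .malo import MALOConfig
from .pipeline import HLDAMALOModel, WrapperFitnessSpec
from .preprocess import ATTRIBUTES, CONTINUOUS, ClevelandRecord, MinMaxScaler
from .vitals import ScreenVerdict, VitalSample

__all__ = [
    "read_cleveland_csv",
    "write_cleveland_csv",
    "read_vitals_csv",
    "write_vitals_csv",
    "write_verdicts_csv",
    "write_report",
    "read_report",
    "save_model",
    "load_model",
    "load_run_config",
]

# header names accepted for Cleveland files; class column may be "class",
# "num" (UCI name) or "target"
_CLASS_ALIASES = {"class", "num", "target", "class_"}

REPORT_COLUMNS = ("Class", "Accuracy", "Precision", "Recall", "Specificity", "F-Score")

_VITAL_COLUMNS = (
    "heart_rate", "systolic", "diastolic", "temperature",
    "spo2", "pr_interval", "rhythm_regular",
)


class FormatError(ValueError):
    """Malformed input file (wrong column count, bad header, ...)."""


def _parse_cell(name: str, raw: str, row_no: int):
    raw = raw.strip()
    if raw in ("?", "", "NA"):
        return None
    try:
        value = float(raw)
    except ValueError as exc:
        raise FormatError(
            f"row {row_no}: field {name!r} has non-numeric value {raw!r}"
        ) from exc
    if name in CONTINUOUS:
        return value
    if not float(value).is_integer():
        raise FormatError(
            f"row {row_no}: discrete field {name!r} has non-integer value {raw!r}"
        )
    return int(value)


def _looks_like_header(first_row: Sequence[str]) -> bool:
    try:
        float(first_row[0].strip())
        return False
    except ValueError:
        return True


def read_cleveland_csv(path: str | Path) -> list[ClevelandRecord]:
    """Parse a 14-column Cleveland-dialect CSV into records.

    ``?`` marks a missing value; field domains are validated and errors
    name the offending field and 1-based row number.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        rows = [r for r in csv.reader(fh) if r and any(c.strip() for c in r)]
    if not rows:
        raise FormatError(f"{path}: empty file")

    start = 0
    columns = list(ATTRIBUTES)
    if _looks_like_header(rows[0]):
        header = [h.strip().lower() for h in rows[0]]
        header = ["class_" if h in _CLASS_ALIASES else h for h in header]
        if sorted(header) != sorted(ATTRIBUTES):
            raise FormatError(f"{path}: unrecognized header {rows[0]}")
        columns = header
        start = 1

    records = []
    for i, row in enumerate(rows[start:], start=start + 1):
        if len(row) != len(ATTRIBUTES):
            raise FormatError(
                f"{path}: row {i} has {len(row)} columns, expected {len(ATTRIBUTES)}"
            )
        kwargs = {}
        for name, raw in zip(columns, row):
            kwargs[name] = _parse_cell(name, raw, i)
        try:
            records.append(ClevelandRecord(**kwargs))
        except ValueError as exc:
            raise FormatError(f"{path}: row {i}: {exc}") from exc
    return records


def _format_cell(name: str, value) -> str:
    if value is None:
        return "?"
    if name in CONTINUOUS:
        return format(float(value), "g")
    return str(int(value))


def write_cleveland_csv(records: Sequence[ClevelandRecord], path: str | Path) -> None:
    """Write records as a headered Cleveland CSV (``class`` column name)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow([a.rstrip("_") for a in ATTRIBUTES])
        for rec in records:
            writer.writerow(
                [_format_cell(a, getattr(rec, a)) for a in ATTRIBUTES]
            )


def write_vitals_csv(samples: Sequence[VitalSample], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_VITAL_COLUMNS)
        for s in samples:
            row = []
            for col in _VITAL_COLUMNS:
                v = getattr(s, col)
                if v is None:
                    row.append("")
                elif col == "rhythm_regular":
                    row.append("1" if v else "0")
                else:
                    row.append(format(float(v), "g"))
            writer.writerow(row)


def read_vitals_csv(path: str | Path) -> list[VitalSample]:
    """Read a headered vitals CSV (one row per timestamped sample)."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file")
        unknown = set(reader.fieldnames) - set(_VITAL_COLUMNS) - {"timestamp"}
        if unknown:
            raise FormatError(f"{path}: unknown columns {sorted(unknown)}")
        samples = []
        for i, row in enumerate(reader, start=2):
            kwargs = {}
            for col in _VITAL_COLUMNS:
                raw = (row.get(col) or "").strip()
                if raw == "":
                    kwargs[col] = None
                elif col == "rhythm_regular":
                    kwargs[col] = raw not in ("0", "false", "False")
                else:
                    try:
                        kwargs[col] = float(raw)
                    except ValueError as exc:
                        raise FormatError(
                            f"{path}: row {i}: bad value {raw!r} for {col}"
                        ) from exc
            samples.append(VitalSample(**kwargs))
    return samples


def write_verdicts_csv(
    samples: Sequence[VitalSample],
    verdicts: Sequence[ScreenVerdict],
    path: str | Path,
) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(("sample", "overall", "findings"))
        for i, v in enumerate(verdicts):
            writer.writerow((i, v.overall, ";".join(v.findings)))


def _metric_str(value: float) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "NA"
    return f"{value:.4f}"


def write_report(rows: Sequence[dict], path: str | Path) -> None:
    """Write the per-class metric report as CSV with the columns
    Class, Accuracy, Precision, Recall, Specificity, F-Score."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(REPORT_COLUMNS)
        for row in rows:
            writer.writerow(
                (
                    row["class"],
                    _metric_str(row["accuracy"]),
                    _metric_str(row["precision"]),
                    _metric_str(row["recall"]),
                    _metric_str(row["specificity"]),
                    _metric_str(row["f_score"]),
                )
            )


def read_report(path: str | Path) -> list[dict]:
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if tuple(header) != REPORT_COLUMNS:
            raise FormatError(f"{path}: unexpected report header {header}")
        rows = []
        for row in reader:
            parsed = {"class": row[0]}
            for name, raw in zip(
                ("accuracy", "precision", "recall", "specificity", "f_score"), row[1:]
            ):
                parsed[name] = float("nan") if raw == "NA" else float(raw)
            rows.append(parsed)
    return rows


def save_model(
    model: HLDAMALOModel,
    path: str | Path,
    scaler: Optional[MinMaxScaler] = None,
) -> None:
    """Serialize a fitted pipeline model (plus the optional feature scaler)
    to a flat JSON artifact."""
    payload = {
        "selected_mask": model.selected_mask.astype(int).tolist(),
        "classes": model.lda.classes.tolist(),
        "projection": model.lda.projection.tolist(),
        "eigenvalues": model.lda.eigenvalues.tolist(),
        "centroids": model.lda.centroids.tolist(),
        "ridge": model.lda.ridge,
        "n_features_selected": model.lda.n_features,
        "malo": {
            "n_ants": model.malo_config.n_ants,
            "n_dims": model.malo_config.n_dims,
            "max_iters": model.malo_config.max_iters,
            "levy_alpha": model.malo_config.levy_alpha,
            "levy_exponent": model.malo_config.levy_exponent,
            "crossover_rate": model.malo_config.crossover_rate,
            "seed": model.malo_config.seed,
            "walk_bounds": list(model.malo_config.walk_bounds),
        },
        "fitness": {
            "cv_folds": model.fitness_spec.cv_folds,
            "feature_penalty": model.fitness_spec.feature_penalty,
            "inner_seed": model.fitness_spec.inner_seed,
        },
        "fitness_history": model.fitness_history.tolist(),
    }
    if scaler is not None and scaler.min_ is not None:
        payload["scaler"] = {
            "min": scaler.min_.tolist(),
            "max": scaler.max_.tolist(),
        }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def load_model(path: str | Path) -> tuple[HLDAMALOModel, Optional[MinMaxScaler]]:
    payload = json.loads(Path(path).read_text())
    lda_model = LDAModel(
        projection=np.asarray(payload["projection"], dtype=float),
        eigenvalues=np.asarray(payload["eigenvalues"], dtype=float),
        centroids=np.asarray(payload["centroids"], dtype=float),
        classes=np.asarray(payload["classes"]),
        ridge=float(payload["ridge"]),
        n_features=int(payload["n_features_selected"]),
    )
    m = payload["malo"]
    cfg = MALOConfig(
        n_ants=m["n_ants"],
        n_dims=m["n_dims"],
        max_iters=m["max_iters"],
        levy_alpha=m["levy_alpha"],
        levy_exponent=m["levy_exponent"],
        crossover_rate=m["crossover_rate"],
        seed=m["seed"],
        walk_bounds=tuple(m["walk_bounds"]),
    )
    f = payload["fitness"]
    spec = WrapperFitnessSpec(
        cv_folds=f["cv_folds"],
        feature_penalty=f["feature_penalty"],
        inner_seed=f["inner_seed"],
    )
    model = HLDAMALOModel(
        selected_mask=np.asarray(payload["selected_mask"], dtype=np.int8),
        lda=lda_model,
        malo_config=cfg,
        fitness_spec=spec,
        fitness_history=np.asarray(payload["fitness_history"], dtype=float),
    )
    scaler = None
    if "scaler" in payload:
        scaler = MinMaxScaler()
        scaler.min_ = np.asarray(payload["scaler"]["min"], dtype=float)
        scaler.max_ = np.asarray(payload["scaler"]["max"], dtype=float)
    return model, scaler


def load_run_config(path: str | Path) -> dict:
    """Load a flat YAML run configuration."""
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return data
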