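"""Synthetic test-bed generation.

Two generators stand in for clinical data sources:

* :func:`generate_cleveland_like` draws tabular records in the 14-attribute
  Cleveland heart-disease schema with a planted class signal: a chosen
  number of informative features carry a standardized mean gap (effect
  size) between the normal and abnormal class, the remaining features are
  pure noise, and the ground-truth informative mask is returned alongside.
* :func:`generate_vitals_stream` draws vital-sign samples whose values fall
  inside or outside the screening rule bands at controlled abnormality
  rates, with the injected truth flags recorded per sample.

Both are fully reproducible from their seed.  The generated features are
independent Gaussians; the correlation structure of real clinical tables is
deliberately not emulated (see the methods note).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .lda import LabeledDataset
from .preprocess import ClevelandRecord, CONTINUOUS, DISCRETE_DOMAINS
from .vitals import VitalSample

__all__ = [
    "GeneratorSpec",
    "generate_cleveland_like",
    "generate_vitals_stream",
    "VITALS_RATE_KEYS",
]

# Affine embeddings of standardized features into realistic attribute scales
# (location, spread chosen near published Cleveland summary statistics).
_CONTINUOUS_EMBED = {
    "age": (54.0, 9.0),
    "trestbps": (131.0, 17.0),
    "chol": (246.0, 51.0),
    "thalach": (149.0, 23.0),
    "oldpeak": (1.05, 1.16),
}

# Marginal frequencies used for discrete slots that carry no planted signal.
_DISCRETE_MARGINALS = {
    "sex": ([0, 1], [0.32, 0.68]),
    "cp": ([1, 2, 3, 4], [0.08, 0.16, 0.28, 0.48]),
    "fbs": ([0, 1], [0.85, 0.15]),
    "restecg": ([0, 1, 2], [0.50, 0.01, 0.49]),
    "exang": ([0, 1], [0.67, 0.33]),
    "slope": ([1, 2, 3], [0.47, 0.46, 0.07]),
    "ca": ([0, 1, 2, 3], [0.59, 0.21, 0.13, 0.07]),
    "thal": ([3, 6, 7], [0.55, 0.06, 0.39]),
}

# Predictor slots of the Cleveland schema, in embedding order: continuous
# slots first so informative features land on continuous attributes.
_SLOT_ORDER = ("age", "trestbps", "chol", "thalach", "oldpeak",
               "sex", "cp", "fbs", "restecg", "exang", "slope", "ca", "thal")


@dataclass(frozen=True)
class GeneratorSpec:
    """Study conditions of the planted-signal generator.

    Defaults reproduce the standard test bed: 400 records with 4
    informative features (standardized mean gap 2.0) among 14, balanced
    classes, 5 % missingness injected completely at random into the record
    view.
    """

    n_samples: int = 400
    n_informative: int = 4
    n_noise: int = 10
    effect_size: float = 2.0
    missing_rate: float = 0.05
    class_balance: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.n_informative < 0 or self.n_noise < 0:
            raise ValueError("feature counts must be nonnegative")
        if self.n_informative + self.n_noise < 1:
            raise ValueError("need at least one feature")
        if self.n_informative + self.n_noise > 14:
            raise ValueError("at most 14 features fit the Cleveland schema")
        if self.effect_size < 0:
            raise ValueError("effect_size must be nonnegative")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError("class_balance must lie in (0, 1)")

    @property
    def n_features(self) -> int:
        return self.n_informative + self.n_noise


def generate_cleveland_like(
    spec: GeneratorSpec,
) -> tuple[LabeledDataset, np.ndarray, list[ClevelandRecord]]:
    """Draw a planted-signal dataset and its Cleveland-record view.

    Returns ``(dataset, truth_mask, records)``: the feature matrix with
    binary labels (0 = normal, 1 = abnormal), the ground-truth informative
    mask, and a list of Cleveland-schema records.  Informative features are
    unit-variance Gaussians whose class means differ by the effect size;
    noise features are class-independent standard Gaussians.

    The record view embeds the first features into the 13 predictor slots
    (continuous slots affinely, categorical slots by quantile
    discretization into the attribute's domain); a 14th feature, when
    present, lives only in the feature matrix.  Missingness is injected
    into predictor slots completely at random, never into the class label.
    """
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_samples, spec.n_features

    n_normal = int(round(n * spec.class_balance))
    n_normal = min(max(n_normal, 1), n - 1)
    y = np.concatenate([np.zeros(n_normal, dtype=int), np.ones(n - n_normal, dtype=int)])
    rng.shuffle(y)

    X = rng.normal(0.0, 1.0, size=(n, p))
    half = spec.effect_size / 2.0
    for j in range(spec.n_informative):
        X[:, j] += np.where(y == 1, half, -half)

    truth_mask = np.zeros(p, dtype=np.int8)
    truth_mask[: spec.n_informative] = 1

    dataset = LabeledDataset(X=X, y=y, class_names=("normal", "abnormal"))
    records = _cleveland_view(X, y, spec, rng)
    return dataset, truth_mask, records


def _discretize(column: np.ndarray, domain: Sequence[int], rng: np.random.Generator) -> np.ndarray:
    """Quantile-bin a continuous column into the ordered attribute domain."""
    levels = np.asarray(sorted(domain))
    qs = np.quantile(column, np.linspace(0, 1, levels.size + 1)[1:-1])
    return levels[np.searchsorted(qs, column, side="right")]


def _cleveland_view(
    X: np.ndarray,
    y: np.ndarray,
    spec: GeneratorSpec,
    rng: np.random.Generator,
) -> list[ClevelandRecord]:
    n, p = X.shape
    columns: dict[str, np.ndarray] = {}
    for slot_idx, name in enumerate(_SLOT_ORDER):
        if slot_idx < p:
            feat = X[:, slot_idx]
            if name in _CONTINUOUS_EMBED:
                loc, scale = _CONTINUOUS_EMBED[name]
                columns[name] = np.round(loc + scale * feat, 1)
            else:
                columns[name] = _discretize(feat, DISCRETE_DOMAINS[name], rng)
        else:
            values, probs = _DISCRETE_MARGINALS[name]
            columns[name] = rng.choice(values, size=n, p=probs)
    # binary label rendered on the 0..4 scale: abnormal -> 1
    columns["class_"] = y.astype(int)

    missing = rng.random((n, len(_SLOT_ORDER))) < spec.missing_rate

    records = []
    for i in range(n):
        kwargs = {}
        for slot_idx, name in enumerate(_SLOT_ORDER):
            if missing[i, slot_idx]:
                kwargs[name] = None
            elif name in CONTINUOUS:
                kwargs[name] = float(columns[name][i])
            else:
                kwargs[name] = int(columns[name][i])
        kwargs["class_"] = int(columns["class_"][i])
        records.append(ClevelandRecord(**kwargs))
    return records


VITALS_RATE_KEYS = (
    "bradycardia",
    "tachycardia",
    "arrhythmia",
    "av_block",
    "fever",
    "elevated_bp",
    "stage1_hypertension",
    "hypoxemia",
)


def generate_vitals_stream(
    n_samples: int,
    abnormality_rates: Optional[dict[str, float]] = None,
    seed: int = 0,
) -> tuple[list[VitalSample], list[tuple[str, ...]]]:
    """Draw vital-sign samples with controlled per-flag abnormality rates.

    Normal draws lie strictly inside the screening rule bands; an injected
    abnormality draws the relevant signal strictly outside its band, so the
    recorded truth flags coincide with the screening verdict by
    construction.  Rate keys: bradycardia, tachycardia (mutually exclusive,
    summing to <= 1), arrhythmia, av_block, fever, elevated_bp,
    stage1_hypertension (mutually exclusive), hypoxemia.
    """
    rates = {k: 0.0 for k in VITALS_RATE_KEYS}
    if abnormality_rates:
        for k, v in abnormality_rates.items():
            if k not in rates:
                raise ValueError(f"unknown abnormality flag {k!r}")
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"rate for {k!r} must lie in [0, 1], got {v}")
            rates[k] = float(v)
    if rates["bradycardia"] + rates["tachycardia"] > 1.0:
        raise ValueError("bradycardia + tachycardia rates exceed 1")
    if rates["elevated_bp"] + rates["stage1_hypertension"] > 1.0:
        raise ValueError("elevated_bp + stage1_hypertension rates exceed 1")

    rng = np.random.default_rng(seed)
    samples: list[VitalSample] = []
    truths: list[tuple[str, ...]] = []
    for _ in range(n_samples):
        flags: set[str] = set()

        u = rng.random()
        if u < rates["bradycardia"]:
            hr = rng.uniform(40.0, 59.5)
            flags.add("bradycardia")
        elif u < rates["bradycardia"] + rates["tachycardia"]:
            hr = rng.uniform(100.5, 160.0)
            flags.add("tachycardia")
        else:
            hr = rng.uniform(60.0, 100.0)

        rhythm_regular = True
        if rng.random() < rates["arrhythmia"]:
            rhythm_regular = False
            flags.add("arrhythmia")

        if rng.random() < rates["av_block"]:
            pr = rng.uniform(0.21, 0.30)
            flags.add("av_block")
        else:
            pr = rng.uniform(0.12, 0.20)

        if rng.random() < rates["fever"]:
            temp = rng.uniform(100.5, 103.0)
            flags.add("fever")
        else:
            temp = rng.uniform(97.0, 99.9)

        u = rng.random()
        if u < rates["elevated_bp"]:
            sys_bp = rng.uniform(120.0, 129.5)
            dia_bp = rng.uniform(65.0, 79.5)
            flags.add("elevated_bp")
        elif u < rates["elevated_bp"] + rates["stage1_hypertension"]:
            sys_bp = rng.uniform(130.0, 139.0)
            dia_bp = rng.uniform(80.0, 89.0)
            flags.add("stage1_hypertension")
        else:
            sys_bp = rng.uniform(100.0, 119.5)
            dia_bp = rng.uniform(65.0, 79.5)

        if rng.random() < rates["hypoxemia"]:
            spo2 = rng.uniform(85.0, 94.5)
            flags.add("hypoxemia")
        else:
            spo2 = rng.uniform(95.0, 100.0)

        samples.append(
            VitalSample(
                heart_rate=round(hr, 1),
                systolic=round(sys_bp, 1),
                diastolic=round(dia_bp, 1),
                temperature=round(temp, 1),
                spo2=round(spo2, 1),
                pr_interval=round(pr, 3),
                rhythm_regular=rhythm_regular,
            )
        )
        truths.append(tuple(sorted(flags)))
    return samples, truths
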