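"""Three-class nucleus classification (lymphocyte / epithelial / malignant).

A support vector machine with an RBF kernel on standardised features;
probability outputs come from pairwise coupling. The trained model carries
its standardisation statistics, feature-name contract and a config
fingerprint so that a persisted model refuses mismatched feature tables.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .segmentation import NucleusSegmentation
from .synthetic import CLASS_NAMES


@dataclass(frozen=True)
class SVMConfig:
    kernel: str = "rbf"
    C: float = 1.0
    gamma: str | float = "scale"
    class_weight: str | dict | None = "balanced"
    standardise: bool = True
    probability: bool = True
    seed: int = 0

    def fingerprint(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class CellClassifierModel:
    pipeline: Pipeline
    feature_names: list[str]
    classes: list[str]
    config: SVMConfig
    fingerprint: str = field(default="")

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "CellClassifierModel":
        model = joblib.load(path)
        if not isinstance(model, CellClassifierModel):
            raise TypeError(f"{path} does not hold a CellClassifierModel")
        return model


def train_cell_classifier(
    features: pd.DataFrame,
    labels,
    config: SVMConfig | None = None,
) -> CellClassifierModel:
    """Fit the nucleus classifier.

    Requires at least two classes and at least 5 examples of each class
    present. NaN features raise an error naming the offending column(s).
    """
    config = config or SVMConfig()
    labels = np.asarray(labels)
    if len(labels) != len(features):
        raise ValueError("labels and feature table lengths differ")
    bad = features.columns[features.isna().any()].tolist()
    if bad:
        raise ValueError(f"NaN values in feature column(s): {bad}")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training data must contain at least two classes")
    thin = [str(c) for c, n in zip(classes, counts) if n < 5]
    if thin:
        raise ValueError(f"fewer than 5 training examples for class(es): {thin}")

    steps = []
    if config.standardise:
        steps.append(("scale", StandardScaler()))
    steps.append(
        (
            "svm",
            SVC(
                kernel=config.kernel,
                C=config.C,
                gamma=config.gamma,
                class_weight=config.class_weight,
                probability=config.probability,
                random_state=config.seed,
            ),
        )
    )
    pipeline = Pipeline(steps)
    with warnings.catch_warnings():
        # sklearn 1.9 deprecates SVC(probability=True); pairwise-coupled
        # probabilities remain the documented behaviour until 1.11
        warnings.simplefilter("ignore", FutureWarning)
        pipeline.fit(features.to_numpy(float), labels)
    return CellClassifierModel(
        pipeline=pipeline,
        feature_names=list(features.columns),
        classes=[str(c) for c in pipeline.named_steps["svm"].classes_],
        config=config,
        fingerprint=config.fingerprint(),
    )


def classify_cells(
    model: CellClassifierModel,
    features: pd.DataFrame,
    segmentation: NucleusSegmentation,
) -> pd.DataFrame:
    """Produce the cell map: one class (and class scores) per nucleus.

    Returns a DataFrame with columns ``nucleus_id, cell_class,
    score_<class>..., row, col``; empty segmentation gives an empty map.
    """
    if list(features.columns) != model.feature_names:
        raise ValueError(
            "feature table does not match the model contract: "
            f"got {list(features.columns)}, expected {model.feature_names}"
        )
    score_cols = [f"score_{c}" for c in CLASS_NAMES]
    if len(features) == 0:
        return pd.DataFrame(
            columns=["nucleus_id", "cell_class", *score_cols, "row", "col"]
        )
    X = features.to_numpy(float)
    predicted = model.pipeline.predict(X)
    out = pd.DataFrame(
        {
            "nucleus_id": features.index.to_numpy(),
            "cell_class": predicted,
        }
    )
    if model.config.probability:
        proba = model.pipeline.predict_proba(X)
        lookup = {c: i for i, c in enumerate(model.classes)}
        for c in CLASS_NAMES:
            out[f"score_{c}"] = proba[:, lookup[c]] if c in lookup else 0.0
    else:
        for c in CLASS_NAMES:
            out[f"score_{c}"] = (predicted == c).astype(float)
    out["row"] = segmentation.centroids[:, 0]
    out["col"] = segmentation.centroids[:, 1]
    return out
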