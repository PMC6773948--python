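"""Two-stage cascade scorer: healthy/cancer gate, then continuous regression.

Stage 1 is a binary classifier that decides whether a patch contains any
cancerous tissue; patches gated healthy receive a score of exactly 0%
(patches without tumour cells are scored 0 by convention). Stage 2 is a
regressor trained only on cancerous patches that outputs a continuous score
clipped to [0, 100].

Both stages are small multilayer perceptrons trained from scratch on a
fixed multi-scale pixel representation: the patch downsampled to a small
square, plus a morphological-opening channel of the darkness map that keeps
only dark blobs above a size scale (large malignant nuclei survive the
opening, small benign nuclei do not — the size selectivity a convolutional
network would otherwise have to learn). This desk-scale stand-in preserves
the cascade contract (learned weights, cross-entropy / squared-error
losses, gating rule) while remaining trainable in seconds on one CPU. The
model family is pluggable through :class:`CascadeConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import joblib
import numpy as np
from scipy import ndimage as ndi
from skimage.transform import resize
from sklearn.neural_network import MLPClassifier, MLPRegressor

HEALTHY, CANCEROUS = 0, 1
STAGE_GATED_HEALTHY = "gated_healthy"
STAGE_REGRESSED = "regressed"


@dataclass(frozen=True)
class CascadeConfig:
    """Hyperparameters for both stages; every source of randomness is
    seeded. ``resize_edge_px`` sets the square edge patches are resampled
    to before flattening; ``opening_radius_px`` is the disk radius of the
    grey opening applied to the darkness map at the intermediate
    ``pyramid_edge_px`` scale (the size-selectivity scale)."""

    resize_edge_px: int = 32
    pyramid_edge_px: int = 128
    opening_radius_px: int = 3
    threshold: float = 0.5
    stage1_hidden: tuple[int, ...] = (64,)
    stage1_max_epochs: int = 200
    stage2_hidden: tuple[int, ...] = (64,)
    stage2_max_epochs: int = 300
    learning_rate: float = 1e-3
    batch_size: int = 32
    patience: int = 10
    tol: float = 1e-6
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")
        if self.resize_edge_px < 4:
            raise ValueError("resize_edge_px must be >= 4")


def _disk(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return (yy**2 + xx**2) <= radius**2


def patch_features(
    rgb_image: np.ndarray,
    edge_px: int,
    pyramid_edge_px: int = 128,
    opening_radius_px: int = 3,
) -> np.ndarray:
    """Multi-scale [0, 1] pixel vector used by both stages.

    Four channels at ``edge_px`` resolution: downsampled R, G, B, plus the
    grey opening of the darkness map (1 - mean intensity) computed at the
    ``pyramid_edge_px`` scale — a size-selective channel in which only dark
    structures wider than the opening disk survive.
    """
    img = np.asarray(rgb_image, float) / 255.0
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB patch")
    mid = resize(img, (pyramid_edge_px, pyramid_edge_px, 3), anti_aliasing=True)
    darkness = 1.0 - mid.mean(axis=2)
    opened = ndi.grey_opening(darkness, footprint=_disk(opening_radius_px))
    rgb_small = resize(mid, (edge_px, edge_px, 3), anti_aliasing=True)
    opened_small = resize(opened, (edge_px, edge_px), anti_aliasing=True)
    return np.concatenate([rgb_small.ravel(), opened_small.ravel()])


def _feature_matrix(patches: Sequence[np.ndarray], config: CascadeConfig) -> np.ndarray:
    shapes = {np.asarray(p).shape for p in patches}
    if len(shapes) > 1:
        raise ValueError(f"patches must share dimensions, got {sorted(shapes)}")
    return np.stack(
        [
            patch_features(
                p,
                config.resize_edge_px,
                config.pyramid_edge_px,
                config.opening_radius_px,
            )
            for p in patches
        ]
    )


@dataclass
class Stage1Model:
    """Healthy-vs-cancerous patch classifier."""

    mlp: MLPClassifier
    config: CascadeConfig
    loss_curve: list[float] = field(default_factory=list)

    def cancer_probability(self, patches: Sequence[np.ndarray]) -> np.ndarray:
        X = _feature_matrix(patches, self.config)
        self._check_width(X)
        idx = list(self.mlp.classes_).index(CANCEROUS)
        return self.mlp.predict_proba(X)[:, idx]

    def _check_width(self, X: np.ndarray) -> None:
        expected = self.mlp.n_features_in_
        if X.shape[1] != expected:
            raise ValueError(
                f"input size mismatch: model expects {expected} features, got {X.shape[1]}"
            )


@dataclass
class Stage2Model:
    """Continuous cellularity regressor for cancerous patches.

    Internally the network regresses the unit-scale fraction; ``predict``
    returns percentages clipped to [0, 100].
    """

    mlp: MLPRegressor
    config: CascadeConfig
    loss_curve: list[float] = field(default_factory=list)

    def predict(self, patches: Sequence[np.ndarray]) -> np.ndarray:
        X = _feature_matrix(patches, self.config)
        expected = self.mlp.n_features_in_
        if X.shape[1] != expected:
            raise ValueError(
                f"input size mismatch: model expects {expected} features, got {X.shape[1]}"
            )
        return np.clip(100.0 * self.mlp.predict(X), 0.0, 100.0)


@dataclass(frozen=True)
class CascadePrediction:
    """Gated cascade output for one patch."""

    cancer_probability: float
    tc_value: float
    stage: str  # gated_healthy | regressed

    def __post_init__(self):
        if self.stage == STAGE_GATED_HEALTHY and self.tc_value != 0.0:
            raise ValueError("gated-healthy predictions must be exactly 0")
        if not 0.0 <= self.tc_value <= 100.0:
            raise ValueError("TC value must lie in [0, 100]")


def train_stage1(
    patches: Sequence[np.ndarray], labels, config: CascadeConfig | None = None
) -> Stage1Model:
    """Train the healthy/cancerous gate.

    ``labels`` are 0 (healthy) / 1 (cancerous); both classes must be
    present. Training is deterministic for a fixed seed.
    """
    config = config or CascadeConfig()
    config.validate()
    y = np.asarray(labels, int)
    if len(y) != len(patches):
        raise ValueError("labels and patches lengths differ")
    if len(np.unique(y)) < 2:
        raise ValueError("stage-1 training needs both healthy and cancerous patches")
    X = _feature_matrix(patches, config)
    mlp = MLPClassifier(
        hidden_layer_sizes=config.stage1_hidden,
        max_iter=config.stage1_max_epochs,
        learning_rate_init=config.learning_rate,
        batch_size=min(config.batch_size, len(y)),
        n_iter_no_change=config.patience,
        tol=config.tol,
        random_state=config.seed,
        solver="adam",
    )
    mlp.fit(X, y)
    return Stage1Model(mlp=mlp, config=config, loss_curve=list(mlp.loss_curve_))


def train_stage2(
    patches: Sequence[np.ndarray], tc_labels, config: CascadeConfig | None = None
) -> Stage2Model:
    """Train the continuous 0-100% regressor on cancerous patches.

    Labels must lie in [0, 100]; the default configuration expects at
    least 50 training patches.
    """
    config = config or CascadeConfig()
    config.validate()
    y = np.asarray(tc_labels, float)
    if len(y) != len(patches):
        raise ValueError("labels and patches lengths differ")
    if y.size < 50:
        raise ValueError("stage-2 default configuration needs >= 50 training patches")
    if y.min() < 0.0 or y.max() > 100.0:
        raise ValueError("stage-2 labels must lie in [0, 100]")
    X = _feature_matrix(patches, config)
    mlp = MLPRegressor(
        hidden_layer_sizes=config.stage2_hidden,
        max_iter=config.stage2_max_epochs,
        learning_rate_init=config.learning_rate,
        batch_size=min(config.batch_size, len(y)),
        n_iter_no_change=config.patience,
        tol=config.tol,
        random_state=config.seed,
        solver="adam",
    )
    mlp.fit(X, y / 100.0)  # unit-scale target stabilises the squared-error loss
    return Stage2Model(mlp=mlp, config=config, loss_curve=list(mlp.loss_curve_))


def predict_cascade(
    stage1: Stage1Model,
    stage2: Stage2Model,
    patch: np.ndarray,
    threshold: float | None = None,
) -> CascadePrediction:
    """Gate then regress one patch.

    Cancer probability below the threshold means the patch is called
    healthy and scored exactly 0; otherwise stage 2 provides the score.
    """
    preds = predict_cascade_many(stage1, stage2, [patch], threshold)
    return preds[0]


def predict_cascade_many(
    stage1: Stage1Model,
    stage2: Stage2Model,
    patches: Sequence[np.ndarray],
    threshold: float | None = None,
) -> list[CascadePrediction]:
    """Vectorised cascade prediction over a patch list."""
    if stage1.config.resize_edge_px != stage2.config.resize_edge_px:
        raise ValueError("stage-1 and stage-2 models use different input sizes")
    thr = stage1.config.threshold if threshold is None else float(threshold)
    probs = stage1.cancer_probability(patches)
    gated = probs < thr
    values = np.zeros(len(patches))
    if (~gated).any():
        keep = [p for p, g in zip(patches, gated) if not g]
        values[~gated] = stage2.predict(keep)
    return [
        CascadePrediction(
            cancer_probability=float(p),
            tc_value=0.0 if g else float(v),
            stage=STAGE_GATED_HEALTHY if g else STAGE_REGRESSED,
        )
        for p, g, v in zip(probs, gated, values)
    ]


def predict_combined(
    stage1: Stage1Model,
    hand_engineered_scorer,
    patch: np.ndarray,
    threshold: float | None = None,
    patch_id: str | None = None,
):
    """Combined system: stage-1 gate, then the hand-engineered scorer.

    Returns a :class:`tcquant.scoring.TCScore` tagged ``combined``. On a
    gated-healthy patch the score is exactly 0; otherwise it equals the
    hand-engineered score for the same patch.
    """
    from .scoring import TCScore, score_patch_hand_engineered

    thr = stage1.config.threshold if threshold is None else float(threshold)
    prob = float(stage1.cancer_probability([patch])[0])
    if prob < thr:
        return TCScore(value=0.0, raw_fraction=0.0, method="combined", patch_id=patch_id)
    he = score_patch_hand_engineered(patch, hand_engineered_scorer, patch_id=patch_id)
    return TCScore(
        value=he.value,
        raw_fraction=he.raw_fraction,
        method="combined",
        patch_id=patch_id,
    )


def save_cascade(stage1: Stage1Model, stage2: Stage2Model, path) -> None:
    joblib.dump({"stage1": stage1, "stage2": stage2}, path)


def load_cascade(path) -> tuple[Stage1Model, Stage2Model]:
    bundle = joblib.load(path)
    if not (isinstance(bundle, dict) and {"stage1", "stage2"} <= set(bundle)):
        raise TypeError(f"{path} does not hold a cascade model bundle")
    return bundle["stage1"], bundle["stage2"]
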