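"""Seeded synthetic benchmarks and truth-supervised training helpers.

These functions tie the synthetic generator to the two scoring branches:
build a reproducible family of patches spanning the cellularity range,
derive nucleus-level class labels from the generator's label maps, and
train the hand-engineered bundle (SVM + calibration) or the cascade from
that supervision. They are the single construction used by the test suite,
the command line and the acceptance script, so "the benchmark" always means
the same patch family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cascade import (
    CANCEROUS,
    HEALTHY,
    CascadeConfig,
    Stage1Model,
    Stage2Model,
    train_stage1,
    train_stage2,
)
from .classify import SVMConfig, train_cell_classifier
from .features import FeatureConfig, extract_features
from .scoring import HandEngineeredModels, fit_calibration, raw_malignant_fraction
from .segmentation import NucleusSegmentation, SegmentationParams, segment_nuclei
from .stains import separate_stains
from .synthetic import (
    LABEL_BACKGROUND,
    LABEL_MALIGNANT_HALO,
    PatchGroundTruth,
    SyntheticPatchSpec,
    generate_patch,
    spec_for_target_tc,
)

LABEL_TO_CLASS = {1: "lymphocyte", 2: "epithelial", 3: "malignant"}


@dataclass
class BenchmarkPatch:
    patch_id: str
    rgb: np.ndarray
    truth: PatchGroundTruth
    target_tc: float

    @property
    def true_tc_percent(self) -> float:
        return 100.0 * self.truth.true_tc_fraction


def benchmark_patches(
    n_patches: int,
    seed: int,
    healthy_fraction: float = 0.2,
    tc_max: float = 0.9,
    base: SyntheticPatchSpec | None = None,
) -> list[BenchmarkPatch]:
    """A reproducible patch family spanning healthy to high cellularity.

    ``healthy_fraction`` of the patches contain no malignant cells (but do
    contain benign nuclei); the rest target cellularity fractions evenly
    spread over (0, tc_max]. Dense targets saturate below the request
    because nucleus placement forbids overlaps; ground truth is exact
    either way.
    """
    rng = np.random.default_rng(seed)
    n_healthy = int(round(healthy_fraction * n_patches))
    targets = np.concatenate(
        [
            np.zeros(n_healthy),
            np.linspace(0.02, tc_max, n_patches - n_healthy),
        ]
    )
    rng.shuffle(targets)
    patches = []
    for i, t in enumerate(targets):
        spec = spec_for_target_tc(
            float(t), seed=int(rng.integers(0, 2**31 - 1)), base=base
        )
        rgb, truth = generate_patch(spec)
        patches.append(
            BenchmarkPatch(
                patch_id=f"patch_{i:04d}", rgb=rgb, truth=truth, target_tc=float(t)
            )
        )
    return patches


def truth_table(patches: list[BenchmarkPatch]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patch_id": [p.patch_id for p in patches],
            "true_tc_percent": [p.true_tc_percent for p in patches],
        }
    )


def label_nuclei_from_truth(
    segmentation: NucleusSegmentation,
    truth: PatchGroundTruth,
    max_match_distance_px: float = 15.0,
) -> np.ndarray:
    """Class name per detected nucleus, or '' where no match exists.

    The label under each detection's centroid decides its class; centroids
    landing on background or halo pixels fall back to the nearest true
    nucleus centre within ``max_match_distance_px``.
    """
    classes = np.empty(segmentation.n_nuclei, dtype=object)
    records = truth.nucleus_records
    centres = records[["row", "col"]].to_numpy(float) if len(records) else None
    for i, (r, c) in enumerate(segmentation.centroids):
        label = int(truth.label_map[int(round(r)), int(round(c))])
        if label in LABEL_TO_CLASS:
            classes[i] = LABEL_TO_CLASS[label]
        elif label in (LABEL_BACKGROUND, LABEL_MALIGNANT_HALO) and centres is not None:
            d = np.hypot(centres[:, 0] - r, centres[:, 1] - c)
            j = int(d.argmin())
            classes[i] = (
                records["cell_class"].iloc[j] if d[j] <= max_match_distance_px else ""
            )
        else:
            classes[i] = ""
    return classes


def build_cell_training_table(
    patches: list[BenchmarkPatch],
    seg_params: SegmentationParams | None = None,
    feature_config: FeatureConfig | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Nucleus feature table + truth-derived class labels over patches."""
    seg_params = seg_params or SegmentationParams()
    feature_config = feature_config or FeatureConfig(
        microns_per_pixel=seg_params.microns_per_pixel
    )
    tables = []
    labels = []
    for p in patches:
        maps = separate_stains(p.rgb)
        seg = segment_nuclei(maps, seg_params)
        if seg.n_nuclei == 0:
            continue
        feats = extract_features(p.rgb, maps, seg, feature_config)
        cls = label_nuclei_from_truth(seg, p.truth)
        keep = cls != ""
        tables.append(feats[keep])
        labels.append(cls[keep])
    if not tables:
        raise ValueError("no labelled nuclei found in the training patches")
    return pd.concat(tables, ignore_index=True), np.concatenate(labels)


def train_hand_engineered(
    train_patches: list[BenchmarkPatch],
    svm_config: SVMConfig | None = None,
    seg_params: SegmentationParams | None = None,
    dilation_radius_um: float = 2.5,
    calibration_method: str = "isotonic",
) -> HandEngineeredModels:
    """Train the full hand-engineered bundle from synthetic supervision.

    The SVM learns nucleus classes from truth-labelled detections; the
    calibration maps raw dilated malignant-area fractions onto the training
    patches' true cellularity percentages.
    """
    seg_params = seg_params or SegmentationParams()
    features, labels = build_cell_training_table(train_patches, seg_params)
    classifier = train_cell_classifier(features, labels, svm_config or SVMConfig())
    models = HandEngineeredModels(
        classifier=classifier,
        calibration=None,
        segmentation_params=seg_params,
        feature_config=FeatureConfig(microns_per_pixel=seg_params.microns_per_pixel),
        dilation_radius_um=dilation_radius_um,
    )
    raw = np.array([raw_malignant_fraction(p.rgb, models) for p in train_patches])
    manual = np.array([p.true_tc_percent for p in train_patches])
    try:
        models.calibration = fit_calibration(raw, manual, calibration_method)
    except ValueError:
        models.calibration = None  # tiny/degenerate training sets: raw x 100
    return models


def cascade_training_arrays(patches: list[BenchmarkPatch]):
    """Stage-1 labels (healthy iff true TC == 0) and stage-2 targets."""
    labels = np.array(
        [HEALTHY if p.truth.true_tc_fraction == 0.0 else CANCEROUS for p in patches]
    )
    tc = np.array([p.true_tc_percent for p in patches])
    return labels, tc


def train_cascade(
    train_patches: list[BenchmarkPatch], config: CascadeConfig | None = None
) -> tuple[Stage1Model, Stage2Model]:
    """Train both cascade stages from synthetic ground truth.

    Stage 2 sees only the cancerous patches, matching the cascade design.
    """
    config = config or CascadeConfig()
    labels, tc = cascade_training_arrays(train_patches)
    images = [p.rgb for p in train_patches]
    stage1 = train_stage1(images, labels, config)
    cancer = labels == CANCEROUS
    stage2 = train_stage2(
        [img for img, c in zip(images, cancer) if c], tc[cancer], config
    )
    return stage1, stage2
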