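"""Tumour-cellularity scoring from a cell map.

The hand-engineered branch mirrors how a pathologist reads a patch: take
the nuclei classified malignant, dilate their union by a cytoplasm radius
(cellularity assessments include the cytoplasm surrounding malignant
nuclei), measure the covered area fraction, and map that fraction through a
monotone calibration fitted against manually assigned scores. Benign nuclei
(lymphocytes, epithelial cells) never contribute to the malignant area —
tumour-infiltrating lymphocytes are excluded from cellularity by
definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import joblib
import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from sklearn.isotonic import IsotonicRegression

from .classify import CellClassifierModel, classify_cells
from .features import FeatureConfig, extract_features
from .segmentation import NucleusSegmentation, SegmentationParams, segment_nuclei
from .stains import separate_stains

MALIGNANT_CLASS = "malignant"


class PipelineStageError(RuntimeError):
    """An error raised by one stage of the scoring pipeline, tagged with
    the stage name so failures are attributable."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"[{stage}] {original}")
        self.stage = stage
        self.original = original


@dataclass(frozen=True)
class TCScore:
    """A tumour-cellularity score in percent with provenance."""

    value: float
    raw_fraction: float
    method: str  # hand_engineered | cascade | combined | manual
    patch_id: Optional[str] = None

    def __post_init__(self):
        if not 0.0 <= self.value <= 100.0:
            raise ValueError("TC score must lie in [0, 100]")
        if not 0.0 <= self.raw_fraction <= 1.0:
            raise ValueError("raw fraction must lie in [0, 1]")


def malignant_mask(
    cell_map: pd.DataFrame, segmentation: NucleusSegmentation
) -> np.ndarray:
    """Binary mask of pixels belonging to nuclei classified malignant."""
    mask = np.zeros(segmentation.labeled_mask.shape, dtype=bool)
    if len(cell_map) == 0:
        return mask
    malignant_ids = cell_map.loc[
        cell_map["cell_class"] == MALIGNANT_CLASS, "nucleus_id"
    ].to_numpy()
    if malignant_ids.size == 0:
        return mask
    return np.isin(segmentation.labeled_mask, malignant_ids)


def disk_structuring_element(radius_px: int) -> np.ndarray:
    """Boolean disk: pixels whose centre distance is <= radius."""
    if radius_px < 0:
        raise ValueError("radius must be >= 0")
    yy, xx = np.mgrid[-radius_px : radius_px + 1, -radius_px : radius_px + 1]
    return (yy**2 + xx**2) <= radius_px**2


def dilate_mask(mask: np.ndarray, radius_um: float, microns_per_pixel: float) -> np.ndarray:
    """Morphological dilation by a disk of radius round(radius_um / mpp) px.

    Radius 0 (after rounding) is the identity. Negative radii are an error.
    """
    if radius_um < 0:
        raise ValueError("dilation radius must be >= 0")
    if microns_per_pixel <= 0:
        raise ValueError("microns_per_pixel must be > 0")
    radius_px = int(round(radius_um / microns_per_pixel))
    mask = np.asarray(mask, bool)
    if radius_px == 0:
        return mask.copy()
    return ndi.binary_dilation(mask, structure=disk_structuring_element(radius_px))


def area_fraction(mask: np.ndarray) -> float:
    """Fraction of pixels set in a binary mask: count(1) / total."""
    mask = np.asarray(mask)
    if mask.size == 0:
        raise ValueError("empty mask array")
    return float(np.count_nonzero(mask)) / mask.size


@dataclass
class CalibrationMap:
    """Monotone map from raw malignant-area fraction to calibrated percent.

    Fitted with isotonic regression by default (non-parametric, order
    preserving); raw fraction 0 is anchored to 0% — a patch with no
    malignant area is never assigned a positive score.
    """

    method: str
    n_pairs: int
    _iso: IsotonicRegression | None = None
    _linear: tuple[float, float] | None = None  # slope, intercept

    def apply(self, raw_fraction) -> np.ndarray:
        raw = np.atleast_1d(np.asarray(raw_fraction, float))
        if self.method == "isotonic":
            out = self._iso.predict(raw)
        elif self.method == "linear":
            slope, intercept = self._linear
            out = slope * raw + intercept
        else:
            raise ValueError(f"unknown calibration method {self.method!r}")
        out = np.clip(out, 0.0, 100.0)
        out[raw == 0.0] = 0.0
        return out


def fit_calibration(
    raw_fractions, manual_scores, method: str = "isotonic"
) -> CalibrationMap:
    """Fit the raw-fraction -> percent calibration.

    Requires >= 10 pairs spanning >= 3 distinct manual scores; a constant
    raw input is unidentifiable and raises.
    """
    raw = np.asarray(raw_fractions, float)
    manual = np.asarray(manual_scores, float)
    if raw.shape != manual.shape:
        raise ValueError("raw_fractions and manual_scores lengths differ")
    if len(raw) < 10:
        raise ValueError("calibration needs at least 10 paired observations")
    if len(np.unique(manual)) < 3:
        raise ValueError("calibration needs >= 3 distinct manual scores")
    if np.ptp(raw) < 1e-12:
        raise ValueError("constant raw fractions: calibration map unidentifiable")

    if method == "isotonic":
        iso = IsotonicRegression(y_min=0.0, y_max=100.0, out_of_bounds="clip")
        iso.fit(raw, manual)
        return CalibrationMap(method="isotonic", n_pairs=len(raw), _iso=iso)
    if method == "linear":
        slope, intercept = np.polyfit(raw, manual, 1)
        if slope < 0:
            slope = 0.0  # keep the map non-decreasing
            intercept = float(manual.mean())
        return CalibrationMap(
            method="linear", n_pairs=len(raw), _linear=(float(slope), float(intercept))
        )
    raise ValueError(f"unknown calibration method {method!r}")


@dataclass
class HandEngineeredModels:
    """Everything the hand-engineered scorer needs at test time."""

    classifier: CellClassifierModel
    calibration: CalibrationMap | None = None
    stain_vectors: tuple | None = None
    segmentation_params: SegmentationParams = field(default_factory=SegmentationParams)
    feature_config: FeatureConfig = field(default_factory=FeatureConfig)
    dilation_radius_um: float = 2.5

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "HandEngineeredModels":
        obj = joblib.load(path)
        if not isinstance(obj, HandEngineeredModels):
            raise TypeError(f"{path} does not hold HandEngineeredModels")
        return obj


def raw_malignant_fraction(
    rgb_image: np.ndarray, models: HandEngineeredModels
) -> float:
    """Uncalibrated malignant-area fraction of one patch."""
    try:
        stain_maps = separate_stains(rgb_image, models.stain_vectors)
    except Exception as e:  # noqa: BLE001 - stage tagging
        raise PipelineStageError("separate_stains", e) from e
    try:
        segmentation = segment_nuclei(stain_maps, models.segmentation_params)
    except Exception as e:
        raise PipelineStageError("segment_nuclei", e) from e
    if segmentation.n_nuclei == 0:
        return 0.0
    try:
        table = extract_features(rgb_image, stain_maps, segmentation, models.feature_config)
    except Exception as e:
        raise PipelineStageError("extract_features", e) from e
    try:
        cell_map = classify_cells(models.classifier, table, segmentation)
    except Exception as e:
        raise PipelineStageError("classify_cells", e) from e
    mask = malignant_mask(cell_map, segmentation)
    mask = dilate_mask(
        mask,
        models.dilation_radius_um,
        models.segmentation_params.microns_per_pixel,
    )
    return area_fraction(mask)


def score_patch_hand_engineered(
    rgb_image: np.ndarray,
    models: HandEngineeredModels,
    patch_id: str | None = None,
) -> TCScore:
    """End-to-end hand-engineered TC score for one patch.

    Composes stain separation -> nucleus segmentation -> feature
    extraction -> SVM cell map -> malignant mask -> cytoplasm dilation ->
    area fraction -> calibration (raw x 100 when no calibration is
    fitted). Deterministic for a fixed model bundle.
    """
    raw = raw_malignant_fraction(rgb_image, models)
    if models.calibration is not None:
        value = float(models.calibration.apply(raw)[0])
    else:
        value = 100.0 * raw
    return TCScore(
        value=float(np.clip(value, 0.0, 100.0)),
        raw_fraction=raw,
        method="hand_engineered",
        patch_id=patch_id,
    )
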