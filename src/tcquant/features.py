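"""Per-nucleus appearance, morphology, texture and spatial features.

One row per segmented nucleus, in nucleus-label order. The groups can be
switched off individually (for ablation):

appearance
    mean/s.d. of each RGB channel and of the stretched hematoxylin
    intensity inside the nucleus (8 features).
morphology
    area in µm², eccentricity, solidity, perimeter-to-area ratio (4).
texture
    grey-level co-occurrence contrast and homogeneity of the quantised
    hematoxylin channel over the nucleus bounding box (distance 1,
    horizontal offset, symmetric, normalised), plus the intensity variance
    inside the nucleus (3).
spatial
    centroid distance to the nearest neighbour (µm), mean distance to the
    k nearest (default k=5, truncated when fewer exist), and local density
    in nuclei per 100 µm² within a 50 µm radius (3). A single-nucleus patch
    gets the patch diagonal as neighbour-distance sentinel and density 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from skimage.feature import graycomatrix, graycoprops
from skimage.measure import regionprops

from .segmentation import NucleusSegmentation
from .stains import StainMaps

GLCM_LEVELS = 16

APPEARANCE_FEATURES = [
    "mean_r", "sd_r", "mean_g", "sd_g", "mean_b", "sd_b",
    "mean_hematoxylin", "sd_hematoxylin",
]
MORPHOLOGY_FEATURES = ["area_um2", "eccentricity", "solidity", "perimeter_area_ratio"]
TEXTURE_FEATURES = ["glcm_contrast", "glcm_homogeneity", "intensity_variance"]
SPATIAL_FEATURES = ["nn_distance_um", "knn_mean_distance_um", "local_density_per_100um2"]


@dataclass(frozen=True)
class FeatureConfig:
    microns_per_pixel: float = 0.5
    k_neighbors: int = 5
    density_radius_um: float = 50.0
    use_appearance: bool = True
    use_morphology: bool = True
    use_texture: bool = True
    use_spatial: bool = True

    def feature_names(self) -> list[str]:
        names: list[str] = []
        if self.use_appearance:
            names += APPEARANCE_FEATURES
        if self.use_morphology:
            names += MORPHOLOGY_FEATURES
        if self.use_texture:
            names += TEXTURE_FEATURES
        if self.use_spatial:
            names += SPATIAL_FEATURES
        return names


def quantise_hematoxylin(hematoxylin: np.ndarray, levels: int = GLCM_LEVELS) -> np.ndarray:
    """Quantise a [0, 1] map to integer grey levels 0..levels-1."""
    q = np.floor(np.clip(hematoxylin, 0.0, 1.0) * levels).astype(np.uint8)
    return np.minimum(q, levels - 1)


def glcm_features(quantised_window: np.ndarray, levels: int = GLCM_LEVELS):
    """Contrast and homogeneity of the horizontal distance-1 symmetric GLCM."""
    if quantised_window.shape[1] < 2:
        return 0.0, 1.0
    glcm = graycomatrix(
        quantised_window, [1], [0], levels=levels, symmetric=True, normed=True
    )
    return (
        float(graycoprops(glcm, "contrast")[0, 0]),
        float(graycoprops(glcm, "homogeneity")[0, 0]),
    )


def extract_features(
    rgb_image: np.ndarray,
    stain_maps: StainMaps,
    segmentation: NucleusSegmentation,
    config: FeatureConfig | None = None,
) -> pd.DataFrame:
    """Feature table with one row per nucleus, indexed by ``nucleus_id``.

    Deterministic; row order follows nucleus label order.
    """
    config = config or FeatureConfig()
    n = segmentation.n_nuclei
    names = config.feature_names()
    if n == 0:
        return pd.DataFrame(columns=names, index=pd.Index([], name="nucleus_id"))

    img = np.asarray(rgb_image, float)
    hema = stain_maps.hematoxylin
    quantised = quantise_hematoxylin(hema)
    mpp = config.microns_per_pixel

    props = regionprops(segmentation.labeled_mask)
    props = sorted(props, key=lambda p: p.label)
    rows = []
    for p in props:
        mask = segmentation.labeled_mask[p.slice] == p.label
        row: dict[str, float] = {}
        if config.use_appearance:
            for ci, ch in enumerate("rgb"):
                vals = img[p.slice][..., ci][mask]
                row[f"mean_{ch}"] = float(vals.mean())
                row[f"sd_{ch}"] = float(vals.std())
            hvals = hema[p.slice][mask]
            row["mean_hematoxylin"] = float(hvals.mean())
            row["sd_hematoxylin"] = float(hvals.std())
        if config.use_morphology:
            row["area_um2"] = float(p.area) * mpp**2
            row["eccentricity"] = float(p.eccentricity)
            row["solidity"] = float(p.solidity)
            row["perimeter_area_ratio"] = float(p.perimeter) / float(p.area)
        if config.use_texture:
            contrast, homogeneity = glcm_features(quantised[p.slice])
            row["glcm_contrast"] = contrast
            row["glcm_homogeneity"] = homogeneity
            row["intensity_variance"] = float(hema[p.slice][mask].var())
        rows.append(row)

    table = pd.DataFrame(rows, index=pd.RangeIndex(1, n + 1, name="nucleus_id"))

    if config.use_spatial:
        cent = segmentation.centroids * mpp  # µm
        diag = float(np.hypot(*[s * mpp for s in segmentation.labeled_mask.shape]))
        if n == 1:
            nn = np.array([diag])
            knn = np.array([diag])
            density = np.array([0.0])
        else:
            dist = cdist(cent, cent)
            np.fill_diagonal(dist, np.inf)
            nn = dist.min(axis=1)
            k = min(config.k_neighbors, n - 1)
            part = np.sort(dist, axis=1)[:, :k]
            knn = part.mean(axis=1)
            radius = config.density_radius_um
            counts = (dist <= radius).sum(axis=1)
            density = counts / (np.pi * radius**2 / 100.0)
        table["nn_distance_um"] = nn
        table["knn_mean_distance_um"] = knn
        table["local_density_per_100um2"] = density

    return table[names]
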