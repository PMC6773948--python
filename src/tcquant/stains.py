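"""Stain-variation suppression: optical density, stain projection, stretch.

The colour pipeline converts an RGB patch to optical density
(``OD = -log10((I + 1) / 256)``), projects each pixel's OD vector onto the
two configured stain directions (hematoxylin-like and eosin-like) by least
squares, and contrast-stretches each projection between two percentiles.
Percentile stretching cancels global brightness changes (which shift OD by
a constant) and scanner-level stain-strength variation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .synthetic import DEFAULT_EOSIN_VECTOR, DEFAULT_HEMATOXYLIN_VECTOR

DEFAULT_STRETCH_PERCENTILES = (1.0, 99.0)


@dataclass
class StainMaps:
    """Stretched per-pixel stain intensities in [0, 1] plus the metadata
    needed to undo the stretch (raw percentile values per channel)."""

    hematoxylin: np.ndarray
    eosin: np.ndarray
    stain_vectors: np.ndarray  # (2, 3) unit rows
    stretch_percentiles: tuple[float, float]
    raw_bounds: dict  # {"hematoxylin": (lo, hi), "eosin": (lo, hi)} raw OD units

    def raw_hematoxylin(self) -> np.ndarray:
        """Hematoxylin projection in raw optical-density units."""
        lo, hi = self.raw_bounds["hematoxylin"]
        return self.hematoxylin * (hi - lo) + lo


def separate_stains(
    rgb_image: np.ndarray,
    stain_vectors=None,
    stretch_percentiles: tuple[float, float] = DEFAULT_STRETCH_PERCENTILES,
) -> StainMaps:
    """Project an RGB patch onto two stain directions and contrast-stretch.

    Parameters
    ----------
    rgb_image : (H, W, 3) uint8 or float array.
    stain_vectors : pair of RGB optical-density direction vectors; defaults
        to standard H&E vectors. Must be non-collinear.
    stretch_percentiles : (low, high) percentiles mapped to 0 and 1.

    A degenerate image (all-white, all-black: no contrast between the
    stretch percentiles) yields valid all-zero maps with a warning.
    """
    img = np.asarray(rgb_image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    if stain_vectors is None:
        stain_vectors = (DEFAULT_HEMATOXYLIN_VECTOR, DEFAULT_EOSIN_VECTOR)
    vecs = np.asarray(stain_vectors, float)
    vecs = vecs / np.linalg.norm(vecs, axis=1, keepdims=True)
    if np.linalg.norm(np.cross(vecs[0], vecs[1])) < 1e-6:
        raise ValueError("stain vectors must be non-collinear")

    od = -np.log10((img.astype(float) + 1.0) / 256.0)
    # least-squares concentrations: solve OD = C @ vecs for C per pixel
    pinv = np.linalg.pinv(vecs)  # (3, 2)
    conc = od @ pinv  # (H, W, 2)

    lo_p, hi_p = stretch_percentiles
    maps = []
    bounds = {}
    for i, name in enumerate(("hematoxylin", "eosin")):
        channel = conc[..., i]
        lo, hi = np.percentile(channel, [lo_p, hi_p])
        if hi - lo < 1e-6:
            warnings.warn(
                f"degenerate stretch for {name} channel (no contrast); "
                "emitting a zero map",
                stacklevel=2,
            )
            maps.append(np.zeros(channel.shape))
            bounds[name] = (float(lo), float(lo) + 1.0)
        else:
            maps.append(np.clip((channel - lo) / (hi - lo), 0.0, 1.0))
            bounds[name] = (float(lo), float(hi))
    return StainMaps(
        hematoxylin=maps[0],
        eosin=maps[1],
        stain_vectors=vecs,
        stretch_percentiles=(float(lo_p), float(hi_p)),
        raw_bounds=bounds,
    )
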