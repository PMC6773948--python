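"""Synthetic H&E-like breast-tissue patches with per-pixel ground truth.

Every downstream stage of the cellularity pipeline (stain separation,
nucleus segmentation, cell classification, scoring, the cascade and the
agreement statistics) is exercised against patches produced here, because
the original slide cohorts behind published tumour-cellularity studies are
not publicly deposited.

A patch is a composite of textured ellipses ("nuclei") of three classes —
lymphocyte, benign epithelial and malignant — rendered through a
Beer-Lambert stain model (hematoxylin + eosin optical-density vectors).
Malignant nuclei additionally carry a cytoplasm halo, so that "area
occupied by malignant tumour cells" has an unambiguous pixel-level ground
truth: the true cellularity fraction is the fraction of pixels labelled
malignant nucleus or malignant halo.

Label conventions (uint8 label map):

====  =========================
0     background / stroma
1     lymphocyte nucleus
2     benign epithelial nucleus
3     malignant nucleus
4     malignant cytoplasm halo
====  =========================

Coordinates are 0-based ``(row, col)`` with origin top-left; all pixel
windows are half-open.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from shapely.geometry import Polygon

logger = logging.getLogger(__name__)

LABEL_BACKGROUND = 0
LABEL_LYMPHOCYTE = 1
LABEL_EPITHELIAL = 2
LABEL_MALIGNANT = 3
LABEL_MALIGNANT_HALO = 4

CLASS_NAMES = ("lymphocyte", "epithelial", "malignant")
CLASS_LABELS = {
    "lymphocyte": LABEL_LYMPHOCYTE,
    "epithelial": LABEL_EPITHELIAL,
    "malignant": LABEL_MALIGNANT,
}

#: Ruifrok–Johnson style unit optical-density vectors for H&E.
DEFAULT_HEMATOXYLIN_VECTOR = (0.650, 0.704, 0.286)
DEFAULT_EOSIN_VECTOR = (0.092, 0.954, 0.283)


class InfeasiblePackingError(ValueError):
    """Requested nucleus area exceeds the configured fill-fraction cap."""


@dataclass(frozen=True)
class NucleusClassParams:
    """Morphology/appearance model for one nucleus class.

    ``radius_mean_um`` is the equivalent-circle radius (the ellipse keeps
    the area of a circle of the sampled radius). ``od_mean`` is the mean
    hematoxylin optical density added inside the nucleus and
    ``texture_amplitude`` scales a smooth multiplicative noise field that
    gives chromatin-like texture.
    """

    radius_mean_um: float
    radius_sd_um: float
    eccentricity_range: tuple[float, float]
    od_mean: float
    od_sd: float
    texture_amplitude: float


DEFAULT_CLASS_PARAMS: dict[str, NucleusClassParams] = {
    "lymphocyte": NucleusClassParams(2.8, 0.25, (0.0, 0.3), 0.95, 0.05, 0.05),
    "epithelial": NucleusClassParams(4.5, 0.45, (0.3, 0.6), 0.50, 0.05, 0.10),
    "malignant": NucleusClassParams(6.5, 0.80, (0.2, 0.7), 0.68, 0.08, 0.30),
}


@dataclass(frozen=True)
class SyntheticPatchSpec:
    """Full description of one synthetic patch; identical spec + seed gives
    bit-identical output."""

    width_px: int = 512
    height_px: int = 512
    microns_per_pixel: float = 0.5
    n_lymphocyte: int = 0
    n_epithelial: int = 0
    n_malignant: int = 0
    class_params: dict[str, NucleusClassParams] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PARAMS)
    )
    cytoplasm_halo_radius_um: float = 2.5
    stain_vectors: tuple[tuple[float, float, float], tuple[float, float, float]] = (
        DEFAULT_HEMATOXYLIN_VECTOR,
        DEFAULT_EOSIN_VECTOR,
    )
    background_noise_sd: float = 3.0
    stroma_eosin_od: float = 0.18
    halo_eosin_od: float = 0.30
    fill_fraction_cap: float = 0.60
    max_attempts_per_nucleus: int = 200
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_lymphocyte, self.n_epithelial, self.n_malignant) < 0:
            raise ValueError("nucleus counts must be >= 0")
        if self.width_px < 1 or self.height_px < 1:
            raise ValueError("patch dimensions must be >= 1 px")
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be > 0")
        if self.cytoplasm_halo_radius_um < 0:
            raise ValueError("cytoplasm halo radius must be >= 0")
        for name, p in self.class_params.items():
            if p.radius_mean_um <= 0:
                raise ValueError(f"{name}: nucleus radius must be > 0")
        h = np.asarray(self.stain_vectors[0], float)
        e = np.asarray(self.stain_vectors[1], float)
        cross = np.linalg.norm(np.cross(h / np.linalg.norm(h), e / np.linalg.norm(e)))
        if cross < 1e-6:
            raise ValueError("stain vectors must be non-collinear")

    @property
    def counts(self) -> dict[str, int]:
        return {
            "lymphocyte": self.n_lymphocyte,
            "epithelial": self.n_epithelial,
            "malignant": self.n_malignant,
        }


@dataclass
class PatchGroundTruth:
    """Per-pixel labels plus per-nucleus records and the true cellularity."""

    label_map: np.ndarray  # uint8, labels 0..4
    nucleus_records: pd.DataFrame  # columns: cell_class, row, col, area_px
    true_tc_fraction: float
    rejected_counts: dict[str, int]

    def recompute_tc_fraction(self) -> float:
        malignant = np.isin(self.label_map, (LABEL_MALIGNANT, LABEL_MALIGNANT_HALO))
        return float(malignant.sum()) / self.label_map.size


def _ellipse_mask(shape, center_rc, a, b, theta):
    """Boolean mask of an ellipse with semi-axes a, b (px) rotated by theta."""
    r0, c0 = center_rc
    half = int(math.ceil(max(a, b))) + 1
    rmin = max(int(r0) - half, 0)
    rmax = min(int(r0) + half + 1, shape[0])
    cmin = max(int(c0) - half, 0)
    cmax = min(int(c0) + half + 1, shape[1])
    rr, cc = np.mgrid[rmin:rmax, cmin:cmax]
    dr = rr - r0
    dc = cc - c0
    ct, st = math.cos(theta), math.sin(theta)
    u = dr * ct + dc * st
    v = -dr * st + dc * ct
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return (slice(rmin, rmax), slice(cmin, cmax)), inside


def _smooth_noise(rng, shape, sigma=1.5):
    n = rng.standard_normal(shape)
    n = ndi.gaussian_filter(n, sigma)
    sd = n.std()
    if sd > 0:
        n /= sd
    return n


def generate_patch(spec: SyntheticPatchSpec):
    """Render one synthetic patch.

    Returns ``(rgb_image, ground_truth)`` where ``rgb_image`` is a
    ``(H, W, 3)`` uint8 array and ``ground_truth`` a
    :class:`PatchGroundTruth`.

    Nuclei are placed by rejection sampling (no two nuclei overlap);
    placements that cannot find room within ``max_attempts_per_nucleus``
    attempts are dropped, logged, and counted in
    ``ground_truth.rejected_counts`` — so realised counts can be lower than
    requested on dense patches. Classes draw from independent RNG streams,
    which makes the malignant pixel set monotone in ``n_malignant``.

    Raises :class:`InfeasiblePackingError` when the requested total nucleus
    area exceeds ``fill_fraction_cap`` of the patch area.
    """
    spec.validate()
    h, w = spec.height_px, spec.width_px
    mpp = spec.microns_per_pixel
    total_px = h * w

    expected_area_px = sum(
        spec.counts[name] * math.pi * (spec.class_params[name].radius_mean_um / mpp) ** 2
        for name in CLASS_NAMES
    )
    if expected_area_px > spec.fill_fraction_cap * total_px:
        raise InfeasiblePackingError(
            f"requested nucleus area {expected_area_px:.0f} px^2 exceeds "
            f"fill-fraction cap {spec.fill_fraction_cap} of the "
            f"{total_px} px^2 patch"
        )

    seq = np.random.SeedSequence(spec.seed)
    streams = {
        name: np.random.default_rng(s)
        for name, s in zip(
            ("lymphocyte", "epithelial", "malignant", "render"), seq.spawn(4)
        )
    }

    label_map = np.zeros((h, w), dtype=np.uint8)
    h_od = np.full((h, w), 0.02, dtype=float)
    e_od = np.full((h, w), spec.stroma_eosin_od, dtype=float)
    e_od += 0.03 * _smooth_noise(streams["render"], (h, w), sigma=8.0)

    records = []
    rejected = {name: 0 for name in CLASS_NAMES}

    # benign classes first, malignant last: the benign layout is then
    # independent of n_malignant (separate streams + fixed occupancy),
    # so adding malignant nuclei can only add malignant pixels.
    for name in ("lymphocyte", "epithelial", "malignant"):
        rng = streams[name]
        params = spec.class_params[name]
        cls_label = CLASS_LABELS[name]
        for _ in range(spec.counts[name]):
            placed = False
            for _attempt in range(spec.max_attempts_per_nucleus):
                r_um = rng.normal(params.radius_mean_um, params.radius_sd_um)
                r_um = float(
                    np.clip(
                        r_um,
                        params.radius_mean_um - 2 * params.radius_sd_um,
                        params.radius_mean_um + 2 * params.radius_sd_um,
                    )
                )
                r_px = max(r_um / mpp, 1.0)
                ecc = rng.uniform(*params.eccentricity_range)
                ratio = (1.0 - ecc**2) ** 0.25
                a = r_px / ratio
                b = r_px * ratio
                theta = rng.uniform(0.0, math.pi)
                margin = a + 1
                if 2 * margin >= min(h, w):
                    continue
                r0 = rng.uniform(margin, h - margin)
                c0 = rng.uniform(margin, w - margin)
                sl, inside = _ellipse_mask((h, w), (r0, c0), a, b, theta)
                if np.any(label_map[sl][inside] != LABEL_BACKGROUND):
                    continue
                label_map[sl][inside] = cls_label
                od = max(float(rng.normal(params.od_mean, params.od_sd)), 0.05)
                tex = 1.0 + params.texture_amplitude * _smooth_noise(
                    rng, inside.shape, sigma=1.5
                )
                tex = np.clip(tex, 0.2, None)
                patch_h = h_od[sl]
                patch_h[inside] += od * tex[inside]
                records.append(
                    {
                        "cell_class": name,
                        "row": r0,
                        "col": c0,
                        "area_px": int(inside.sum()),
                    }
                )
                placed = True
                break
            if not placed:
                rejected[name] += 1
        if rejected[name]:
            logger.info(
                "rejected %d/%d %s placements (seed=%d)",
                rejected[name],
                spec.counts[name],
                name,
                spec.seed,
            )

    # cytoplasm halo around malignant nuclei: labelled 4 only where the
    # pixel is not already a nucleus, rendered as an eosin boost.
    halo_px = int(round(spec.cytoplasm_halo_radius_um / mpp))
    if halo_px > 0 and np.any(label_map == LABEL_MALIGNANT):
        yy, xx = np.mgrid[-halo_px : halo_px + 1, -halo_px : halo_px + 1]
        disk = (yy**2 + xx**2) <= halo_px**2
        dilated = ndi.binary_dilation(label_map == LABEL_MALIGNANT, structure=disk)
        halo = dilated & (label_map == LABEL_BACKGROUND)
        label_map[halo] = LABEL_MALIGNANT_HALO
        e_od[halo] += spec.halo_eosin_od
        h_od[halo] += 0.04

    hvec = np.asarray(spec.stain_vectors[0], float)
    evec = np.asarray(spec.stain_vectors[1], float)
    hvec = hvec / np.linalg.norm(hvec)
    evec = evec / np.linalg.norm(evec)
    od_rgb = h_od[..., None] * hvec + e_od[..., None] * evec
    rgb = 255.0 * np.power(10.0, -od_rgb)
    if spec.background_noise_sd > 0:
        rgb = rgb + streams["render"].normal(0.0, spec.background_noise_sd, rgb.shape)
    rgb = np.clip(rgb, 0, 255).astype(np.uint8)

    records_df = pd.DataFrame(
        records, columns=["cell_class", "row", "col", "area_px"]
    )
    truth = PatchGroundTruth(
        label_map=label_map,
        nucleus_records=records_df,
        true_tc_fraction=float(
            np.isin(label_map, (LABEL_MALIGNANT, LABEL_MALIGNANT_HALO)).sum()
        )
        / total_px,
        rejected_counts=rejected,
    )
    return rgb, truth


def truth_from_label_map(label_map: np.ndarray) -> PatchGroundTruth:
    """Reconstruct ground truth from a stored label map.

    Nucleus records are recovered as connected components per nucleus
    class; the cellularity fraction is recomputed from the pixel labels.
    Used when patches round-trip through PNG/TIFF files.
    """
    label_map = np.asarray(label_map, np.uint8)
    records = []
    for name, cls_label in CLASS_LABELS.items():
        lab, n = ndi.label(label_map == cls_label)
        if n == 0:
            continue
        centroids = ndi.center_of_mass(label_map == cls_label, lab, range(1, n + 1))
        areas = np.bincount(lab.ravel())[1:]
        for (r, c), a in zip(centroids, areas):
            records.append(
                {"cell_class": name, "row": r, "col": c, "area_px": int(a)}
            )
    records_df = pd.DataFrame(records, columns=["cell_class", "row", "col", "area_px"])
    truth = PatchGroundTruth(
        label_map=label_map,
        nucleus_records=records_df,
        true_tc_fraction=0.0,
        rejected_counts={name: 0 for name in CLASS_NAMES},
    )
    truth.true_tc_fraction = truth.recompute_tc_fraction()
    return truth


@dataclass(frozen=True)
class SyntheticSlideSpec:
    """A rows x cols mosaic of patch specs plus a tumour-bed polygon
    (vertex list in slide pixel coordinates, x then y)."""

    grid: tuple[tuple[SyntheticPatchSpec, ...], ...]
    tumour_bed_polygon: tuple[tuple[float, float], ...]

    def validate(self) -> None:
        if len(self.grid) < 1 or len(self.grid[0]) < 1:
            raise ValueError("grid must be at least 1 x 1")
        ncols = len(self.grid[0])
        if any(len(row) != ncols for row in self.grid):
            raise ValueError("grid rows must all have the same length")
        poly = Polygon(self.tumour_bed_polygon)
        if not (poly.is_valid and poly.is_simple):
            raise ValueError("tumour-bed polygon must be simple (non-self-intersecting)")


def generate_slide(spec: SyntheticSlideSpec):
    """Assemble a flat slide mosaic from per-cell patch specs.

    Returns ``(mosaic_rgb, mosaic_label_map, truth_table, polygon)`` where
    ``truth_table`` has one row per grid cell with columns
    ``patch_id,row,col,true_tc_percent``.
    """
    spec.validate()
    rows = len(spec.grid)
    cols = len(spec.grid[0])
    ph = spec.grid[0][0].height_px
    pw = spec.grid[0][0].width_px
    mosaic = np.zeros((rows * ph, cols * pw, 3), dtype=np.uint8)
    labels = np.zeros((rows * ph, cols * pw), dtype=np.uint8)
    table = []
    for r in range(rows):
        for c in range(cols):
            cell = spec.grid[r][c]
            if cell.height_px != ph or cell.width_px != pw:
                raise ValueError("all grid cells must share patch dimensions")
            rgb, truth = generate_patch(cell)
            mosaic[r * ph : (r + 1) * ph, c * pw : (c + 1) * pw] = rgb
            labels[r * ph : (r + 1) * ph, c * pw : (c + 1) * pw] = truth.label_map
            table.append(
                {
                    "patch_id": f"r{r}c{c}",
                    "row": r,
                    "col": c,
                    "true_tc_percent": 100.0 * truth.true_tc_fraction,
                }
            )
    truth_table = pd.DataFrame(table)
    return mosaic, labels, truth_table, np.asarray(spec.tumour_bed_polygon, float)


def sample_manual_scores(
    truth_table: pd.DataFrame,
    rater_noise_sd: float,
    rounding_step,
    seed: int,
) -> pd.DataFrame:
    """Simulate a pathologist scoring patches from the truth table.

    ``score = clip(true TC% + N(0, sd), 0, 100)`` rounded to
    ``rounding_step`` (``None``/"continuous", 5 or 10). Patches whose true
    cellularity is exactly zero are always scored 0 — raters reliably
    recognise tumour-free tissue.
    """
    if rater_noise_sd < 0:
        raise ValueError("rater_noise_sd must be >= 0")
    if rounding_step not in (None, "continuous", 5, 10):
        raise ValueError("rounding_step must be one of None/'continuous', 5, 10")
    rng = np.random.default_rng(seed)
    truth = truth_table["true_tc_percent"].to_numpy(float)
    scores = np.clip(truth + rng.normal(0.0, rater_noise_sd, truth.shape), 0.0, 100.0)
    if rounding_step in (5, 10):
        scores = np.round(scores / rounding_step) * rounding_step
    scores[truth == 0.0] = 0.0
    return pd.DataFrame(
        {"patch_id": truth_table["patch_id"].to_numpy(), "score": scores}
    )


def spec_for_target_tc(
    target_tc: float,
    seed: int,
    *,
    base: SyntheticPatchSpec | None = None,
    n_lymphocyte: int | None = None,
    n_epithelial: int | None = None,
) -> SyntheticPatchSpec:
    """Patch spec whose malignant count aims at a target cellularity fraction.

    The count is set from the expected per-nucleus pixel yield (nucleus plus
    cytoplasm halo). Dense targets saturate below the request because
    placement rejects overlaps; the emitted ground truth is always exact.
    """
    if not 0.0 <= target_tc <= 1.0:
        raise ValueError("target_tc must be in [0, 1]")
    base = base or SyntheticPatchSpec()
    rng = np.random.default_rng(seed)
    n_lym = int(rng.integers(5, 40)) if n_lymphocyte is None else n_lymphocyte
    n_epi = int(rng.integers(5, 30)) if n_epithelial is None else n_epithelial
    mpp = base.microns_per_pixel
    r_px = base.class_params["malignant"].radius_mean_um / mpp
    halo_px = base.cytoplasm_halo_radius_um / mpp
    yield_px = math.pi * (r_px + halo_px) ** 2 * 0.92  # ~8% halo overlap loss
    n_mal = int(round(target_tc * base.width_px * base.height_px / yield_px))
    return replace(
        base,
        n_lymphocyte=n_lym,
        n_epithelial=n_epi,
        n_malignant=n_mal,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
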