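"""Nucleus features (with a naive per-pixel oracle) and SVM classification."""

import numpy as np
import pandas as pd
import pytest

from tcquant.classify import SVMConfig, classify_cells, train_cell_classifier
from tcquant.features import (
    GLCM_LEVELS,
    FeatureConfig,
    extract_features,
    quantise_hematoxylin,
)
from tcquant.benchmark import build_cell_training_table, label_nuclei_from_truth
from tcquant.segmentation import segment_nuclei
from tcquant.stains import separate_stains
from tcquant.synthetic import generate_patch

from conftest import small_spec
from test_stains_segmentation import render_disks


# ---------------------------------------------------------------- oracle ---
def naive_features(rgb, stain_maps, segmentation, mpp=0.5, k=5, radius_um=50.0):
    """Independent per-pixel reimplementation of the feature definitions
    using explicit loops (no regionprops / graycomatrix)."""
    img = np.asarray(rgb, float)
    hema = stain_maps.hematoxylin
    q = quantise_hematoxylin(hema)
    lm = segmentation.labeled_mask
    out = {}
    centroids = {}
    for nid in range(1, segmentation.n_nuclei + 1):
        coords = np.argwhere(lm == nid)
        pix_rgb = np.array([img[r, c] for r, c in coords])
        pix_h = np.array([hema[r, c] for r, c in coords])
        row = {}
        for ci, ch in enumerate("rgb"):
            row[f"mean_{ch}"] = pix_rgb[:, ci].mean()
            row[f"sd_{ch}"] = pix_rgb[:, ci].std()
        row["mean_hematoxylin"] = pix_h.mean()
        row["sd_hematoxylin"] = pix_h.std()
        # area and eccentricity from raw central moments
        area = len(coords)
        row["area_um2"] = area * mpp**2
        rbar, cbar = coords.mean(axis=0)
        mu20 = ((coords[:, 0] - rbar) ** 2).sum() / area
        mu02 = ((coords[:, 1] - cbar) ** 2).sum() / area
        mu11 = ((coords[:, 0] - rbar) * (coords[:, 1] - cbar)).sum() / area
        common = np.sqrt((mu20 - mu02) ** 2 + 4 * mu11**2)
        l1 = (mu20 + mu02 + common) / 2
        l2 = (mu20 + mu02 - common) / 2
        row["eccentricity"] = np.sqrt(1 - l2 / l1) if l1 > 0 else 0.0
        # GLCM over the bounding box: horizontal distance-1, symmetric, normed
        rmin, cmin = coords.min(axis=0)
        rmax, cmax = coords.max(axis=0)
        window = q[rmin : rmax + 1, cmin : cmax + 1]
        counts = np.zeros((GLCM_LEVELS, GLCM_LEVELS))
        for r in range(window.shape[0]):
            for c in range(window.shape[1] - 1):
                counts[window[r, c], window[r, c + 1]] += 1
                counts[window[r, c + 1], window[r, c]] += 1
        p = counts / counts.sum()
        contrast = homogeneity = 0.0
        for i in range(GLCM_LEVELS):
            for j in range(GLCM_LEVELS):
                contrast += p[i, j] * (i - j) ** 2
                homogeneity += p[i, j] / (1 + (i - j) ** 2)
        row["glcm_contrast"] = contrast
        row["glcm_homogeneity"] = homogeneity
        row["intensity_variance"] = pix_h.var()
        centroids[nid] = (rbar, cbar)
        out[nid] = row
    # spatial features from centroid distances
    ids = sorted(out)
    pts = np.array([centroids[i] for i in ids]) * mpp
    for idx, nid in enumerate(ids):
        d = [
            float(np.hypot(*(pts[idx] - pts[j])))
            for j in range(len(ids))
            if j != idx
        ]
        d.sort()
        out[nid]["nn_distance_um"] = d[0]
        kk = min(k, len(d))
        out[nid]["knn_mean_distance_um"] = float(np.mean(d[:kk]))
        within = sum(1 for x in d if x <= radius_um)
        out[nid]["local_density_per_100um2"] = within / (np.pi * radius_um**2 / 100)
    return pd.DataFrame([out[i] for i in ids], index=pd.Index(ids, name="nucleus_id"))


@pytest.fixture(scope="module")
def small_pipeline():
    rgb, truth = generate_patch(
        small_spec(n_lymphocyte=4, n_epithelial=3, n_malignant=4, seed=19)
    )
    maps = separate_stains(rgb)
    seg = segment_nuclei(maps)
    return rgb, truth, maps, seg


class TestExtractFeatures:
    def test_matches_naive_per_pixel_oracle(self, small_pipeline):
        rgb, _, maps, seg = small_pipeline
        assert seg.n_nuclei >= 8
        table = extract_features(rgb, maps, seg)
        oracle = naive_features(rgb, maps, seg)
        # solidity and perimeter-to-area depend on library-specific convex
        # hull rasterisation / contour weights; checked separately below
        shared = [c for c in table.columns if c in oracle.columns]
        for col in shared:
            assert np.allclose(
                table[col].to_numpy(), oracle[col].to_numpy(), atol=1e-6
            ), col

    def test_symmetric_pair_shares_nearest_neighbour_distance(self):
        rgb = render_disks([(40, 40), (40, 90)], radius_px=8)
        maps = separate_stains(rgb)
        seg = segment_nuclei(maps)
        assert seg.n_nuclei == 2
        table = extract_features(rgb, maps, seg)
        d = np.hypot(*(seg.centroids[0] - seg.centroids[1])) * 0.5
        assert table["nn_distance_um"].to_numpy() == pytest.approx([d, d])

    def test_circular_nucleus_shape_limits(self):
        # analytic limit on an ideal rasterised disk, bypassing segmentation
        from tcquant.segmentation import NucleusSegmentation

        radius = 20  # large enough that hull rasterisation error is < 5%
        rgb = render_disks([(64, 64)], radius_px=radius)
        maps = separate_stains(rgb)
        rr, cc = np.mgrid[:128, :128]
        disk = ((rr - 64) ** 2 + (cc - 64) ** 2 <= radius**2).astype(np.int32)
        seg = NucleusSegmentation(
            labeled_mask=disk,
            areas_px=np.array([disk.sum()]),
            centroids=np.array([[64.0, 64.0]]),
            boundaries=[],
        )
        table = extract_features(rgb, maps, seg)
        assert table["eccentricity"].iloc[0] <= 0.05
        assert table["solidity"].iloc[0] >= 0.95
        # perimeter/area of a rasterised disk ~ 2/r in pixel units
        assert table["perimeter_area_ratio"].iloc[0] == pytest.approx(
            2 / radius, rel=0.2
        )

    def test_single_nucleus_uses_diagonal_sentinel(self):
        rgb = render_disks([(64, 64)], radius_px=10)
        maps = separate_stains(rgb)
        seg = segment_nuclei(maps)
        table = extract_features(rgb, maps, seg)
        diag = np.hypot(128, 128) * 0.5
        assert table["nn_distance_um"].iloc[0] == pytest.approx(diag)
        assert table["local_density_per_100um2"].iloc[0] == 0.0

    def test_empty_segmentation_gives_empty_table(self):
        rgb, _ = generate_patch(small_spec(seed=3))
        maps = separate_stains(rgb)
        seg = segment_nuclei(maps)
        table = extract_features(rgb, maps, seg)
        assert len(table) == 0
        assert list(table.columns) == FeatureConfig().feature_names()

    def test_group_switches_change_dimensionality(self, small_pipeline):
        rgb, _, maps, seg = small_pipeline
        no_texture = FeatureConfig(use_texture=False)
        table = extract_features(rgb, maps, seg, no_texture)
        assert list(table.columns) == no_texture.feature_names()
        assert "glcm_contrast" not in table.columns

    def test_translation_invariance_for_interior_nuclei(self, small_pipeline):
        rgb, _, maps, seg = small_pipeline
        shifted = rgb[10:, 10:]
        maps2 = separate_stains(shifted)
        seg2 = segment_nuclei(maps2)
        t1 = extract_features(rgb, maps, seg)
        t2 = extract_features(shifted, maps2, seg2)
        # match nuclei across the crop by centroid offset
        static_cols = [
            c
            for c in t1.columns
            if not c.endswith("_um") and c != "local_density_per_100um2"
        ]
        matched = 0
        for i, (r, c) in enumerate(seg.centroids):
            if r < 25 or c < 25:  # skip nuclei near the cropped margin
                continue
            d = np.hypot(seg2.centroids[:, 0] - (r - 10), seg2.centroids[:, 1] - (c - 10))
            j = int(d.argmin())
            if d[j] > 2.0:
                continue
            matched += 1
            a = t1.iloc[i][static_cols].to_numpy(float)
            b = t2.iloc[j][static_cols].to_numpy(float)
            # GLCM features quantise the stretched map, so small stretch
            # shifts move discrete counts; allow a wider relative band
            assert np.allclose(a, b, atol=0.05, rtol=0.15)
        assert matched >= 3


class TestCellClassifier:
    @pytest.fixture(scope="class")
    def training_data(self):
        patches = []
        from tcquant.benchmark import BenchmarkPatch

        for seed in range(6):
            spec = small_spec(
                n_lymphocyte=6, n_epithelial=5, n_malignant=5, seed=100 + seed
            )
            rgb, truth = generate_patch(spec)
            patches.append(
                BenchmarkPatch(patch_id=f"t{seed}", rgb=rgb, truth=truth, target_tc=0)
            )
        return build_cell_training_table(patches)

    def test_separable_classes_high_heldout_accuracy(self, training_data):
        feats, labels = training_data
        rng = np.random.default_rng(0)
        idx = rng.permutation(len(feats))
        cut = int(0.7 * len(idx))
        model = train_cell_classifier(feats.iloc[idx[:cut]], labels[idx[:cut]])
        pred = model.pipeline.predict(feats.iloc[idx[cut:]].to_numpy(float))
        assert (pred == labels[idx[cut:]]).mean() >= 0.95

    def test_training_is_deterministic(self, training_data):
        feats, labels = training_data
        m1 = train_cell_classifier(feats, labels)
        m2 = train_cell_classifier(feats, labels)
        X = feats.to_numpy(float)
        assert np.array_equal(
            m1.pipeline.decision_function(X), m2.pipeline.decision_function(X)
        )

    def test_permuted_labels_give_chance_accuracy(self, training_data):
        feats, labels = training_data
        rng = np.random.default_rng(1)
        shuffled = rng.permutation(labels)
        idx = rng.permutation(len(feats))
        cut = int(0.7 * len(idx))
        model = train_cell_classifier(feats.iloc[idx[:cut]], shuffled[idx[:cut]])
        pred = model.pipeline.predict(feats.iloc[idx[cut:]].to_numpy(float))
        acc = (pred == shuffled[idx[cut:]]).mean()
        assert abs(acc - 1 / 3) <= 0.15

    def test_training_accuracy_at_least_heldout(self, training_data):
        feats, labels = training_data
        rng = np.random.default_rng(2)
        idx = rng.permutation(len(feats))
        cut = int(0.7 * len(idx))
        model = train_cell_classifier(feats.iloc[idx[:cut]], labels[idx[:cut]])
        train_acc = (
            model.pipeline.predict(feats.iloc[idx[:cut]].to_numpy(float))
            == labels[idx[:cut]]
        ).mean()
        test_acc = (
            model.pipeline.predict(feats.iloc[idx[cut:]].to_numpy(float))
            == labels[idx[cut:]]
        ).mean()
        assert train_acc >= test_acc - 1e-9

    def test_single_class_rejected(self, training_data):
        feats, labels = training_data
        only = labels == "malignant"
        with pytest.raises(ValueError, match="two classes"):
            train_cell_classifier(feats[only], labels[only])

    def test_nan_features_rejected_naming_column(self, training_data):
        feats, labels = training_data
        bad = feats.copy()
        bad.iloc[0, bad.columns.get_loc("area_um2")] = np.nan
        with pytest.raises(ValueError, match="area_um2"):
            train_cell_classifier(bad, labels)

    def test_standardisation_roundtrip(self, training_data):
        feats, labels = training_data
        model = train_cell_classifier(feats, labels)
        scaler = model.pipeline.named_steps["scale"]
        X = feats.to_numpy(float)
        assert np.allclose(scaler.inverse_transform(scaler.transform(X)), X, atol=1e-9)

    def test_classify_cells_contract(self, small_pipeline_module_scope=None):
        rgb, truth = generate_patch(
            small_spec(n_lymphocyte=10, n_epithelial=8, n_malignant=6, seed=300)
        )
        maps = separate_stains(rgb)
        seg = segment_nuclei(maps)
        feats = extract_features(rgb, maps, seg)
        labels = label_nuclei_from_truth(seg, truth)
        keep = labels != ""
        model = train_cell_classifier(feats[keep], labels[keep], SVMConfig())
        cell_map = classify_cells(model, feats, seg)
        assert len(cell_map) == seg.n_nuclei
        score_cols = [c for c in cell_map.columns if c.startswith("score_")]
        assert np.allclose(cell_map[score_cols].sum(axis=1), 1.0)
        # dimensionality mismatch rejected
        with pytest.raises(ValueError, match="contract"):
            classify_cells(model, feats.drop(columns=["area_um2"]), seg)

    def test_empty_features_give_empty_cellmap(self, training_data):
        feats, labels = training_data
        model = train_cell_classifier(feats, labels)
        from tcquant.segmentation import NucleusSegmentation

        empty_seg = NucleusSegmentation(
            labeled_mask=np.zeros((16, 16), np.int32),
            areas_px=np.zeros(0, int),
            centroids=np.zeros((0, 2)),
            boundaries=[],
        )
        empty = feats.iloc[:0]
        cell_map = classify_cells(model, empty, empty_seg)
        assert len(cell_map) == 0


def test_nucleus_classification_gate_on_benchmark(he_models, bench_test):
    """Truth-labelled nucleus accuracy >= 0.90 on held-out patches."""
    correct = total = 0
    for p in bench_test[:15]:
        maps = separate_stains(p.rgb)
        seg = segment_nuclei(maps, he_models.segmentation_params)
        if seg.n_nuclei == 0:
            continue
        feats = extract_features(p.rgb, maps, seg, he_models.feature_config)
        cell_map = classify_cells(he_models.classifier, feats, seg)
        labels = label_nuclei_from_truth(seg, p.truth)
        keep = labels != ""
        correct += (cell_map["cell_class"].to_numpy()[keep] == labels[keep]).sum()
        total += keep.sum()
    assert total > 100
    assert correct / total >= 0.90
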