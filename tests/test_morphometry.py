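"""Vessel morphometry: preprocessing, density, skeleton classes, group stats."""

import numpy as np
import pandas as pd
import pytest
import scipy.ndimage as ndi

from fateseg import generate_vessel_volume, straight_tube, y_tree
from fateseg.morphometry import (
    ROI,
    batch_pca,
    classify_voxels,
    density,
    group_variability,
    preprocess,
    skeletonize3d,
)


def brute_force_classes(skel):
    """Literal 26-neighbor counting over every voxel."""
    counts = {"end_point": 0, "slab": 0, "junction": 0}
    nz, ny, nx = skel.shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not skel[z, y, x]:
                    continue
                n = 0
                for dz in (-1, 0, 1):
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            if dz == dy == dx == 0:
                                continue
                            zz, yy, xx = z + dz, y + dy, x + dx
                            if 0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx:
                                n += bool(skel[zz, yy, xx])
                if n < 2:
                    counts["end_point"] += 1
                elif n == 2:
                    counts["slab"] += 1
                else:
                    counts["junction"] += 1
    return counts


def test_voxel_classes_match_brute_force_on_random_skeletons():
    rng = np.random.default_rng(17)
    for _ in range(25):
        skel = rng.random((5, 5, 5)) < 0.25
        got = classify_voxels(skel)
        want = brute_force_classes(skel)
        for key in ("end_point", "slab", "junction"):
            assert got[key] == want[key], key
        assert got["total"] == skel.sum()


def test_single_voxel_and_straight_path_classes():
    single = np.zeros((3, 3, 3), dtype=bool)
    single[1, 1, 1] = True
    assert classify_voxels(single) == {
        "end_point": 1, "slab": 0, "junction": 0, "junction_nodes": 0, "total": 1}
    path = np.zeros((3, 3, 12), dtype=bool)
    path[1, 1, 1:11] = True  # 10-voxel straight path
    c = classify_voxels(path)
    assert (c["end_point"], c["slab"], c["junction"]) == (2, 8, 0)


def test_classes_invariant_to_flips_and_translation():
    rng = np.random.default_rng(3)
    skel = rng.random((6, 6, 6)) < 0.2
    base = classify_voxels(skel)
    flipped = classify_voxels(skel[::-1, :, ::-1])
    shifted = np.zeros((9, 9, 9), dtype=bool)
    shifted[2:8, 1:7, 3:9] = skel
    moved = classify_voxels(shifted)
    for key in ("end_point", "slab", "junction", "total"):
        assert base[key] == flipped[key] == moved[key]


def test_preprocess_flat_volume_empty_foreground():
    vol = np.full((16, 16, 16), 50.0)
    binary = preprocess(vol, bg_radius=5, median_radius=1, threshold=10.0)
    assert not binary.any()


def test_preprocess_recovers_noiseless_tube():
    vol, truth = straight_tube(noise_sd=0.0)
    binary = preprocess(vol, bg_radius=15, median_radius=1, threshold="auto")
    tube = ndi.distance_transform_edt(~truth.centerline) <= 2.0
    jaccard = (binary & tube).sum() / (binary | tube).sum()
    assert jaccard >= 0.95


def test_preprocess_threshold_out_of_range_rejected():
    vol, _ = straight_tube(noise_sd=0.0)
    with pytest.raises(ValueError, match="outside"):
        preprocess(vol, threshold=1e6)


def test_density_matches_voxel_count_oracle():
    rng = np.random.default_rng(5)
    binary = rng.random((20, 20, 20)) < 0.3
    roi = ROI("r", 2, 12, 3, 18, 0, 20)
    sub = binary[2:12, 3:18, 0:20]
    assert density(binary, roi) == pytest.approx(100.0 * sub.sum() / sub.size)
    assert density(np.ones((4, 4, 4), dtype=bool)) == 100.0
    half = np.zeros((4, 4, 4), dtype=bool)
    half[:2] = True
    assert density(half) == 50.0


def test_density_roi_validation():
    binary = np.zeros((5, 5, 5), dtype=bool)
    with pytest.raises(ValueError):
        density(binary, ROI("bad", 0, 9, 0, 5, 0, 5))
    with pytest.raises(ValueError):
        density(binary, ROI("empty", 2, 2, 0, 5, 0, 5))


def test_skeletonize_empty_and_straight_tube():
    empty = skeletonize3d(np.zeros((8, 8, 8), dtype=bool))
    assert empty.n_voxels == 0
    vol, _ = straight_tube(noise_sd=0.0)
    binary = preprocess(vol, threshold="auto")
    sv = skeletonize3d(binary)
    counts = classify_voxels(sv)
    assert counts["end_point"] == 2
    assert counts["junction_nodes"] == 0
    # skeleton is a subset of its source foreground
    assert not (sv.skeleton & ~binary).any()
    # single 26-connected path
    from skimage.measure import label

    assert label(sv.skeleton, connectivity=3).max() == 1


def test_y_tree_recovers_three_endpoints_one_junction():
    vol, truth = y_tree(noise_sd=0.0)
    binary = preprocess(vol, threshold="auto")
    counts = classify_voxels(skeletonize3d(binary))
    assert counts["end_point"] == truth.n_endpoints == 3
    assert counts["junction_nodes"] == truth.n_junctions == 1


def test_skeletonization_preserves_component_count():
    vol1, _ = y_tree(noise_sd=0.0)
    vol2, _ = straight_tube(noise_sd=0.0, shape=(56, 56, 56))
    from skimage.measure import label

    binary = preprocess(vol1 + np.roll(vol2, 20, axis=0), threshold="auto")
    sv = skeletonize3d(binary)
    assert label(sv.skeleton, connectivity=3).max() == label(binary, connectivity=3).max()


def test_junction_recovery_across_seeds():
    """Detected junction count within ±1 of ground truth at zero noise."""
    for seed in range(10):
        vol, truth = generate_vessel_volume(5, noise_sd=0.0, seed=seed)
        binary = preprocess(vol, threshold="auto")
        counts = classify_voxels(skeletonize3d(binary))
        assert abs(counts["junction_nodes"] - truth.n_junctions) <= 1


def test_group_variability_closed_form():
    table = group_variability([10, 10, 10, 8, 12], ["c", "c", "c", "k", "k"])
    by = table.set_index("group")
    assert by.loc["c", "sd"] == 0.0 and by.loc["c", "cv_percent"] == 0.0
    assert by.loc["k", "mean"] == pytest.approx(10.0)
    assert by.loc["k", "sd"] == pytest.approx(np.sqrt(8))
    assert by.loc["k", "cv_percent"] == pytest.approx(100 * np.sqrt(8) / 10)
    with pytest.raises(ValueError, match="need >= 2"):
        group_variability([1.0, 2.0, 3.0], ["a", "a", "b"])


def test_injected_variance_ratio_yields_cv_ratio():
    """Variance ratio 4 between groups gives a CV ratio of 2."""
    z = np.array([-1.5, -0.5, 0.5, 1.5, -1.0, 1.0])
    z = (z - z.mean()) / z.std(ddof=1)
    control = 10 + 1.0 * z
    ko = 10 + 2.0 * z
    table = group_variability(
        np.concatenate([control, ko]), ["control"] * 6 + ["ko"] * 6
    ).set_index("group")
    ratio = table.loc["ko", "cv_percent"] / table.loc["control", "cv_percent"]
    assert ratio == pytest.approx(2.0, rel=0.10)


def brute_force_pca(X):
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    return Xc @ v[:, order], w[order]


def test_batch_pca_matches_eigendecomposition():
    rng = np.random.default_rng(11)
    X = rng.random((8, 5))
    table = pd.DataFrame(X, index=[f"e{i}" for i in range(8)])
    coords, _ = batch_pca(table, ["b1"] * 4 + ["b2"] * 4)
    ref, w = brute_force_pca(X)
    for j in range(2):
        got = coords[f"PC{j + 1}"].to_numpy()
        np.testing.assert_allclose(np.abs(got), np.abs(ref[:, j]), atol=1e-8)


def test_batch_pca_rank_one_and_identical_embryos():
    base = np.array([1.0, 2.0, 3.0])
    X = np.outer([1.0, 2.0, 3.0, 4.0], base)
    table = pd.DataFrame(X)
    coords, summary = batch_pca(table, ["b1", "b1", "b2", "b2"])
    evr = coords.attrs["explained_variance_ratio"]
    assert evr[0] == pytest.approx(1.0)
    X2 = np.vstack([X, X[0]])
    coords2, _ = batch_pca(pd.DataFrame(X2), ["b1"] * 5)
    np.testing.assert_allclose(
        coords2.iloc[0, :1].to_numpy(dtype=float),
        coords2.iloc[4, :1].to_numpy(dtype=float), atol=1e-9)
    with pytest.raises(ValueError, match="constant"):
        batch_pca(pd.DataFrame(np.ones((4, 3))), ["a"] * 4)
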