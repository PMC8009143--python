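"""Keypoints, matching and geometric verification."""

import numpy as np
import pytest

from gastro3d.features import (
    Keypoint,
    MatchSet,
    detect_and_describe,
    geometric_verify,
    match_consistency_curve,
    match_pair,
)
from gastro3d.geometry import CameraIntrinsics, look_at_pose

INTR = CameraIntrinsics(fx=150, fy=150, cx=63.5, cy=63.5, width=128, height=128)


def test_constant_image_yields_no_keypoints():
    kps, desc = detect_and_describe(np.full((64, 64), 0.5))
    assert kps == [] and desc.shape == (0, 128)


def test_single_gaussian_blob_is_found_at_its_center():
    u, v = np.meshgrid(np.arange(128.0), np.arange(128.0))
    img = 0.2 + 0.8 * np.exp(-(((u - 50) ** 2 + (v - 50) ** 2) / (2 * 4.0**2)))
    kps, desc = detect_and_describe(img)
    assert len(kps) >= 1
    d = [np.hypot(k.x - 50, k.y - 50) for k in kps]
    assert min(d) < 1.0


def test_tiny_image_is_rejected():
    with pytest.raises(ValueError):
        detect_and_describe(np.zeros((8, 8)))


def test_self_matching_is_the_identity():
    rng = np.random.default_rng(0)
    desc = rng.random((30, 128))
    desc /= np.linalg.norm(desc, axis=1, keepdims=True)
    ms = match_pair(desc, desc, ratio=0.99)
    assert len(ms) == 30
    assert np.array_equal(ms.pairs[:, 0], ms.pairs[:, 1])
    assert np.allclose(ms.distances, 0.0, atol=1e-12)


def test_planted_identical_descriptors_are_recovered():
    rng = np.random.default_rng(1)
    planted = rng.random((10, 128))
    noise_a = rng.random((90, 128))
    noise_b = rng.random((90, 128))
    da = np.vstack([planted, noise_a])
    db = np.vstack([planted, noise_b])
    da /= np.linalg.norm(da, axis=1, keepdims=True)
    db /= np.linalg.norm(db, axis=1, keepdims=True)
    ms = match_pair(da, db, ratio=0.8)
    got = {tuple(p) for p in ms.pairs}
    for i in range(10):
        assert (i, i) in got


def test_matching_is_symmetric_after_cross_check():
    rng = np.random.default_rng(2)
    da = rng.random((40, 128))
    db = rng.random((35, 128))
    ms_ab = match_pair(da, db)
    ms_ba = match_pair(db, da)
    ab = {tuple(p) for p in ms_ab.pairs}
    ba = {(j, i) for i, j in ms_ba.pairs}
    # the mutual-nearest-neighbour core is identical in both directions
    assert ab & ba == ab or ab & ba == ba


def test_empty_descriptor_side_gives_empty_match_set():
    with pytest.warns(UserWarning):
        ms = match_pair(np.zeros((0, 128)), np.random.random((5, 128)))
    assert len(ms) == 0


def _projected_scene(n=80, outlier_frac=0.0, seed=0):
    rng = np.random.default_rng(seed)
    pts = rng.uniform([-0.4, -0.4, 1.5], [0.4, 0.4, 2.5], size=(n, 3))
    p1 = look_at_pose([0, 0, 0], [0, 0, 1], [0, 1, 0])
    p2 = look_at_pose([0.3, 0.05, 0.02], [0.25, 0, 1], [0, 1, 0])
    a = INTR.project(p1.transform(pts))
    b = INTR.project(p2.transform(pts))
    outliers = np.zeros(n, dtype=bool)
    n_out = int(outlier_frac * n)
    if n_out:
        idx = rng.choice(n, n_out, replace=False)
        b[idx] += rng.uniform(15, 40, size=(n_out, 2)) * rng.choice([-1, 1], (n_out, 2))
        outliers[idx] = True
    kps_a = [Keypoint(x=p[0], y=p[1], scale=1, orientation=0) for p in a]
    kps_b = [Keypoint(x=p[0], y=p[1], scale=1, orientation=0) for p in b]
    pairs = np.column_stack([np.arange(n), np.arange(n)])
    ms = MatchSet(0, 1, pairs, np.zeros(n))
    return ms, kps_a, kps_b, outliers


def test_verification_accepts_exact_two_view_geometry():
    ms, ka, kb, _ = _projected_scene()
    ms = geometric_verify(ms, ka, kb, INTR, seed=0)
    assert ms.inliers.all()


def test_verification_separates_planted_outliers():
    ms, ka, kb, outliers = _projected_scene(n=100, outlier_frac=0.5, seed=3)
    ms = geometric_verify(ms, ka, kb, INTR, seed=0)
    inl = ms.inliers
    recall = inl[~outliers].mean()
    leaked = inl[outliers].mean()
    assert recall >= 0.95
    assert leaked <= 0.05


def test_fewer_than_eight_matches_are_all_outliers():
    ms, ka, kb, _ = _projected_scene(n=7)
    ms = geometric_verify(ms, ka, kb, INTR, seed=0)
    assert len(ms) == 7 and not ms.inliers.any()


def test_verification_is_deterministic_given_seed():
    ms1, ka, kb, _ = _projected_scene(n=60, outlier_frac=0.3, seed=5)
    ms2, _, _, _ = _projected_scene(n=60, outlier_frac=0.3, seed=5)
    r1 = geometric_verify(ms1, ka, kb, INTR, seed=9).inliers
    r2 = geometric_verify(ms2, ka, kb, INTR, seed=9).inliers
    assert np.array_equal(r1, r2)


def test_consistency_curve_rejects_wrong_frame_count():
    frames = [np.zeros((64, 64))] * 10
    with pytest.raises(ValueError):
        match_consistency_curve(frames, INTR)


def test_consistency_curve_is_flat_for_identical_images():
    rng = np.random.default_rng(4)
    from scipy.ndimage import gaussian_filter

    img = gaussian_filter(rng.random((128, 128)), 1.5)
    curve, avg_kp = match_consistency_curve([img] * 11, INTR)
    assert avg_kp > 0
    assert len(curve) == 10
    assert (curve == curve[0]).all()
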