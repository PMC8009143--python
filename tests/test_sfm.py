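"""Two-view geometry, triangulation, registration, bundle adjustment."""

import copy

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from gastro3d.features import Keypoint, MatchSet
from gastro3d.geometry import (
    CameraIntrinsics,
    Pose,
    angle_between_deg,
    look_at_pose,
    rotation_angle_deg,
)
from gastro3d.sfm import (
    ReconstructionModel,
    Track,
    TriangulationError,
    bundle_adjust,
    estimate_two_view,
    reconstruction_stats,
    register_frame,
    run_incremental_sfm,
    triangulate,
)

INTR = CameraIntrinsics(fx=150, fy=150, cx=79.5, cy=79.5, width=160, height=160)


# ---------------------------------------------------------------------------
# triangulation


def test_symmetric_two_view_point_is_recovered_exactly():
    p1 = look_at_pose([-0.5, 0, 0], [0, 0, 2], [0, 1, 0])
    p2 = look_at_pose([0.5, 0, 0], [0, 0, 2], [0, 1, 0])
    X = np.array([0.0, 0.0, 2.0])
    obs = [(p1, INTR.project(p1.transform(X))[0]), (p2, INTR.project(p2.transform(X))[0])]
    Xh = triangulate(obs, INTR)
    assert np.linalg.norm(Xh - X) < 1e-9


def test_zero_baseline_is_rejected_with_reason():
    p = look_at_pose([0, 0, 0], [0, 0, 1], [0, 1, 0])
    with pytest.raises(TriangulationError, match="baseline"):
        triangulate([(p, np.array([80.0, 80.0])), (p, np.array([81.0, 80.0]))], INTR)


def test_small_triangulation_angle_is_rejected():
    p1 = look_at_pose([0, 0, 0], [0, 0, 1], [0, 1, 0])
    p2 = look_at_pose([0.001, 0, 0], [0.001, 0, 1], [0, 1, 0])
    X = np.array([0.0, 0.0, 2.0])
    obs = [(p1, INTR.project(p1.transform(X))[0]), (p2, INTR.project(p2.transform(X))[0])]
    with pytest.raises(TriangulationError, match="angle"):
        triangulate(obs, INTR, min_angle_deg=1.0)


def test_noise_grows_with_depth_to_baseline_ratio():
    """Median triangulation error is monotone in distance at fixed baseline."""
    rng = np.random.default_rng(0)
    p1 = look_at_pose([-0.15, 0, 0], [0, 0, 2], [0, 1, 0])
    p2 = look_at_pose([0.15, 0, 0], [0, 0, 2], [0, 1, 0])
    med = []
    for depth in (1.5, 3.0, 6.0):
        errs = []
        for _ in range(60):
            X = np.array([rng.uniform(-0.1, 0.1), rng.uniform(-0.1, 0.1), depth])
            obs = []
            for p in (p1, p2):
                px = INTR.project(p.transform(X))[0] + rng.normal(0, 1.0, 2)
                obs.append((p, px))
            try:
                Xh = triangulate(obs, INTR, min_angle_deg=0.1)
                errs.append(np.linalg.norm(Xh - X))
            except TriangulationError:
                pass
        med.append(np.median(errs))
    assert med[0] < med[1] < med[2]


# ---------------------------------------------------------------------------
# two-view pose


def _two_view_setup(n=120, second_center=(0.3, 0.1, 0.0), seed=0):
    rng = np.random.default_rng(seed)
    pts = rng.uniform([-0.5, -0.5, 1.5], [0.5, 0.5, 3.0], size=(n, 3))
    p1 = look_at_pose([0, 0, 0], [0, 0, 1], [0, 1, 0])
    p2 = look_at_pose(list(second_center), [0.25, 0.05, 1], [0, 1, 0])
    ka = [Keypoint(x=q[0], y=q[1], scale=1, orientation=0) for q in INTR.project(p1.transform(pts))]
    kb = [Keypoint(x=q[0], y=q[1], scale=1, orientation=0) for q in INTR.project(p2.transform(pts))]
    ms = MatchSet(0, 1, np.column_stack([np.arange(n)] * 2), np.zeros(n))
    rel = p2.compose(p1.inverse())
    return ms, ka, kb, rel


def test_two_view_pose_is_exact_on_noiseless_data():
    ms, ka, kb, rel = _two_view_setup()
    tv = estimate_two_view(ms, ka, kb, INTR, seed=1)
    assert not tv.degenerate
    assert rotation_angle_deg(tv.pose.R, rel.R) < 0.1
    assert angle_between_deg(tv.pose.t, rel.t) < 0.1


def test_zero_baseline_pair_is_flagged_degenerate():
    ms, ka, _, _ = _two_view_setup()
    tv = estimate_two_view(ms, ka, ka, INTR, seed=1)
    assert tv.degenerate
    assert tv.reason != ""


def test_two_view_is_deterministic_given_seed():
    ms, ka, kb, _ = _two_view_setup(seed=3)
    a = estimate_two_view(ms, ka, kb, INTR, seed=11)
    b = estimate_two_view(ms, ka, kb, INTR, seed=11)
    assert np.array_equal(a.pose.q, b.pose.q)
    assert np.array_equal(a.inliers, b.inliers)


# ---------------------------------------------------------------------------
# PnP registration


def _pnp_setup(n=60, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.uniform([-0.5, -0.5, 1.5], [0.5, 0.5, 3.0], size=(n, 3))
    pose = look_at_pose([0.2, -0.1, 0.1], [0.1, 0, 2], [0, 1, 0])
    px = INTR.project(pose.transform(X))
    return X, px, pose


def test_pnp_recovers_an_exact_pose():
    X, px, pose = _pnp_setup()
    est, mask, reason = register_frame(X, px, INTR, seed=1)
    assert reason == "" and mask.all()
    assert rotation_angle_deg(est.R, pose.R) < 0.01
    assert np.linalg.norm(est.t - pose.t) < 1e-6


def test_pnp_survives_thirty_percent_outliers():
    rng = np.random.default_rng(5)
    X, px, pose = _pnp_setup(seed=5)
    idx = rng.choice(len(X), int(0.3 * len(X)), replace=False)
    px = px.copy()
    px[idx] += rng.uniform(25, 60, size=(len(idx), 2))
    est, mask, reason = register_frame(X, px, INTR, seed=2)
    assert est is not None
    assert rotation_angle_deg(est.R, pose.R) < 0.05


def test_pnp_flags_collinear_points():
    t = np.linspace(0, 1, 20)
    X = np.outer(t, [0.1, 0.2, 0.3]) + [0, 0, 2]
    pose = look_at_pose([0.2, -0.1, 0.1], [0.1, 0, 2], [0, 1, 0])
    px = INTR.project(pose.transform(X))
    est, _, reason = register_frame(X, px, INTR, seed=1)
    assert est is None and "collinear" in reason


def test_pnp_reports_insufficient_correspondences():
    est, _, reason = register_frame(np.zeros((3, 3)), np.zeros((3, 2)), INTR)
    assert est is None and "4" in reason


# ---------------------------------------------------------------------------
# bundle adjustment


def _ba_model(n_cams=10, n_pts=200, seed=1):
    rng = np.random.default_rng(seed)
    poses = [
        look_at_pose(
            [0.6 * np.cos(a), 0.6 * np.sin(a), -2.0 + 0.05 * i], [0, 0, 0], [0, 1, 0]
        )
        for i, a in enumerate(np.linspace(0, 1.0, n_cams))
    ]
    pts = rng.uniform(-0.5, 0.5, size=(n_pts, 3))
    model = ReconstructionModel(intrinsics=INTR)
    kp = {i: [] for i in range(n_cams)}
    tracks = []
    for X in pts:
        obs = []
        for i, p in enumerate(poses):
            px = INTR.project(p.transform(X))[0]
            if 0 <= px[0] < 160 and 0 <= px[1] < 160:
                obs.append((i, len(kp[i])))
                kp[i].append(px)
        if len(obs) >= 2:
            tracks.append(Track(point=X.copy(), observations=obs))
    model.tracks = tracks
    model.keypoints = {i: np.array(kp[i]).reshape(-1, 2) for i in range(n_cams)}
    model.poses = {i: Pose(q=p.q.copy(), t=p.t.copy()) for i, p in enumerate(poses)}
    return model, poses


def test_ba_is_a_fixed_point_at_ground_truth():
    model, poses = _ba_model()
    out = bundle_adjust(model)
    assert out.mean_reprojection_error() < 1e-8
    for i, p in enumerate(poses):
        assert rotation_angle_deg(out.poses[i].R, p.R) < 1e-5


def test_ba_recovers_one_degree_pose_perturbations():
    model, poses = _ba_model()
    rng = np.random.default_rng(2)
    pert = copy.deepcopy(model)
    for i in range(1, 10):
        dR = Rotation.from_rotvec(rng.normal(size=3) * np.radians(1.0) / np.sqrt(3)).as_matrix()
        p = pert.poses[i]
        pert.poses[i] = Pose.from_Rt(dR @ p.R, p.t + rng.normal(size=3) * 0.01)
    out = bundle_adjust(pert)
    for i, p in enumerate(poses):
        assert rotation_angle_deg(out.poses[i].R, p.R) < 0.05


def test_ba_never_increases_the_reprojection_error():
    model, _ = _ba_model(seed=7)
    rng = np.random.default_rng(8)
    # contaminate some observations so the robust fit has real work to do
    for f in model.keypoints:
        n = len(model.keypoints[f])
        idx = rng.choice(n, max(1, n // 20), replace=False)
        model.keypoints[f][idx] += rng.normal(0, 6, size=(len(idx), 2))
    before = model.mean_reprojection_error()
    out = bundle_adjust(model)
    assert out.mean_reprojection_error() <= before + 1e-9


# ---------------------------------------------------------------------------
# statistics and small pipelines


def test_reconstruction_stats_counts_track_lengths():
    model = ReconstructionModel(intrinsics=INTR)
    model.poses = {0: Pose(), 1: Pose(), 2: Pose(), 3: Pose()}
    model.keypoints = {i: np.zeros((10, 2)) for i in range(4)}
    model.tracks = [
        Track(point=np.zeros(3), observations=[(0, 0), (1, 0)]),
        Track(point=np.zeros(3), observations=[(0, 1), (1, 1), (2, 0)]),
        Track(point=np.zeros(3), observations=[(0, 2), (1, 2), (2, 1), (3, 0)]),
    ]
    st = reconstruction_stats(model, 4)
    assert st.pct_registered == 100.0
    assert st.avg_observation == pytest.approx(3.0)
    st2 = reconstruction_stats(model, 8)
    assert st2.pct_registered == 50.0


def test_two_frame_minimal_input_yields_two_cameras(scene, vic_frames):
    model = run_incremental_sfm(vic_frames[9:11], scene.intrinsics, seed=0)
    assert len(model.poses) == 2
    tri = [t for t in model.tracks if t.point is not None]
    assert all(len(t.observations) == 2 for t in tri)


def test_quality_metrics_are_gauge_invariant(model):
    """Applying a similarity transform to the model leaves metrics unchanged."""
    import copy as _copy

    from gastro3d.sfm import reconstruction_stats as stats

    before = stats(model, 20)
    moved = _copy.deepcopy(model)
    s, R = 2.5, Rotation.from_rotvec([0.3, -0.2, 0.6]).as_matrix()
    t = np.array([0.5, -1.0, 2.0])
    for f, p in moved.poses.items():
        c_new = s * R @ p.center + t
        R_new = p.R @ R.T
        moved.poses[f] = Pose.from_Rt(R_new, -R_new @ c_new)
    for tr in moved.tracks:
        if tr.point is not None:
            tr.point = s * R @ tr.point + t
    after = stats(moved, 20)
    assert after.pct_registered == before.pct_registered
    assert after.avg_observation == before.avg_observation
    assert after.mean_reprojection_px == pytest.approx(
        before.mean_reprojection_px, abs=1e-6
    )


def test_cheirality_holds_for_every_retained_point(model):
    for tr in model.tracks:
        if tr.point is None:
            continue
        for f, _ in tr.observations:
            if f in model.poses:
                assert model.poses[f].transform(tr.point)[0, 2] > 0
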