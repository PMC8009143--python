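"""Shared fixtures: one default synthetic study, reconstructed once.

The heavy artifacts (rendered sequences, the structure-from-motion
model, meshes) are session-scoped so the whole suite pays for them a
single time.
"""

from __future__ import annotations

import numpy as np
import pytest

from gastro3d.endosim import (
    RidgeParams,
    SceneParams,
    _cast_rays,
    make_scene,
    render_frame,
    render_plane,
)
from gastro3d.geometry import umeyama_alignment
from gastro3d.sfm import ReconstructionModel, Track, densify_points, run_incremental_sfm
from gastro3d.surface import (
    estimate_normals,
    reconstruct_mesh,
    remove_outliers_plane_ransac,
)

SCENE_SEED = 0


@pytest.fixture(scope="session")
def scene():
    return make_scene(seed=SCENE_SEED)


@pytest.fixture(scope="session")
def vic_frames(scene):
    """Oracle virtual-dye red planes (the ideal translation output)."""
    return [
        render_plane(scene, i, "dye", "R")
        for i in range(scene.trajectory.n_frames)
    ]


@pytest.fixture(scope="session")
def nodye_frames(scene):
    """No-dye RGB frames with the channel-misalignment artifact."""
    return [
        render_frame(scene, i, "no_dye")
        for i in range(scene.trajectory.n_frames)
    ]


@pytest.fixture(scope="session")
def model(scene, vic_frames):
    return run_incremental_sfm(vic_frames, scene.intrinsics, seed=SCENE_SEED)


def gt_alignment(scene, model):
    """Similarity transform mapping the model gauge onto ground truth.

    Correspondences: each track's estimated point vs. the analytic
    surface point hit by the ray through its first observation from the
    ground-truth pose.
    """
    intr = scene.intrinsics
    est, gt = [], []
    for tr in model.tracks:
        if tr.point is None:
            continue
        f, k = tr.observations[0]
        px = model.keypoints[f][k]
        pose = scene.trajectory.poses[f]
        d_cam = np.array(
            [(px[0] - intr.cx) / intr.fx, (px[1] - intr.cy) / intr.fy, 1.0]
        )
        d_cam /= np.linalg.norm(d_cam)
        _, pt = _cast_rays(scene.surface, pose.center, (pose.R.T @ d_cam)[None])
        est.append(tr.point)
        gt.append(pt[0])
    return umeyama_alignment(np.array(est), np.array(gt)), np.array(est), np.array(gt)


@pytest.fixture(scope="session")
def alignment(scene, model):
    return gt_alignment(scene, model)


@pytest.fixture(scope="session")
def cleaned_cloud(model):
    dense = densify_points(model)
    cloud, removed, log = remove_outliers_plane_ransac(dense, seed=SCENE_SEED)
    return cloud


@pytest.fixture(scope="session")
def organ_mesh(model, cleaned_cloud):
    centers = np.array([model.poses[f].center for f in model.registered_frames])
    normals = estimate_normals(cleaned_cloud, k=16, interior_point=centers.mean(axis=0))
    return reconstruct_mesh(cleaned_cloud, normals, depth=7)


@pytest.fixture(scope="session")
def textured_mesh(scene, model, organ_mesh, nodye_frames):
    from gastro3d.surface import texture_mesh

    return texture_mesh(organ_mesh, nodye_frames, model.poses, scene.intrinsics)


# ---------------------------------------------------------------------------
# ridge study (rugae analogue) with ground-truth poses


@pytest.fixture(scope="session")
def ridge_scene():
    return make_scene(
        SceneParams(ridge=RidgeParams(phi0=0.5, theta_range=(0.9, 2.2))),
        seed=SCENE_SEED,
    )


@pytest.fixture(scope="session")
def ridge_frames(ridge_scene):
    return [
        render_frame(ridge_scene, i, "no_dye", misalignment=False)
        for i in range(ridge_scene.trajectory.n_frames)
    ]


@pytest.fixture(scope="session")
def ridge_model(ridge_scene):
    """Ground-truth-posed model with synthetic tracks from surface samples.

    Isolates the localization / refinement machinery from pose
    estimation error.
    """
    rng = np.random.default_rng(SCENE_SEED)
    sc = ridge_scene
    intr = sc.intrinsics
    model = ReconstructionModel(intrinsics=intr)
    model.poses = {i: sc.trajectory.poses[i] for i in range(20)}
    v = rng.normal(size=(400, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    pts = v * sc.surface.radius(v)[:, None]
    kps: dict[int, list] = {i: [] for i in range(20)}
    tracks = []
    for X in pts:
        obs = []
        for i in range(20):
            pose = model.poses[i]
            Xc = pose.transform(X)[0]
            if Xc[2] <= 0:
                continue
            px = intr.project(Xc[None])[0]
            if not (0 <= px[0] < intr.width and 0 <= px[1] < intr.height):
                continue
            d = X - pose.center
            dist = np.linalg.norm(d)
            t, _ = _cast_rays(sc.surface, pose.center, (d / dist)[None])
            if abs(t[0] - dist) > 0.01:
                continue
            obs.append((i, len(kps[i])))
            kps[i].append(px)
        if len(obs) >= 2:
            tracks.append(Track(point=X.copy(), observations=obs))
    model.tracks = tracks
    model.keypoints = {i: np.array(kps[i]).reshape(-1, 2) for i in range(20)}
    return model


def mesh_profile(mesh, dirs, win=0.02, band=0.15):
    """Median radial height of mesh vertices around each direction."""
    v = mesh.vertices
    vr = np.linalg.norm(v, axis=1)
    vd = v / vr[:, None]
    inband = np.abs(vr - np.median(vr)) < band
    h = np.full(len(dirs), np.nan)
    for i, d in enumerate(dirs):
        close = (vd @ d > np.cos(win)) & inband
        if close.sum() >= 3:
            h[i] = np.median(vr[close])
    return h
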