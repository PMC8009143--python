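"""Incremental structure-from-motion over single-channel frames.

The stages are the classical ones: two-view initialization from an
essential matrix, multi-view DLT triangulation with nonlinear
refinement, PnP camera registration inside RANSAC, and sparse bundle
adjustment with a Huber robust loss.  Reconstructions carry the usual
monocular gauge freedom; the gauge is fixed by anchoring the first
camera and scaling the initial baseline to unit length, and all
quality evaluation goes through a similarity (Umeyama) alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares
from scipy.sparse import lil_matrix
from scipy.spatial.transform import Rotation

from .features import (
    MatchSet,
    detect_and_describe,
    estimate_essential_ransac,
    geometric_verify,
    match_pair,
)
from .frames import ImageFrame
from .geometry import CameraIntrinsics, Pose, umeyama_alignment

__all__ = [
    "Track",
    "ReconstructionModel",
    "SfmConfig",
    "TwoViewResult",
    "TriangulationError",
    "estimate_two_view",
    "triangulate",
    "register_frame",
    "bundle_adjust",
    "run_incremental_sfm",
    "reconstruction_stats",
    "ReconstructionStats",
    "write_model",
]


class TriangulationError(ValueError):
    """Raised when a point cannot be triangulated reliably."""


@dataclass
class Track:
    """One 3D point with its (frame_id, keypoint_id) observations."""

    point: np.ndarray | None
    observations: list  # [(frame_id, keypoint_id), ...]
    color: np.ndarray | None = None

    def frames(self) -> list[int]:
        return [f for f, _ in self.observations]


@dataclass
class ReconstructionModel:
    """Central SfM state: intrinsics, registered poses, track graph."""

    intrinsics: CameraIntrinsics
    poses: dict = field(default_factory=dict)  # frame_id -> Pose
    tracks: list = field(default_factory=list)
    keypoints: dict = field(default_factory=dict)  # frame_id -> (n, 2) pixel array
    unregistered: set = field(default_factory=set)
    log: list = field(default_factory=list)

    @property
    def registered_frames(self) -> list[int]:
        return sorted(self.poses)

    def points(self) -> np.ndarray:
        pts = [t.point for t in self.tracks if t.point is not None]
        return np.array(pts) if pts else np.zeros((0, 3))

    def observation_arrays(self):
        """Flatten all observations of triangulated tracks into index arrays."""
        cams, pts, pix = [], [], []
        for ti, tr in enumerate(self.tracks):
            if tr.point is None:
                continue
            for fid, kid in tr.observations:
                if fid in self.poses:
                    cams.append(fid)
                    pts.append(ti)
                    pix.append(self.keypoints[fid][kid])
        return (
            np.array(cams, dtype=int),
            np.array(pts, dtype=int),
            np.asarray(pix, dtype=float).reshape(-1, 2),
        )

    def mean_reprojection_error(self) -> float:
        cams, pts, pix = self.observation_arrays()
        if len(cams) == 0:
            return float("nan")
        err = _reprojection_residuals(self, cams, pts, pix)
        return float(np.mean(np.linalg.norm(err.reshape(-1, 2), axis=1)))


def _reprojection_residuals(model, cams, pts, pix) -> np.ndarray:
    ids = sorted(model.poses)
    id_to_idx = {f: i for i, f in enumerate(ids)}
    Rm = np.stack([model.poses[f].R for f in ids])
    tm = np.stack([model.poses[f].t for f in ids])
    tid = np.array([id_to_idx[c] for c in cams])
    track_pts = np.zeros((len(model.tracks), 3))
    for i, tr in enumerate(model.tracks):
        if tr.point is not None:
            track_pts[i] = tr.point
    X = track_pts[pts]
    Xc = np.einsum("nij,nj->ni", Rm[tid], X) + tm[tid]
    proj = model.intrinsics.project(Xc)
    return (proj - pix).ravel()


# ---------------------------------------------------------------------------
# two-view initialization


@dataclass
class TwoViewResult:
    pose: Pose | None  # camera j in the frame of camera i; |t| = 1
    points: np.ndarray  # triangulated inlier points (camera-i frame)
    inliers: np.ndarray  # mask over the input matches
    degenerate: bool
    reason: str = ""


def _decompose_essential(E: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    U, _, Vt = np.linalg.svd(E)
    if np.linalg.det(U) < 0:
        U = -U
    if np.linalg.det(Vt) < 0:
        Vt = -Vt
    W = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
    R1, R2 = U @ W @ Vt, U @ W.T @ Vt
    t = U[:, 2]
    return [(R1, t), (R1, -t), (R2, t), (R2, -t)]


def _triangulate_linear_batch(P_list: list[np.ndarray], xn_list: list[np.ndarray]):
    """Batched DLT triangulation from >= 2 views of n points.

    ``P_list``: per-view 3x4 projection matrices (normalized coordinates);
    ``xn_list``: per-view (n, 2) normalized observations.
    """
    n = len(xn_list[0])
    rows = []
    for P, xn in zip(P_list, xn_list):
        rows.append(xn[:, 0, None] * P[2] - P[0])
        rows.append(xn[:, 1, None] * P[2] - P[1])
    A = np.stack(rows, axis=1)  # (n, 2*views, 4)
    _, _, Vt = np.linalg.svd(A)
    X = Vt[:, -1, :]
    w = X[:, 3]
    w = np.where(np.abs(w) < 1e-15, 1e-15, w)
    return X[:, :3] / w[:, None]


def estimate_two_view(
    matches: MatchSet,
    kps_i,
    kps_j,
    intrinsics: CameraIntrinsics,
    seed: int = 0,
    threshold_px: float = 1.0,
    min_cheirality_frac: float = 0.7,
    min_median_angle_deg: float = 0.5,
) -> TwoViewResult:
    """Relative pose of frame j w.r.t. frame i from verified matches.

    The essential matrix is estimated by RANSAC, decomposed into the four
    (R, t) candidates, and disambiguated by cheirality (both-view positive
    depth).  The translation is normalized to unit length because global
    scale is unobservable.  Near-zero baselines and rotation-dominant
    geometry are flagged degenerate so the caller can try another pair;
    because a short-baseline RANSAC draw can land on a rotation-dominant
    solution by chance, up to three restarts are tried first.
    """
    result = None
    for attempt in range(3):
        result = _estimate_two_view_once(
            matches, kps_i, kps_j, intrinsics, seed + 101 * attempt,
            threshold_px, min_cheirality_frac, min_median_angle_deg,
        )
        if not result.degenerate:
            return result
    return result


def _estimate_two_view_once(
    matches,
    kps_i,
    kps_j,
    intrinsics,
    seed,
    threshold_px,
    min_cheirality_frac,
    min_median_angle_deg,
) -> TwoViewResult:
    if len(matches) < 8:
        return TwoViewResult(None, np.zeros((0, 3)), np.zeros(len(matches), bool), True, "fewer than 8 matches")
    sel = matches.inliers if matches.inliers.any() else np.ones(len(matches), bool)
    pix_i = np.array([[kps_i[a].x, kps_i[a].y] for a in matches.pairs[sel, 0]])
    pix_j = np.array([[kps_j[b].x, kps_j[b].y] for b in matches.pairs[sel, 1]])
    xn1 = intrinsics.normalize(pix_i)
    xn2 = intrinsics.normalize(pix_j)
    # zero-baseline guard: the flow between identical poses is (near) zero
    flow = np.linalg.norm(pix_i - pix_j, axis=1)
    thr = threshold_px / ((intrinsics.fx + intrinsics.fy) / 2.0)
    E, mask = estimate_essential_ransac(xn1, xn2, thr, seed=seed)
    full_mask = np.zeros(len(matches), dtype=bool)
    if E is None or mask.sum() < 8:
        return TwoViewResult(None, np.zeros((0, 3)), full_mask, True, "essential estimation failed")
    P1 = np.hstack([np.eye(3), np.zeros((3, 1))])
    best = None
    for R, t in _decompose_essential(E):
        P2 = np.hstack([R, t[:, None]])
        X = _triangulate_linear_batch([P1, P2], [xn1[mask], xn2[mask]])
        z1 = X[:, 2]
        z2 = (X @ R.T + t)[:, 2]
        good = (z1 > 0) & (z2 > 0)
        if best is None or good.sum() > best[0]:
            best = (int(good.sum()), R, t, X, good)
    n_good, R, t, X, good = best
    if n_good < min_cheirality_frac * mask.sum():
        return TwoViewResult(None, np.zeros((0, 3)), full_mask, True, "cheirality ambiguous")
    # triangulation angles of the accepted points
    Xg = X[good]
    c2 = -R.T @ t
    r1 = Xg / np.linalg.norm(Xg, axis=1, keepdims=True)
    r2 = Xg - c2
    r2 /= np.linalg.norm(r2, axis=1, keepdims=True)
    ang = np.degrees(np.arccos(np.clip(np.sum(r1 * r2, axis=1), -1, 1)))
    if np.median(ang) < min_median_angle_deg or np.median(flow) < 0.5:
        return TwoViewResult(None, np.zeros((0, 3)), full_mask, True, "near-zero baseline (pure rotation)")
    sel_idx = np.nonzero(sel)[0]
    full_mask[sel_idx[mask]] = True
    return TwoViewResult(Pose.from_Rt(R, t), Xg, full_mask, False)


# ---------------------------------------------------------------------------
# triangulation


def _refine_point_gn(
    X0: np.ndarray, poses: list[Pose], pix: np.ndarray, intr: CameraIntrinsics, iters: int = 10
) -> np.ndarray:
    """Gauss-Newton refinement of one point's reprojection error."""
    X = X0.copy()
    for _ in range(iters):
        J = np.zeros((2 * len(poses), 3))
        r = np.zeros(2 * len(poses))
        for k, pose in enumerate(poses):
            R = pose.R
            Xc = R @ X + pose.t
            x, y, z = Xc
            if z <= 1e-12:
                return X
            proj = np.array([intr.fx * x / z + intr.cx, intr.fy * y / z + intr.cy])
            r[2 * k : 2 * k + 2] = proj - pix[k]
            d_proj = np.array(
                [
                    [intr.fx / z, 0.0, -intr.fx * x / z**2],
                    [0.0, intr.fy / z, -intr.fy * y / z**2],
                ]
            )
            J[2 * k : 2 * k + 2] = d_proj @ R
        try:
            dX = np.linalg.lstsq(J, -r, rcond=None)[0]
        except np.linalg.LinAlgError:
            return X
        X = X + dX
        if np.linalg.norm(dX) < 1e-14:
            break
    return X


def triangulate(
    observations: list,
    intrinsics: CameraIntrinsics,
    min_angle_deg: float = 1.0,
    refine: bool = True,
) -> np.ndarray:
    """Triangulate one world point from >= 2 (Pose, pixel) observations.

    Linear DLT estimate refined by Gauss-Newton on the reprojection
    error.  Raises :class:`TriangulationError` for near-zero baselines,
    negative depths, or a maximum triangulation angle below
    ``min_angle_deg``.
    """
    if len(observations) < 2:
        raise TriangulationError("need at least two observations")
    poses = [o[0] for o in observations]
    pix = np.array([o[1] for o in observations], dtype=float)
    centers = np.array([p.center for p in poses])
    base = max(
        np.linalg.norm(centers[i] - centers[j])
        for i in range(len(poses))
        for j in range(i + 1, len(poses))
    )
    if base < 1e-9:
        raise TriangulationError("near-zero baseline between all observing cameras")
    P_list = [np.hstack([p.R, p.t[:, None]]) for p in poses]
    xn = intrinsics.normalize(pix)
    X = _triangulate_linear_batch(P_list, [x[None, :] for x in xn])[0]
    if refine:
        X = _refine_point_gn(X, poses, pix, intrinsics)
    depths = np.array([p.transform(X)[0, 2] for p in poses])
    if np.any(depths <= 0):
        raise TriangulationError("negative depth in an observing camera")
    rays = X - centers
    rays /= np.linalg.norm(rays, axis=1, keepdims=True)
    max_ang = 0.0
    for i in range(len(poses)):
        for j in range(i + 1, len(poses)):
            a = np.degrees(np.arccos(np.clip(rays[i] @ rays[j], -1, 1)))
            max_ang = max(max_ang, a)
    if max_ang < min_angle_deg:
        raise TriangulationError(
            f"triangulation angle {max_ang:.3f} deg below {min_angle_deg} deg"
        )
    return X


# ---------------------------------------------------------------------------
# PnP registration


def _pnp_dlt(xn: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray] | None:
    """Direct linear transform pose from >= 6 normalized 2D-3D pairs."""
    n = len(X)
    A = np.zeros((2 * n, 12))
    Xh = np.column_stack([X, np.ones(n)])
    A[0::2, 0:4] = Xh
    A[0::2, 8:12] = -xn[:, 0, None] * Xh
    A[1::2, 4:8] = Xh
    A[1::2, 8:12] = -xn[:, 1, None] * Xh
    _, S, Vt = np.linalg.svd(A)
    if S[-2] < 1e-10 * S[0]:  # rank-deficient configuration (e.g. collinear points)
        return None
    P = Vt[-1].reshape(3, 4)
    # fix the projective sign so that det(M) > 0; the SVD then yields a
    # proper rotation and the cheirality of exact data comes out right
    M = P[:, :3]
    if np.linalg.det(M) < 0:
        P, M = -P, -M
    U, D, Vt2 = np.linalg.svd(M)
    if np.any(D < 1e-12 * D[0]):
        return None
    R = U @ Vt2
    t = P[:, 3] / D.mean()
    return R, t


def _pose_refine(
    pose: Pose,
    X: np.ndarray,
    pix: np.ndarray,
    intr: CameraIntrinsics,
    loss: str = "linear",
    f_scale: float = 1.0,
) -> Pose:
    def resid(p):
        R = Rotation.from_rotvec(p[:3]).as_matrix()
        Xc = X @ R.T + p[3:6]
        z = np.where(np.abs(Xc[:, 2]) < 1e-9, 1e-9, Xc[:, 2])
        u = intr.fx * Xc[:, 0] / z + intr.cx
        v = intr.fy * Xc[:, 1] / z + intr.cy
        return np.column_stack([u - pix[:, 0], v - pix[:, 1]]).ravel()

    p0 = np.concatenate([Rotation.from_matrix(pose.R).as_rotvec(), pose.t])
    if loss == "linear":
        sol = least_squares(resid, p0, method="lm", max_nfev=200)
    else:
        sol = least_squares(
            resid, p0, method="trf", loss=loss, f_scale=f_scale, max_nfev=200
        )
    return Pose.from_Rt(Rotation.from_rotvec(sol.x[:3]).as_matrix(), sol.x[3:6])


def _pose_inliers(
    pose: Pose, X: np.ndarray, pix: np.ndarray, intr: CameraIntrinsics, thr: float
) -> np.ndarray:
    Xc = pose.transform(X)
    ok = Xc[:, 2] > 0
    proj = np.full((len(X), 2), np.inf)
    if ok.any():
        proj[ok] = intr.project(Xc[ok])
    return ok & (np.linalg.norm(proj - pix, axis=1) < thr)


def register_frame(
    points3d: np.ndarray,
    pixels: np.ndarray,
    intrinsics: CameraIntrinsics,
    seed: int = 0,
    threshold_px: float = 4.0,
    min_inliers: int = 15,
    max_iters: int = 500,
    initial_pose: Pose | None = None,
) -> tuple[Pose | None, np.ndarray, str]:
    """PnP-within-RANSAC pose for a new frame from 2D-3D correspondences.

    Two candidate estimators run: a 6-point DLT inside RANSAC, and —
    when ``initial_pose`` is supplied (e.g. the nearest registered
    neighbour in a video sequence) — a robust warm-start refinement,
    which handles the near-planar point configurations where DLT is
    ill-conditioned.  The candidate with more inliers wins.
    Returns ``(pose, inlier_mask, reason)``; pose is ``None`` when the
    inlier support falls below ``min_inliers`` or the geometry is
    degenerate (e.g. all points collinear).
    """
    points3d = np.asarray(points3d, float)
    pixels = np.asarray(pixels, float)
    n = len(points3d)
    if n < 4:
        return None, np.zeros(n, bool), "fewer than 4 correspondences"
    # collinearity check on the 3D points
    sv = np.linalg.svd(points3d - points3d.mean(axis=0), compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1e-300):
        return None, np.zeros(n, bool), "degenerate: 3D points collinear"
    if n < 6 and initial_pose is None:
        return None, np.zeros(n, bool), "fewer than 6 correspondences for DLT"
    candidates: list[Pose] = []
    if n >= 6:
        xn = intrinsics.normalize(pixels)
        rng = np.random.default_rng(seed)
        best_mask, best_count = np.zeros(n, bool), 0
        it, needed = 0, max_iters
        while it < min(needed, max_iters):
            sample = rng.choice(n, size=6, replace=False)
            res = _pnp_dlt(xn[sample], points3d[sample])
            it += 1
            if res is None:
                continue
            mask = _pose_inliers(Pose.from_Rt(*res), points3d, pixels, intrinsics, threshold_px)
            if mask.sum() > best_count:
                best_count, best_mask = int(mask.sum()), mask
                ratio = best_count / n
                denom = np.log(max(1.0 - ratio**6, 1e-12))
                if denom < -1e-12:
                    needed = int(np.ceil(np.log(1e-3) / denom)) + 1
        if best_count >= 6:
            res = _pnp_dlt(xn[best_mask], points3d[best_mask])
            if res is not None:
                candidates.append(Pose.from_Rt(*res))
    if initial_pose is not None:
        candidates.append(
            _pose_refine(
                initial_pose, points3d, pixels, intrinsics,
                loss="soft_l1", f_scale=threshold_px,
            )
        )
    best: tuple[Pose, np.ndarray] | None = None
    for pose in candidates:
        mask = _pose_inliers(pose, points3d, pixels, intrinsics, threshold_px)
        for _ in range(2):  # refine on inliers, recount
            if mask.sum() < max(min_inliers, 6):
                break
            pose = _pose_refine(pose, points3d[mask], pixels[mask], intrinsics)
            mask = _pose_inliers(pose, points3d, pixels, intrinsics, threshold_px)
        if best is None or mask.sum() > best[1].sum():
            best = (pose, mask)
    if best is None:
        return None, np.zeros(n, bool), "no pose candidate"
    pose, mask = best
    if mask.sum() < max(min_inliers, 6):
        return None, mask, f"insufficient inliers ({int(mask.sum())} < {min_inliers})"
    return pose, mask, ""


# ---------------------------------------------------------------------------
# bundle adjustment


def _rotvec_point_jacobian(rv: np.ndarray, R: np.ndarray, X: np.ndarray) -> np.ndarray:
    """d(R(v) X)/dv for one rotation vector and a batch of points.

    Closed form (Gallego & Yezzi): for u = X,
    d(R u)/dv = -R [u]x (v v^T + (R^T - I)[v]x) / |v|^2, with the v -> 0
    limit -[u]x... evaluated as -R [u]x at the origin.
    Returns (n, 3, 3).
    """
    n = len(X)
    ux = np.zeros((n, 3, 3))
    ux[:, 0, 1] = -X[:, 2]
    ux[:, 0, 2] = X[:, 1]
    ux[:, 1, 0] = X[:, 2]
    ux[:, 1, 2] = -X[:, 0]
    ux[:, 2, 0] = -X[:, 1]
    ux[:, 2, 1] = X[:, 0]
    nv2 = float(rv @ rv)
    if nv2 < 1e-16:
        return -np.einsum("ij,njk->nik", R, ux)
    vx = np.array(
        [
            [0.0, -rv[2], rv[1]],
            [rv[2], 0.0, -rv[0]],
            [-rv[1], rv[0], 0.0],
        ]
    )
    M = (np.outer(rv, rv) + (R.T - np.eye(3)) @ vx) / nv2
    return -np.einsum("ij,njk,kl->nil", R, ux, M)


def bundle_adjust(
    model: ReconstructionModel,
    huber_px: float = 2.0,
    max_nfev: int | None = 60,
    ftol: float = 1e-10,
) -> ReconstructionModel:
    """Joint nonlinear refinement of all poses and points.

    Minimizes Huber-robustified reprojection residuals with
    ``scipy.optimize.least_squares`` using an analytic sparse Jacobian.
    The gauge is fixed by anchoring the first registered camera; the
    scale is restored afterwards so the first baseline keeps its length.
    The refined model is only accepted when the mean reprojection error
    did not increase; otherwise the input model is returned unchanged
    with a log entry.
    """
    ids = sorted(model.poses)
    if len(ids) < 2:
        return model
    cams, pts, pix = model.observation_arrays()
    if len(cams) == 0:
        return model
    track_ids = sorted(set(pts))
    tmap = {t: k for k, t in enumerate(track_ids)}
    cmap = {f: k for k, f in enumerate(ids)}
    cam_idx = np.array([cmap[c] for c in cams])
    pt_idx = np.array([tmap[p] for p in pts])

    n_cam, n_pt = len(ids), len(track_ids)
    cam0 = model.poses[ids[0]]
    rvec0 = np.concatenate(
        [
            np.concatenate(
                [Rotation.from_matrix(model.poses[f].R).as_rotvec(), model.poses[f].t]
            )
            for f in ids[1:]
        ]
    ) if n_cam > 1 else np.zeros(0)
    pts0 = np.concatenate([model.tracks[t].point for t in track_ids])
    x0 = np.concatenate([rvec0, pts0])
    intr = model.intrinsics
    baseline_before = np.linalg.norm(model.poses[ids[1]].center - cam0.center)
    err_before = model.mean_reprojection_error()

    R0, t0 = cam0.R, cam0.t

    def unpack(x):
        cam_p = x[: 6 * (n_cam - 1)].reshape(-1, 6)
        Rm = np.empty((n_cam, 3, 3))
        tm = np.empty((n_cam, 3))
        Rm[0], tm[0] = R0, t0
        if n_cam > 1:
            Rm[1:] = Rotation.from_rotvec(cam_p[:, :3]).as_matrix()
            tm[1:] = cam_p[:, 3:]
        X = x[6 * (n_cam - 1) :].reshape(-1, 3)
        return Rm, tm, X

    def resid(x):
        Rm, tm, X = unpack(x)
        Xc = np.einsum("nij,nj->ni", Rm[cam_idx], X[pt_idx]) + tm[cam_idx]
        z = np.where(np.abs(Xc[:, 2]) < 1e-9, 1e-9, Xc[:, 2])
        u = intr.fx * Xc[:, 0] / z + intr.cx
        v = intr.fy * Xc[:, 1] / z + intr.cy
        return np.column_stack([u - pix[:, 0], v - pix[:, 1]]).ravel()

    n_obs = len(cams)

    def jac(x):
        Rm, tm, X = unpack(x)
        Xw = X[pt_idx]
        Xc = np.einsum("nij,nj->ni", Rm[cam_idx], Xw) + tm[cam_idx]
        z = np.where(np.abs(Xc[:, 2]) < 1e-9, 1e-9, Xc[:, 2])
        dproj = np.zeros((n_obs, 2, 3))
        dproj[:, 0, 0] = intr.fx / z
        dproj[:, 0, 2] = -intr.fx * Xc[:, 0] / z**2
        dproj[:, 1, 1] = intr.fy / z
        dproj[:, 1, 2] = -intr.fy * Xc[:, 1] / z**2
        # point block: dproj * R
        Jpt = np.einsum("nij,njk->nik", dproj, Rm[cam_idx])  # (n_obs, 2, 3)
        rows_list, cols_list, data_list = [], [], []
        r2 = np.repeat(2 * np.arange(n_obs), 2)  # rows per obs, u then v
        obs_rows = np.stack(
            [2 * np.arange(n_obs), 2 * np.arange(n_obs) + 1], axis=1
        )  # (n_obs, 2)
        pt_cols = 6 * (n_cam - 1) + 3 * pt_idx  # base column of each obs's point
        rr = np.broadcast_to(obs_rows[:, :, None], (n_obs, 2, 3))
        cc = np.broadcast_to(pt_cols[:, None, None] + np.arange(3), (n_obs, 2, 3))
        rows_list.append(rr.ravel())
        cols_list.append(cc.ravel())
        data_list.append(Jpt.ravel())
        # camera blocks, per camera (anchor camera excluded)
        cam_p = x[: 6 * (n_cam - 1)].reshape(-1, 6)
        for k in range(1, n_cam):
            sel = np.nonzero(cam_idx == k)[0]
            if len(sel) == 0:
                continue
            rv = cam_p[k - 1, :3]
            dRv = _rotvec_point_jacobian(rv, Rm[k], Xw[sel])  # (m, 3, 3)
            Jrot = np.einsum("nij,njk->nik", dproj[sel], dRv)
            Jt = dproj[sel]
            base = 6 * (k - 1)
            rr = np.broadcast_to(obs_rows[sel][:, :, None], (len(sel), 2, 3))
            cc_r = np.broadcast_to(
                base + np.arange(3), (len(sel), 2, 3)
            )
            cc_t = np.broadcast_to(
                base + 3 + np.arange(3), (len(sel), 2, 3)
            )
            rows_list += [rr.ravel(), rr.ravel()]
            cols_list += [cc_r.ravel(), cc_t.ravel()]
            data_list += [Jrot.ravel(), Jt.ravel()]
        from scipy.sparse import coo_matrix

        J = coo_matrix(
            (
                np.concatenate(data_list),
                (np.concatenate(rows_list), np.concatenate(cols_list)),
            ),
            shape=(2 * n_obs, len(x)),
        )
        return J.tocsr()

    sol = least_squares(
        resid,
        x0,
        jac=jac,
        loss="huber",
        f_scale=huber_px,
        method="trf",
        tr_solver="lsmr",
        ftol=ftol,
        max_nfev=max_nfev,
    )
    Rm, tm, X = unpack(sol.x)
    new = ReconstructionModel(
        intrinsics=model.intrinsics,
        poses=dict(model.poses),
        tracks=[replace(t) for t in model.tracks],
        keypoints=model.keypoints,
        unregistered=set(model.unregistered),
        log=model.log,
    )
    for k, f in enumerate(ids):
        new.poses[f] = Pose.from_Rt(Rm[k], tm[k])
    for t, k in tmap.items():
        new.tracks[t] = replace(model.tracks[t], point=X[k].copy())
    # restore the gauge scale (anchor camera is fixed; rescale about it)
    baseline_after = np.linalg.norm(new.poses[ids[1]].center - new.poses[ids[0]].center)
    if baseline_after > 1e-12:
        s = baseline_before / baseline_after
        c0 = new.poses[ids[0]].center
        for f in ids:
            p = new.poses[f]
            c_new = c0 + s * (p.center - c0)
            new.poses[f] = Pose.from_Rt(p.R, -p.R @ c_new)
        for tr in new.tracks:
            if tr.point is not None:
                tr.point = c0 + s * (tr.point - c0)
    err_after = new.mean_reprojection_error()
    if np.isfinite(err_after) and err_after <= err_before + 1e-12:
        new.log.append(f"BA: mean reprojection {err_before:.4f} -> {err_after:.4f} px")
        return new
    model.log.append(
        f"BA rejected: error would increase {err_before:.4f} -> {err_after:.4f} px"
    )
    return model


# ---------------------------------------------------------------------------
# incremental pipeline


@dataclass(frozen=True)
class SfmConfig:
    ratio: float = 0.8
    verify_threshold_px: float = 1.0
    min_pair_inliers: int = 15
    init_min_inliers: int = 30
    pnp_threshold_px: float = 4.0
    min_pnp_inliers: int = 15
    min_triangulation_angle_deg: float = 1.5
    max_reprojection_px: float = 2.5
    ba_every: int = 2
    huber_px: float = 2.0
    sequential_window: int | None = None  # None = exhaustive all-pairs matching
    # final-model hygiene: points kept only when observed with enough
    # parallax and residual; applied after all registrations so it cannot
    # starve the incremental growth
    final_min_triangulation_angle_deg: float = 10.0
    final_max_reprojection_px: float = 1.5
    final_min_track_len: int = 3
    # temporal smoothness gate: an endoscope moves continuously, so a new
    # frame's pose may not jump arbitrarily relative to its nearest
    # registered temporal neighbour (guards against the planar-PnP
    # mirror ambiguity)
    max_neighbor_rotation_deg_per_frame: float = 12.0
    max_neighbor_center_step_factor: float = 8.0


class _UnionFind:
    def __init__(self):
        self.parent = {}

    def find(self, a):
        p = self.parent.setdefault(a, a)
        while p != self.parent[p]:
            self.parent[p] = self.parent[self.parent[p]]
            p = self.parent[p]
        self.parent[a] = p
        return p

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _build_tracks(matchsets: list[MatchSet]) -> list[Track]:
    uf = _UnionFind()
    for ms in matchsets:
        for a, b in ms.inlier_pairs():
            uf.union((ms.frame_i, int(a)), (ms.frame_j, int(b)))
    groups: dict = {}
    for node in list(uf.parent):
        groups.setdefault(uf.find(node), []).append(node)
    tracks = []
    for obs in groups.values():
        if len(obs) < 2:
            continue
        frames = [f for f, _ in obs]
        if len(set(frames)) != len(frames):
            continue  # conflicting track: two keypoints of one frame merged
        tracks.append(Track(point=None, observations=sorted(obs)))
    return tracks


def _triangulate_tracks(
    model: ReconstructionModel, config: SfmConfig, candidates: list | None = None
) -> int:
    """(Re)triangulate untriangulated tracks with >= 2 registered views.

    Vectorized: tracks are grouped by their number of registered views and
    solved with batched DLT followed by batched Gauss-Newton refinement.
    ``candidates`` restricts the work to track indices whose registered
    support may have changed.
    """
    intr = model.intrinsics
    idx_iter = range(len(model.tracks)) if candidates is None else candidates
    groups: dict[int, list] = {}
    for ti in idx_iter:
        tr = model.tracks[ti]
        if tr.point is not None:
            continue
        obs = [(f, k) for f, k in tr.observations if f in model.poses]
        if len(obs) >= 2:
            groups.setdefault(len(obs), []).append((ti, obs))
    n_new = 0
    for n_v, items in groups.items():
        m = len(items)
        P = np.empty((m, n_v, 3, 4))
        pix = np.empty((m, n_v, 2))
        centers = np.empty((m, n_v, 3))
        for a, (_, obs) in enumerate(items):
            for b, (f, k) in enumerate(obs):
                pose = model.poses[f]
                P[a, b, :, :3] = pose.R
                P[a, b, :, 3] = pose.t
                pix[a, b] = model.keypoints[f][k]
                centers[a, b] = pose.center
        xn = intr.normalize(pix.reshape(-1, 2)).reshape(m, n_v, 2)
        A = np.concatenate(
            [
                xn[:, :, 0:1] * P[:, :, 2, :] - P[:, :, 0, :],
                xn[:, :, 1:2] * P[:, :, 2, :] - P[:, :, 1, :],
            ],
            axis=1,
        )
        _, _, Vt = np.linalg.svd(A)
        Xh = Vt[:, -1, :]
        w = np.where(np.abs(Xh[:, 3]) < 1e-15, 1e-15, Xh[:, 3])
        X = Xh[:, :3] / w[:, None]
        # batched Gauss-Newton on the pixel reprojection error
        F = np.diag([intr.fx, intr.fy])
        for _ in range(5):
            Xc = np.einsum("mvij,mj->mvi", P[:, :, :, :3], X) + P[:, :, :, 3]
            z = np.where(np.abs(Xc[:, :, 2]) < 1e-12, 1e-12, Xc[:, :, 2])
            proj = np.stack(
                [
                    intr.fx * Xc[:, :, 0] / z + intr.cx,
                    intr.fy * Xc[:, :, 1] / z + intr.cy,
                ],
                axis=-1,
            )
            r = (proj - pix).reshape(m, -1)  # (m, 2*n_v)
            dpdX = np.empty((m, n_v, 2, 3))
            dpdX[:, :, 0, 0] = intr.fx / z
            dpdX[:, :, 0, 1] = 0.0
            dpdX[:, :, 0, 2] = -intr.fx * Xc[:, :, 0] / z**2
            dpdX[:, :, 1, 0] = 0.0
            dpdX[:, :, 1, 1] = intr.fy / z
            dpdX[:, :, 1, 2] = -intr.fy * Xc[:, :, 1] / z**2
            J = np.einsum("mvij,mvjk->mvik", dpdX, P[:, :, :, :3]).reshape(m, -1, 3)
            JtJ = np.einsum("mri,mrj->mij", J, J) + 1e-12 * np.eye(3)
            Jtr = np.einsum("mri,mr->mi", J, r)
            try:
                dX = np.linalg.solve(JtJ, -Jtr[:, :, None])[:, :, 0]
            except np.linalg.LinAlgError:
                break
            X = X + dX
        # acceptance checks: cheirality, reprojection error, triangulation angle
        Xc = np.einsum("mvij,mj->mvi", P[:, :, :, :3], X) + P[:, :, :, 3]
        ok = np.all(Xc[:, :, 2] > 0, axis=1)
        z = np.where(np.abs(Xc[:, :, 2]) < 1e-12, 1e-12, Xc[:, :, 2])
        proj = np.stack(
            [
                intr.fx * Xc[:, :, 0] / z + intr.cx,
                intr.fy * Xc[:, :, 1] / z + intr.cy,
            ],
            axis=-1,
        )
        err = np.linalg.norm(proj - pix, axis=-1).max(axis=1)
        ok &= err <= config.max_reprojection_px
        rays = X[:, None, :] - centers
        rays /= np.maximum(np.linalg.norm(rays, axis=-1, keepdims=True), 1e-15)
        max_ang = np.zeros(m)
        for i in range(n_v):
            for j in range(i + 1, n_v):
                cosang = np.clip(np.sum(rays[:, i] * rays[:, j], axis=-1), -1, 1)
                max_ang = np.maximum(max_ang, np.degrees(np.arccos(cosang)))
        ok &= max_ang >= config.min_triangulation_angle_deg
        for a, (ti, _) in enumerate(items):
            if ok[a]:
                model.tracks[ti].point = X[a].copy()
                n_new += 1
    return n_new


def _filter_observations(model: ReconstructionModel, config: SfmConfig) -> int:
    """Drop observations (and points) violating reprojection or cheirality."""
    n_drop = 0
    for tr in model.tracks:
        if tr.point is None:
            continue
        keep = []
        for f, k in tr.observations:
            if f not in model.poses:
                keep.append((f, k))
                continue
            Xc = model.poses[f].transform(tr.point)[0]
            if Xc[2] <= 0:
                n_drop += 1
                continue
            err = np.linalg.norm(
                model.intrinsics.project(Xc[None]) - model.keypoints[f][k]
            )
            if err > config.max_reprojection_px:
                n_drop += 1
                continue
            keep.append((f, k))
        tr.observations = keep
        if sum(1 for f, _ in keep if f in model.poses) < 2:
            tr.point = None
    return n_drop


def _final_point_filter(model: ReconstructionModel, config: SfmConfig) -> int:
    """Drop triangulated points with weak parallax or large residuals."""
    intr = model.intrinsics
    n_drop = 0
    for tr in model.tracks:
        if tr.point is None:
            continue
        obs = [(f, k) for f, k in tr.observations if f in model.poses]
        centers = np.array([model.poses[f].center for f, _ in obs])
        rays = tr.point[None, :] - centers
        rays /= np.maximum(np.linalg.norm(rays, axis=1, keepdims=True), 1e-15)
        cosang = np.clip(rays @ rays.T, -1, 1)
        max_ang = float(np.degrees(np.arccos(cosang.min())))
        errs = [
            np.linalg.norm(
                intr.project(model.poses[f].transform(tr.point))
                - model.keypoints[f][k]
            )
            for f, k in obs
        ]
        if (
            max_ang < config.final_min_triangulation_angle_deg
            or len(obs) < config.final_min_track_len
            or max(errs) > config.final_max_reprojection_px
        ):
            tr.point = None
            n_drop += 1
    return n_drop


def densify_points(
    model: ReconstructionModel,
    min_angle_deg: float = 8.0,
    max_reprojection_px: float = 1.5,
    min_track_len: int = 3,
) -> np.ndarray:
    """Re-triangulate every track at looser thresholds, for meshing.

    The model's own point set is filtered strictly for metric quality;
    surface reconstruction benefits from more (slightly noisier)
    support.  Tracks must span ``min_track_len`` registered views, so a
    single marginal camera cannot contribute unchecked geometry.  The
    model is not modified.
    """
    keep = [
        t
        for t in model.tracks
        if sum(1 for f, _ in t.observations if f in model.poses) >= min_track_len
    ]
    work = ReconstructionModel(
        intrinsics=model.intrinsics,
        poses=model.poses,
        tracks=[Track(point=None, observations=t.observations) for t in keep],
        keypoints=model.keypoints,
    )
    cfg = SfmConfig(
        min_triangulation_angle_deg=min_angle_deg,
        max_reprojection_px=max_reprojection_px,
    )
    _triangulate_tracks(work, cfg)
    return work.points()


def _pose_audit(model: ReconstructionModel, config: SfmConfig, seed: int) -> int:
    """Re-register or drop cameras that fit the final points poorly.

    After filtering, every camera should agree with the surviving
    high-quality points.  A camera stuck in a bad local minimum is
    re-registered against them (warm-started from its neighbour); if no
    acceptable pose exists it is honestly reported as unregistered
    rather than silently shipping a wrong pose.
    """
    intr = model.intrinsics
    n_changed = 0
    for fid in list(model.registered_frames):
        X, px = [], []
        for tr in model.tracks:
            if tr.point is None:
                continue
            for f, k in tr.observations:
                if f == fid:
                    X.append(tr.point)
                    px.append(model.keypoints[fid][k])
        X, px = np.array(X), np.array(px).reshape(-1, 2)
        if len(X) < 6:
            continue  # too little evidence to judge this camera
        mask = _pose_inliers(model.poses[fid], X, px, intr, config.pnp_threshold_px)
        if mask.sum() >= max(6, 0.7 * len(X)):
            continue
        others = [f for f in model.poses if f != fid]
        nearest = min(others, key=lambda f: abs(f - fid)) if others else None
        pose, new_mask, _ = register_frame(
            X, px, intr,
            seed=seed + 97 * fid,
            threshold_px=config.pnp_threshold_px,
            min_inliers=config.min_pnp_inliers,
            initial_pose=model.poses[nearest] if nearest is not None else None,
        )
        if pose is not None and new_mask.sum() > mask.sum():
            model.poses[fid] = pose
            model.log.append(
                f"pose audit: re-registered frame {fid} "
                f"({int(mask.sum())} -> {int(new_mask.sum())} inliers)"
            )
        else:
            del model.poses[fid]
            model.unregistered.add(fid)
            model.log.append(
                f"pose audit: dropped frame {fid} ({int(mask.sum())}/{len(X)} inliers)"
            )
        n_changed += 1
    return n_changed


def _smoothness_audit(model: ReconstructionModel, config: SfmConfig) -> int:
    """Drop cameras that kink the trajectory beyond the smoothness prior.

    An endoscope moves continuously; after the final adjustment the
    relative rotation between temporally adjacent registered cameras
    must stay below the per-frame bound.  When a pair violates it, the
    camera with less final-point support is reported unregistered.
    """
    from .geometry import rotation_angle_deg as _rad

    n_drop = 0
    while True:
        ids = model.registered_frames
        if len(ids) < 3:
            break
        support = {f: 0 for f in ids}
        for tr in model.tracks:
            if tr.point is None:
                continue
            for f, _ in tr.observations:
                if f in support:
                    support[f] += 1
        worst, worst_rate = None, 0.0
        for a, b in zip(ids[:-1], ids[1:]):
            rate = _rad(model.poses[a].R, model.poses[b].R) / max(1, b - a)
            if rate > worst_rate:
                worst_rate, worst = rate, (a, b)
        if worst is None or worst_rate <= config.max_neighbor_rotation_deg_per_frame:
            break
        a, b = worst
        drop = a if support[a] <= support[b] else b
        del model.poses[drop]
        model.unregistered.add(drop)
        model.log.append(
            f"smoothness audit: dropped frame {drop} "
            f"(kink {worst_rate:.1f} deg/frame between {a} and {b})"
        )
        n_drop += 1
    return n_drop


def run_incremental_sfm(
    vic_frames: list,
    intrinsics: CameraIntrinsics,
    config: SfmConfig | None = None,
    seed: int = 0,
) -> ReconstructionModel:
    """Reconstruct cameras and sparse points from an ordered frame sequence.

    ``vic_frames`` are single-plane images (arrays or
    :class:`~gastro3d.frames.ImageFrame`).  Features are detected and
    exhaustively matched, matches verified against an essential matrix,
    tracks built, and the model grown incrementally from the best-scoring
    initial pair with periodic bundle adjustment.
    """
    config = config or SfmConfig()
    planes = [
        f.pixels if isinstance(f, ImageFrame) else np.asarray(f, float)
        for f in vic_frames
    ]
    if len(planes) < 2:
        raise ValueError("need at least two frames")
    model = ReconstructionModel(intrinsics=intrinsics)
    model.unregistered = set(range(len(planes)))

    feats = [detect_and_describe(p) for p in planes]
    for i, (kps, _) in enumerate(feats):
        model.keypoints[i] = np.array([[kp.x, kp.y] for kp in kps]).reshape(-1, 2)
    model.log.append(
        "features: " + ", ".join(str(len(k)) for k, _ in feats)
    )

    pairs = []
    for i in range(len(planes)):
        for j in range(i + 1, len(planes)):
            if config.sequential_window and j - i > config.sequential_window:
                continue
            pairs.append((i, j))
    matchsets = []
    for i, j in pairs:
        ms = match_pair(feats[i][1], feats[j][1], ratio=config.ratio, frame_i=i, frame_j=j)
        if len(ms) < 8:
            continue
        ms = geometric_verify(
            ms, feats[i][0], feats[j][0], intrinsics,
            threshold_px=config.verify_threshold_px, seed=seed + 1000 * i + j,
        )
        if ms.n_inliers >= config.min_pair_inliers:
            matchsets.append(ms)
    model.tracks = _build_tracks(matchsets)
    model.log.append(f"pairs kept: {len(matchsets)}; tracks: {len(model.tracks)}")
    if not matchsets:
        model.log.append("no valid pairs; empty model")
        return model

    # --- initial pair: maximize inliers x median triangulation angle
    best_init, best_score = None, -1.0
    candidates = sorted(matchsets, key=lambda m: -m.n_inliers)[:30]
    for ms in candidates:
        if ms.n_inliers < config.init_min_inliers:
            continue
        tv = estimate_two_view(
            ms, feats[ms.frame_i][0], feats[ms.frame_j][0], intrinsics,
            seed=seed + 7 * ms.frame_i + ms.frame_j,
        )
        if tv.degenerate:
            continue
        Xg = tv.points
        c2 = tv.pose.center
        r1 = Xg / np.linalg.norm(Xg, axis=1, keepdims=True)
        r2 = (Xg - c2) / np.linalg.norm(Xg - c2, axis=1, keepdims=True)
        med_ang = float(np.median(np.degrees(np.arccos(np.clip(np.sum(r1 * r2, axis=1), -1, 1)))))
        score = ms.n_inliers * med_ang
        if score > best_score:
            best_score, best_init = score, (ms, tv)
    if best_init is None:
        model.log.append("no valid initial pair; empty model")
        return model
    ms, tv = best_init
    i0, j0 = ms.frame_i, ms.frame_j
    model.poses[i0] = Pose()
    model.poses[j0] = tv.pose  # |t| = 1 fixes the gauge scale
    model.unregistered -= {i0, j0}
    model.log.append(f"initial pair ({i0}, {j0}): {ms.n_inliers} inliers, score {best_score:.1f}")
    _triangulate_tracks(model, config)

    # tracks indexed by observing frame, for targeted re-triangulation
    frame_tracks: dict[int, list] = {}
    for ti, tr in enumerate(model.tracks):
        for f, _ in tr.observations:
            frame_tracks.setdefault(f, []).append(ti)

    # --- incremental registration; failed frames are retried after the
    # model has grown (their support improves), up to 3 attempts each
    attempts: dict[int, int] = {}
    since_ba = 0
    while True:
        counts = {}
        for tr in model.tracks:
            if tr.point is None:
                continue
            for f, k in tr.observations:
                if f in model.unregistered and attempts.get(f, 0) < 3:
                    counts[f] = counts.get(f, 0) + 1
        counts = {f: c for f, c in counts.items() if c >= max(6, config.min_pnp_inliers)}
        if not counts:
            break
        fid = max(counts, key=lambda f: counts[f])
        X, px = [], []
        for ti, tr in enumerate(model.tracks):
            if tr.point is None:
                continue
            for f, k in tr.observations:
                if f == fid:
                    X.append(tr.point)
                    px.append(model.keypoints[fid][k])
        nearest = min(model.poses, key=lambda f: abs(f - fid))
        pose, mask, reason = register_frame(
            np.array(X), np.array(px), intrinsics,
            seed=seed + 13 * fid + 1009 * attempts.get(fid, 0),
            threshold_px=config.pnp_threshold_px,
            min_inliers=config.min_pnp_inliers,
            initial_pose=model.poses[nearest],
        )
        if pose is None:
            attempts[fid] = attempts.get(fid, 0) + 1
            model.log.append(f"frame {fid} not registered: {reason}")
            continue
        # temporal smoothness gate against the nearest registered neighbour
        from .geometry import rotation_angle_deg as _rad

        gap = max(1, abs(fid - nearest))
        ang = _rad(pose.R, model.poses[nearest].R)
        reg_ids = model.registered_frames
        steps = [
            np.linalg.norm(model.poses[a].center - model.poses[b].center)
            / max(1, abs(a - b))
            for a, b in zip(reg_ids[:-1], reg_ids[1:])
        ]
        med_step = float(np.median(steps)) if steps else np.inf
        jump = np.linalg.norm(pose.center - model.poses[nearest].center)
        if ang > config.max_neighbor_rotation_deg_per_frame * gap or (
            np.isfinite(med_step)
            and jump > config.max_neighbor_center_step_factor * med_step * gap
        ):
            attempts[fid] = attempts.get(fid, 0) + 1
            model.log.append(
                f"frame {fid} rejected by smoothness gate "
                f"(rot {ang:.1f} deg, jump {jump:.3f} vs step {med_step:.3f})"
            )
            continue
        model.poses[fid] = pose
        model.unregistered.discard(fid)
        model.log.append(f"registered frame {fid} ({int(mask.sum())}/{len(mask)} PnP inliers)")
        _triangulate_tracks(model, config, candidates=frame_tracks.get(fid, []))
        since_ba += 1
        if since_ba >= config.ba_every:
            model = bundle_adjust(model, huber_px=config.huber_px)
            _filter_observations(model, config)
            _triangulate_tracks(model, config)
            since_ba = 0
            attempts = {}  # the refined model may rescue frames that failed
    model = bundle_adjust(model, huber_px=config.huber_px)
    _filter_observations(model, config)
    # strict final pass: drop low-parallax / high-residual points, re-adjust
    for _ in range(1):
        n_dropped = _final_point_filter(model, config)
        model.log.append(f"final filter dropped {n_dropped} low-quality points")
        model = bundle_adjust(model, huber_px=config.huber_px, max_nfev=120)
        if n_dropped == 0:
            break
    if _pose_audit(model, config, seed):
        _filter_observations(model, config)
        model = bundle_adjust(model, huber_px=config.huber_px, max_nfev=120)
    if _smoothness_audit(model, config):
        _filter_observations(model, config)
        model = bundle_adjust(model, huber_px=config.huber_px, max_nfev=120)
    model.log.append(
        f"done: {len(model.poses)}/{len(planes)} frames, "
        f"{len([t for t in model.tracks if t.point is not None])} points, "
        f"mean reproj {model.mean_reprojection_error():.3f} px"
    )
    return model


# ---------------------------------------------------------------------------
# statistics and serialization


@dataclass(frozen=True)
class ReconstructionStats:
    n_input_frames: int
    n_registered: int
    pct_registered: float
    avg_observation: float
    mean_reprojection_px: float
    n_points: int


def reconstruction_stats(
    model: ReconstructionModel,
    n_input_frames: int,
    avg_mode: str = "track_length",
) -> ReconstructionStats:
    """Registration percentage, average observation count, reprojection error.

    ``avg_mode='track_length'`` reports the mean number of observations
    per triangulated track; ``'per_image'`` reports the mean number of
    track observations per registered image.
    """
    tri = [t for t in model.tracks if t.point is not None]
    n_obs = sum(
        sum(1 for f, _ in t.observations if f in model.poses) for t in tri
    )
    if avg_mode == "track_length":
        avg = n_obs / len(tri) if tri else 0.0
    elif avg_mode == "per_image":
        avg = n_obs / len(model.poses) if model.poses else 0.0
    else:
        raise ValueError(f"unknown avg_mode {avg_mode!r}")
    return ReconstructionStats(
        n_input_frames=n_input_frames,
        n_registered=len(model.poses),
        pct_registered=100.0 * len(model.poses) / n_input_frames,
        avg_observation=float(avg),
        mean_reprojection_px=model.mean_reprojection_error(),
        n_points=len(tri),
    )


def write_model(model: ReconstructionModel, path: str) -> dict:
    """Serialize as the widely used cameras/images/points3D text triple + PLY."""
    import os

    import trimesh

    os.makedirs(path, exist_ok=True)
    intr = model.intrinsics
    cam_path = os.path.join(path, "cameras.txt")
    with open(cam_path, "w") as fh:
        fh.write("# camera_id model width height fx fy cx cy\n")
        fh.write(
            f"1 PINHOLE {intr.width} {intr.height} {intr.fx:.10g} {intr.fy:.10g} "
            f"{intr.cx:.10g} {intr.cy:.10g}\n"
        )
    img_path = os.path.join(path, "images.txt")
    with open(img_path, "w") as fh:
        fh.write("# image_id qw qx qy qz tx ty tz camera_id name\n")
        for f in model.registered_frames:
            q, t = model.poses[f].q, model.poses[f].t
            fh.write(
                f"{f} {q[0]:.12g} {q[1]:.12g} {q[2]:.12g} {q[3]:.12g} "
                f"{t[0]:.12g} {t[1]:.12g} {t[2]:.12g} 1 frame_{f:06d}.png\n"
            )
    pts_path = os.path.join(path, "points3D.txt")
    with open(pts_path, "w") as fh:
        fh.write("# point_id x y z track[(image_id, keypoint_id), ...]\n")
        for i, tr in enumerate(model.tracks):
            if tr.point is None:
                continue
            obs = " ".join(f"{f} {k}" for f, k in tr.observations)
            x, y, z = tr.point
            fh.write(f"{i} {x:.10g} {y:.10g} {z:.10g} {obs}\n")
    ply_path = os.path.join(path, "points.ply")
    pts = model.points()
    if len(pts):
        colors = None
        cols = [t.color for t in model.tracks if t.point is not None]
        if all(c is not None for c in cols) and cols:
            colors = (np.array(cols) * 255).astype(np.uint8)
        trimesh.PointCloud(pts, colors=colors).export(ply_path)
    return {"cameras": cam_path, "images": img_path, "points3D": pts_path, "ply": ply_path}
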