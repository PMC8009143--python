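"""Shared camera geometry: intrinsics, poses, projection, similarity alignment.

Conventions used throughout the package
---------------------------------------
* Right-handed coordinates; the camera looks down its +z axis.
* Poses are stored world-to-camera: ``x_cam = R @ x_world + t``.
* Pixels are 0-based with the pixel center at integer coordinates;
  ``u`` is the column (x) coordinate, ``v`` the row (y) coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsics shared across a sequence (a single endoscope).

    Focal lengths and principal point are in pixels; ``k1``/``k2`` are
    dimensionless radial distortion coefficients (zero for the simulator).
    """

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int
    k1: float = 0.0
    k2: float = 0.0

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")

    @property
    def K(self) -> np.ndarray:
        return np.array(
            [[self.fx, 0.0, self.cx], [0.0, self.fy, self.cy], [0.0, 0.0, 1.0]]
        )

    def normalize(self, pix: np.ndarray) -> np.ndarray:
        """Pixel coordinates -> normalized image coordinates (undistorted)."""
        pix = np.atleast_2d(pix)
        x = (pix[:, 0] - self.cx) / self.fx
        y = (pix[:, 1] - self.cy) / self.fy
        if self.k1 or self.k2:
            # one Newton step is ample for the mild distortions supported here
            xd, yd = x.copy(), y.copy()
            for _ in range(5):
                r2 = x * x + y * y
                f = 1.0 + self.k1 * r2 + self.k2 * r2 * r2
                x, y = xd / f, yd / f
        return np.column_stack([x, y])

    def project(self, pts_cam: np.ndarray) -> np.ndarray:
        """Camera-frame 3D points -> pixel coordinates (no cheirality check)."""
        pts_cam = np.atleast_2d(pts_cam)
        x = pts_cam[:, 0] / pts_cam[:, 2]
        y = pts_cam[:, 1] / pts_cam[:, 2]
        if self.k1 or self.k2:
            r2 = x * x + y * y
            f = 1.0 + self.k1 * r2 + self.k2 * r2 * r2
            x, y = x * f, y * f
        return np.column_stack([self.fx * x + self.cx, self.fy * y + self.cy])


@dataclass
class Pose:
    """World-to-camera rigid transform stored as unit quaternion + translation.

    Quaternion ordering is ``(qw, qx, qy, qz)``.
    """

    q: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0, 0.0]))
    t: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        n = np.linalg.norm(self.q)
        if not np.isfinite(n) or n == 0:
            raise ValueError("quaternion must be nonzero")
        self.q = self.q / n

    @classmethod
    def from_Rt(cls, R: np.ndarray, t: np.ndarray) -> "Pose":
        q = Rotation.from_matrix(R).as_quat()  # (x, y, z, w)
        return cls(q=np.array([q[3], q[0], q[1], q[2]]), t=np.asarray(t, float))

    @property
    def R(self) -> np.ndarray:
        w, x, y, z = self.q
        return Rotation.from_quat([x, y, z, w]).as_matrix()

    @property
    def center(self) -> np.ndarray:
        """Camera center in world coordinates."""
        return -self.R.T @ self.t

    def transform(self, pts_world: np.ndarray) -> np.ndarray:
        return np.atleast_2d(pts_world) @ self.R.T + self.t

    def inverse(self) -> "Pose":
        R = self.R
        return Pose.from_Rt(R.T, -R.T @ self.t)

    def compose(self, other: "Pose") -> "Pose":
        """Return self ∘ other (apply ``other`` first)."""
        R1, R2 = self.R, other.R
        return Pose.from_Rt(R1 @ R2, R1 @ other.t + self.t)


def look_at_pose(center: np.ndarray, target: np.ndarray, up: np.ndarray) -> Pose:
    """World-to-camera pose with the optical axis pointing from center to target."""
    center = np.asarray(center, float)
    z = np.asarray(target, float) - center
    z = z / np.linalg.norm(z)
    x = np.cross(z, np.asarray(up, float))
    nx = np.linalg.norm(x)
    if nx < 1e-12:  # up parallel to view direction: pick any perpendicular
        x = np.cross(z, np.array([1.0, 0.0, 0.0]))
        nx = np.linalg.norm(x)
        if nx < 1e-12:
            x = np.cross(z, np.array([0.0, 1.0, 0.0]))
            nx = np.linalg.norm(x)
    x = x / nx
    y = np.cross(z, x)
    R = np.stack([x, y, z])  # rows = camera axes in world coords
    return Pose.from_Rt(R, -R @ center)


def rotation_angle_deg(R1: np.ndarray, R2: np.ndarray) -> float:
    """Geodesic angle between two rotations, in degrees."""
    cos = (np.trace(R1.T @ R2) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))


def angle_between_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    v1 = np.asarray(v1, float) / np.linalg.norm(v1)
    v2 = np.asarray(v2, float) / np.linalg.norm(v2)
    return float(np.degrees(np.arccos(np.clip(v1 @ v2, -1.0, 1.0))))


def umeyama_alignment(
    src: np.ndarray, dst: np.ndarray, with_scale: bool = True
) -> tuple[float, np.ndarray, np.ndarray]:
    """Least-squares similarity transform mapping ``src`` onto ``dst``.

    Returns ``(s, R, t)`` with ``dst ≈ s * R @ src + t``.  This fixes the
    gauge freedom of monocular reconstructions (rotation, translation and
    global scale are unobservable).
    """
    src = np.asarray(src, float)
    dst = np.asarray(dst, float)
    if src.shape != dst.shape or src.shape[0] < 3:
        raise ValueError("need >= 3 corresponding points of equal shape")
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    xs, xd = src - mu_s, dst - mu_d
    cov = xd.T @ xs / len(src)
    U, D, Vt = np.linalg.svd(cov)
    S = np.eye(3)
    if np.linalg.det(U) * np.linalg.det(Vt) < 0:
        S[2, 2] = -1.0
    R = U @ S @ Vt
    if with_scale:
        var_s = (xs**2).sum() / len(src)
        s = float(np.trace(np.diag(D) @ S) / var_s)
    else:
        s = 1.0
    t = mu_d - s * R @ mu_s
    return s, R, t
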