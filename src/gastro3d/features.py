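"""Keypoint detection, descriptor matching and geometric verification.

SIFT (difference-of-Gaussian extrema with gradient-orientation-histogram
descriptors) is the workhorse here because the dye pattern produces
blob-like texture at a range of scales.  Matching is exhaustive
nearest-neighbour with Lowe's ratio test plus a mutual cross-check, and
verified matches are the inliers of an essential-matrix RANSAC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from skimage.feature import SIFT

from .geometry import CameraIntrinsics

__all__ = [
    "Keypoint",
    "MatchSet",
    "detect_and_describe",
    "match_pair",
    "geometric_verify",
    "match_consistency_curve",
    "estimate_essential_ransac",
]


@dataclass(frozen=True)
class Keypoint:
    """Sub-pixel image keypoint; ``x`` is the column, ``y`` the row (0-based)."""

    x: float
    y: float
    scale: float
    orientation: float


@dataclass
class MatchSet:
    """Descriptor matches between a frame pair, with inlier flags."""

    frame_i: int
    frame_j: int
    pairs: np.ndarray  # (n, 2) int: keypoint index in i, keypoint index in j
    distances: np.ndarray  # (n,) descriptor distances
    inliers: np.ndarray = field(default=None)  # bool mask, set by verification

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=int).reshape(-1, 2)
        self.distances = np.asarray(self.distances, dtype=float).reshape(-1)
        if self.inliers is None:
            self.inliers = np.zeros(len(self.pairs), dtype=bool)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def n_inliers(self) -> int:
        return int(self.inliers.sum())

    def inlier_pairs(self) -> np.ndarray:
        return self.pairs[self.inliers]


def detect_and_describe(
    image: np.ndarray, **sift_kwargs
) -> tuple[list[Keypoint], np.ndarray]:
    """Detect SIFT keypoints and extract unit-normalized 128-d descriptors.

    Deterministic.  A contrast-free image yields zero keypoints rather
    than an error.  ``sift_kwargs`` are forwarded to the detector
    (``n_octaves``, ``c_dog`` peak threshold, ``c_edge`` edge threshold, ...).
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("empty image")
    if image.ndim != 2:
        raise ValueError("detect_and_describe expects a single-plane image")
    if min(image.shape) < 16:
        raise ValueError("image smaller than one scale-space octave")
    det = SIFT(**sift_kwargs)
    try:
        det.detect_and_extract(image)
    except RuntimeError:  # no scale-space extrema found
        return [], np.zeros((0, 128))
    kps = [
        Keypoint(x=float(c), y=float(r), scale=float(s), orientation=float(o))
        for (r, c), s, o in zip(det.positions, det.sigmas, det.orientations)
    ]
    desc = det.descriptors.astype(float)
    norms = np.linalg.norm(desc, axis=1, keepdims=True)
    desc = desc / np.maximum(norms, 1e-12)
    return kps, desc


def match_pair(
    desc_i: np.ndarray,
    desc_j: np.ndarray,
    ratio: float = 0.8,
    frame_i: int = 0,
    frame_j: int = 1,
) -> MatchSet:
    """Exhaustive nearest-neighbour matching with ratio test and cross-check.

    A match survives when its nearest/second-nearest distance ratio is
    below ``ratio`` in the i->j direction and the pairing is mutual.
    Ties are broken toward the lower keypoint index (argmin convention).
    """
    desc_i = np.asarray(desc_i, float)
    desc_j = np.asarray(desc_j, float)
    if len(desc_i) == 0 or len(desc_j) == 0:
        if len(desc_i) != len(desc_j):
            warnings.warn("one side has no descriptors; returning empty match set")
        return MatchSet(frame_i, frame_j, np.zeros((0, 2)), np.zeros(0))
    d = cdist(desc_i, desc_j)
    nn_j = np.argmin(d, axis=1)
    best = d[np.arange(len(desc_i)), nn_j]
    if d.shape[1] >= 2:
        d_masked = d.copy()
        d_masked[np.arange(len(desc_i)), nn_j] = np.inf
        second = d_masked.min(axis=1)
        ok = best < ratio * second
    else:
        ok = np.ones(len(desc_i), dtype=bool)
    nn_i = np.argmin(d, axis=0)  # cross-check: j's nearest neighbour in i
    mutual = nn_i[nn_j] == np.arange(len(desc_i))
    keep = ok & mutual
    idx_i = np.nonzero(keep)[0]
    pairs = np.column_stack([idx_i, nn_j[idx_i]])
    return MatchSet(frame_i, frame_j, pairs, best[idx_i])


# ---------------------------------------------------------------------------
# essential-matrix RANSAC


def _eight_point_essential(x1: np.ndarray, x2: np.ndarray) -> np.ndarray | None:
    """Normalized 8-point estimate of E from normalized image coordinates."""
    n = len(x1)
    A = np.column_stack(
        [
            x2[:, 0] * x1[:, 0],
            x2[:, 0] * x1[:, 1],
            x2[:, 0],
            x2[:, 1] * x1[:, 0],
            x2[:, 1] * x1[:, 1],
            x2[:, 1],
            x1[:, 0],
            x1[:, 1],
            np.ones(n),
        ]
    )
    _, _, Vt = np.linalg.svd(A)
    E = Vt[-1].reshape(3, 3)
    U, S, Vt = np.linalg.svd(E)
    s = (S[0] + S[1]) / 2.0
    return U @ np.diag([s, s, 0.0]) @ Vt


def _sampson_error(E: np.ndarray, x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """First-order epipolar error in normalized coordinates."""
    h1 = np.column_stack([x1, np.ones(len(x1))])
    h2 = np.column_stack([x2, np.ones(len(x2))])
    Ex1 = h1 @ E.T
    Etx2 = h2 @ E
    num = np.sum(h2 * Ex1, axis=1) ** 2
    den = Ex1[:, 0] ** 2 + Ex1[:, 1] ** 2 + Etx2[:, 0] ** 2 + Etx2[:, 1] ** 2
    return num / np.maximum(den, 1e-15)


def estimate_essential_ransac(
    xn1: np.ndarray,
    xn2: np.ndarray,
    threshold: float,
    seed: int = 0,
    max_iters: int = 2000,
    confidence: float = 0.999,
) -> tuple[np.ndarray | None, np.ndarray]:
    """RANSAC essential matrix on normalized coordinates.

    ``threshold`` is the Sampson distance cutoff (normalized units).
    Deterministic given ``seed``.  Returns (E, inlier_mask).
    """
    n = len(xn1)
    if n < 8:
        return None, np.zeros(n, dtype=bool)
    rng = np.random.default_rng(seed)
    best_E, best_mask, best_count = None, np.zeros(n, dtype=bool), 0
    thr2 = threshold**2
    it, needed = 0, max_iters
    while it < min(needed, max_iters):
        sample = rng.choice(n, size=8, replace=False)
        E = _eight_point_essential(xn1[sample], xn2[sample])
        if E is None:
            it += 1
            continue
        mask = _sampson_error(E, xn1, xn2) < thr2
        count = int(mask.sum())
        if count > best_count:
            best_E, best_mask, best_count = E, mask, count
            ratio = count / n
            denom = np.log(max(1.0 - ratio**8, 1e-12))
            if denom < -1e-12:
                needed = int(np.ceil(np.log(1.0 - confidence) / denom)) + 1
        it += 1
    if best_E is not None and best_count >= 8:
        # final least-squares refit on all inliers
        E = _eight_point_essential(xn1[best_mask], xn2[best_mask])
        if E is not None:
            mask = _sampson_error(E, xn1, xn2) < thr2
            if mask.sum() >= best_count:
                best_E, best_mask = E, mask
    return best_E, best_mask


def geometric_verify(
    matches: MatchSet,
    kps_i: list[Keypoint],
    kps_j: list[Keypoint],
    intrinsics: CameraIntrinsics,
    threshold_px: float = 1.0,
    seed: int = 0,
) -> MatchSet:
    """Flag matches consistent with a single essential matrix as inliers.

    The RANSAC threshold is given in pixels and converted to normalized
    coordinates with the mean focal length.  Fewer than 8 matches leaves
    everything flagged as outlier.
    """
    matches.inliers = np.zeros(len(matches), dtype=bool)
    if len(matches) < 8:
        return matches
    pix_i = np.array([[kps_i[a].x, kps_i[a].y] for a in matches.pairs[:, 0]])
    pix_j = np.array([[kps_j[b].x, kps_j[b].y] for b in matches.pairs[:, 1]])
    xn1 = intrinsics.normalize(pix_i)
    xn2 = intrinsics.normalize(pix_j)
    thr = threshold_px / ((intrinsics.fx + intrinsics.fy) / 2.0)
    E, mask = estimate_essential_ransac(xn1, xn2, thr, seed=seed)
    if E is not None:
        matches.inliers = mask
    return matches


def match_consistency_curve(
    frames: list[np.ndarray],
    intrinsics: CameraIntrinsics,
    ratio: float = 0.8,
    threshold_px: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Temporal match-consistency evaluation over 11 consecutive frames.

    The first frame is the anchor ``t``; element ``k-1`` of the returned
    curve is the number of geometrically verified inlier matches between
    the anchor and frame ``t+k`` (k = 1..10).  Also returns the average
    keypoint count per image.  This is the standard protocol for judging
    whether a texture enhancement produces matches that *persist* over
    time rather than merely more keypoints.
    """
    if len(frames) != 11:
        raise ValueError("match_consistency_curve needs exactly 11 frames (t..t+10)")
    feats = [detect_and_describe(f) for f in frames]
    avg_kp = float(np.mean([len(k) for k, _ in feats]))
    kps0, desc0 = feats[0]
    curve = np.zeros(10, dtype=int)
    for k in range(1, 11):
        kpsk, desck = feats[k]
        ms = match_pair(desc0, desck, ratio=ratio, frame_i=0, frame_j=k)
        ms = geometric_verify(ms, kps0, kpsk, intrinsics, threshold_px, seed=seed + k)
        curve[k - 1] = ms.n_inliers
    return curve, avg_kp
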