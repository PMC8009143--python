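"""Frame localization on the whole-organ model and local mesh refinement.

Once the whole stomach is reconstructed, a clinician wants to know
*where* a given frame sits on the organ and to see that neighbourhood
in more detail.  Localization is pure retrieval: the frame's stored
camera pose plus the projection of its image onto the faces it sees.
Refinement retrieves the frames connected to the reference through
shared tracks, runs plane-sweep multi-view stereo over them, meshes the
fused dense cloud at a finer scale than the global model, and polishes
vertex positions with a photometric-consistency + Laplacian-smoothness
objective (a light-weight stand-in for full inverse rendering: no
albedo/illumination factorization, geometry only).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter

from .frames import ImageFrame
from .geometry import CameraIntrinsics, Pose
from .sfm import ReconstructionModel
from .surface import (
    TexturedMesh,
    estimate_normals,
    reconstruct_mesh,
    texture_mesh,
)

__all__ = [
    "localize_frame",
    "connected_frames",
    "local_mvs",
    "refine_mesh_photometric",
    "local_pipeline",
    "LocalizeConfig",
]


@dataclass(frozen=True)
class LocalizeConfig:
    n_connected: int = 22
    n_depth_hypotheses: int = 64
    ncc_window: int = 7
    min_ncc: float = 0.2
    consistency_rel: float = 0.01
    min_consistent_views: int = 3
    mvs_sources: int = 4
    cloud_stride: int = 2
    mesh_depth_increment: int = 2
    max_cloud_points: int = 30000
    refine_views: int = 8
    crop_to_reference: bool = True
    local_max_grid: int = 96
    local_smooth_sigma: float = 0.0
    refine_iters: int = 16
    refine_step: float = 0.003  # initial vertex step, scene units
    photometric_weight: float = 1.0
    smoothness_weight: float = 0.5
    patch_scale: float = 0.04  # tangent patch half-extent, scene units
    # a vertex moves only when its graph-diffused photometric gradient
    # exceeds this (1 - NCC) threshold, set above the measured gradient
    # noise of flat-texture regions so that they cannot drift
    gradient_threshold: float = 0.00045
    # patches this close to an image border are excluded: the high-pass
    # prefilter's boundary handling corrupts the texture signal there
    border_margin_px: float = 16.0
    # camera-carried lighting adds smooth gradients that drown the weak
    # mucosal texture; a high-pass prefilter isolates the texture signal
    highpass_sigma_px: float = 8.0


def _gray(frame) -> np.ndarray:
    if isinstance(frame, ImageFrame):
        return frame.pixels.mean(axis=2) if frame.is_rgb else frame.pixels
    arr = np.asarray(frame, float)
    return arr.mean(axis=2) if arr.ndim == 3 else arr


# ---------------------------------------------------------------------------
# localization


def localize_frame(
    model: ReconstructionModel,
    tmesh: TexturedMesh,
    frame_id: int,
    frame: ImageFrame | None = None,
) -> tuple[Pose, TexturedMesh]:
    """Retrieve a frame's stored pose and its footprint on the organ mesh.

    Localization is retrieval, not re-estimation: the returned pose is
    the model's stored pose, bit for bit.  The footprint overlay is a
    textured copy of the mesh whose faces visible from that pose carry
    the frame's own projection (other faces are untextured).
    Unregistered frames raise, naming the nearest registered neighbour.
    """
    if frame_id not in model.poses:
        nearest = min(model.poses, key=lambda f: abs(f - frame_id), default=None)
        raise KeyError(
            f"frame {frame_id} is not registered; nearest registered "
            f"neighbour is frame {nearest}"
        )
    pose = model.poses[frame_id]
    src = frame if frame is not None else tmesh.frames.get(frame_id)
    if src is None:
        raise ValueError("no image available for the selected frame")
    overlay = texture_mesh(
        tmesh.mesh, [src], {frame_id: pose}, model.intrinsics,
    )
    if (overlay.face_frame >= 0).sum() == 0:
        warnings.warn(f"frame {frame_id} sees no face of the mesh (empty footprint)")
    return pose, overlay


def connected_frames(model: ReconstructionModel, frame_id: int, n: int = 22) -> list[int]:
    """Frames sharing the most tracks with the reference, most-shared first.

    This is the track-information retrieval that feeds local multi-view
    stereo: the returned cameras all observe 3D points seen by the
    reference frame.  Ties are broken by temporal proximity; the
    reference itself is never returned.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if frame_id not in model.poses:
        raise KeyError(f"frame {frame_id} is not registered")
    shared: dict[int, int] = {}
    for tr in model.tracks:
        if tr.point is None:
            continue
        fids = [f for f, _ in tr.observations if f in model.poses]
        if frame_id in fids:
            for f in fids:
                if f != frame_id:
                    shared[f] = shared.get(f, 0) + 1
    ranked = sorted(shared, key=lambda f: (-shared[f], abs(f - frame_id)))
    if len(ranked) < n:
        warnings.warn(
            f"only {len(ranked)} connected frames available (requested {n})"
        )
    return ranked[:n]


# ---------------------------------------------------------------------------
# plane-sweep multi-view stereo


def _sweep_depth(
    ref_gray: np.ndarray,
    ref_pose: Pose,
    src_grays: list[np.ndarray],
    src_poses: list[Pose],
    intr: CameraIntrinsics,
    depth_range: tuple[float, float],
    cfg: LocalizeConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """NCC plane sweep in inverse depth; returns (depth, score) maps."""
    h, w = ref_gray.shape
    u, v = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    rays = np.stack(
        [(u - intr.cx) / intr.fx, (v - intr.cy) / intr.fy, np.ones_like(u)], axis=-1
    )
    Rr_T = ref_pose.R.T
    c_ref = ref_pose.center
    inv_lo, inv_hi = 1.0 / depth_range[1], 1.0 / depth_range[0]
    inv_depths = np.linspace(inv_lo, inv_hi, cfg.n_depth_hypotheses)
    win = cfg.ncc_window
    mu_r = uniform_filter(ref_gray, win)
    var_r = uniform_filter(ref_gray**2, win) - mu_r**2
    sd_r = np.sqrt(np.maximum(var_r, 1e-10))
    floor_r = (0.05 * ref_gray.std()) ** 2

    scores = np.full((cfg.n_depth_hypotheses, h, w), -np.inf)
    for di, inv_d in enumerate(inv_depths):
        z = 1.0 / inv_d
        # world points at this depth along the reference rays
        Xw = (rays * z) @ Rr_T.T + c_ref  # (h, w, 3); rays are camera-frame
        acc = np.zeros((h, w))
        cnt = np.zeros((h, w))
        for sg, sp in zip(src_grays, src_poses):
            Xc = Xw @ sp.R.T + sp.t
            zz = Xc[:, :, 2]
            ok = zz > 1e-9
            us = np.where(ok, intr.fx * Xc[:, :, 0] / np.where(ok, zz, 1) + intr.cx, -1)
            vs = np.where(ok, intr.fy * Xc[:, :, 1] / np.where(ok, zz, 1) + intr.cy, -1)
            inb = ok & (us >= 0) & (us <= w - 1) & (vs >= 0) & (vs <= h - 1)
            warped = np.zeros((h, w))
            if inb.any():
                x0 = np.clip(us.astype(int), 0, w - 2)
                y0 = np.clip(vs.astype(int), 0, h - 2)
                fx = np.clip(us - x0, 0, 1)
                fy = np.clip(vs - y0, 0, 1)
                warped = (
                    sg[y0, x0] * (1 - fx) * (1 - fy)
                    + sg[y0, x0 + 1] * fx * (1 - fy)
                    + sg[y0 + 1, x0] * (1 - fx) * fy
                    + sg[y0 + 1, x0 + 1] * fx * fy
                )
                warped = np.where(inb, warped, 0.0)
            mu_w = uniform_filter(warped, win)
            var_w = uniform_filter(warped**2, win) - mu_w**2
            sd_w = np.sqrt(np.maximum(var_w, 1e-10))
            cov = uniform_filter(ref_gray * warped, win) - mu_r * mu_w
            ncc = cov / (sd_r * sd_w + 1e-10)
            floor_w = (0.05 * sg.std()) ** 2
            valid = inb & (var_w > floor_w) & (var_r > floor_r)
            acc += np.where(valid, ncc, 0.0)
            cnt += valid
        with np.errstate(invalid="ignore"):
            scores[di] = np.where(cnt > 0, acc / np.maximum(cnt, 1), -np.inf)

    best = np.argmax(scores, axis=0)
    best_score = np.take_along_axis(scores, best[None], axis=0)[0]
    # sub-hypothesis refinement: parabola through the three neighbours
    ii, jj = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    b0 = np.clip(best, 1, cfg.n_depth_hypotheses - 2)
    with np.errstate(all="ignore"):
        s_m = scores[b0 - 1, ii, jj]
        s_0 = scores[b0, ii, jj]
        s_p = scores[b0 + 1, ii, jj]
        denom = s_m - 2 * s_0 + s_p
        delta = np.where(np.abs(denom) > 1e-12, 0.5 * (s_m - s_p) / denom, 0.0)
    delta = np.clip(np.where(np.isfinite(delta), delta, 0.0), -0.5, 0.5)
    step = inv_depths[1] - inv_depths[0]
    inv_best = inv_depths[b0] + delta * step
    depth = 1.0 / inv_best
    depth = np.where(best_score >= cfg.min_ncc, depth, np.nan)
    return depth.astype(np.float32), best_score.astype(np.float32)


def local_mvs(
    frames: list[ImageFrame],
    poses: dict,
    intrinsics: CameraIntrinsics,
    depth_range: tuple[float, float],
    config: LocalizeConfig | None = None,
) -> tuple[dict, np.ndarray]:
    """Dense local geometry by plane-sweep stereo with consistency fusion.

    Each frame serves once as the reference against its nearest-pose
    sources; a depth estimate survives only when re-projected depths
    agree across ``min_consistent_views`` other views to within
    ``consistency_rel``.  Texture-less regions fail the NCC floor and
    come out empty rather than wrong.
    Returns (per-frame depth maps, fused world-space point cloud).
    """
    config = config or LocalizeConfig()
    if len(frames) < 3:
        raise ValueError("local MVS needs at least 3 posed frames")
    if not depth_range[0] < depth_range[1] or depth_range[0] <= 0:
        raise ValueError("depth_range must be (near, far) with 0 < near < far")
    fids = [f.frame_id for f in frames]
    missing = [f for f in fids if f not in poses]
    if missing:
        raise ValueError(f"frames without poses: {missing}")
    # the endoscope's own light paints a smooth, depth-insensitive
    # gradient over every image; high-pass filtering leaves the actual
    # surface texture for the photometric consistency to lock onto
    from scipy.ndimage import gaussian_filter as _gf

    def prep(img):
        g = _gray(img)
        if config.highpass_sigma_px > 0:
            g = g - _gf(g, config.highpass_sigma_px)
        return g

    grays = {f.frame_id: prep(f) for f in frames}
    centers = {fid: poses[fid].center for fid in fids}

    depths: dict[int, np.ndarray] = {}
    for fid in fids:
        others = sorted(
            (g for g in fids if g != fid),
            key=lambda g: np.linalg.norm(centers[g] - centers[fid]),
        )[: config.mvs_sources]
        depths[fid], _ = _sweep_depth(
            grays[fid],
            poses[fid],
            [grays[g] for g in others],
            [poses[g] for g in others],
            intrinsics,
            depth_range,
            config,
        )

    # cross-view depth consistency + fusion
    h, w = next(iter(grays.values())).shape
    u, v = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    fused = []
    s = config.cloud_stride
    for fid in fids:
        d = depths[fid]
        rays = np.stack(
            [(u - intrinsics.cx) / intrinsics.fx, (v - intrinsics.cy) / intrinsics.fy,
             np.ones_like(u)], axis=-1,
        )
        Xw = (rays * d[:, :, None]) @ poses[fid].R + poses[fid].center
        consist = np.zeros((h, w))
        for g in fids:
            if g == fid:
                continue
            Xc = Xw @ poses[g].R.T + poses[g].t
            zz = Xc[:, :, 2]
            ok = np.isfinite(zz) & (zz > 1e-9)
            us = intrinsics.fx * np.where(ok, Xc[:, :, 0] / np.where(ok, zz, 1), 0) + intrinsics.cx
            vs = intrinsics.fy * np.where(ok, Xc[:, :, 1] / np.where(ok, zz, 1), 0) + intrinsics.cy
            inb = ok & (us >= 0) & (us <= w - 1) & (vs >= 0) & (vs <= h - 1)
            ui = np.clip(np.round(us).astype(int), 0, w - 1)
            vi = np.clip(np.round(vs).astype(int), 0, h - 1)
            d_other = depths[g][vi, ui]
            rel = np.abs(d_other - zz) / np.maximum(zz, 1e-9)
            consist += (inb & np.isfinite(d_other) & (rel < config.consistency_rel))
        good = np.isfinite(d) & (consist >= config.min_consistent_views)
        sel = good[::s, ::s]
        fused.append(Xw[::s, ::s][sel])
    cloud = np.concatenate(fused, axis=0) if fused else np.zeros((0, 3))
    return depths, cloud


# ---------------------------------------------------------------------------
# photometric refinement


def _bilinear(img: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    h, w = img.shape
    x = np.clip(x, 0, w - 1.001)
    y = np.clip(y, 0, h - 1.001)
    x0 = x.astype(int)
    y0 = y.astype(int)
    fx, fy = x - x0, y - y0
    return (
        img[y0, x0] * (1 - fx) * (1 - fy)
        + img[y0, x0 + 1] * fx * (1 - fy)
        + img[y0 + 1, x0] * (1 - fx) * fy
        + img[y0 + 1, x0 + 1] * fx * fy
    )


def _tangent_offsets(normals: np.ndarray, patch_scale: float) -> np.ndarray:
    """Rigid 3x3 tangent-plane sample offsets per vertex, (V, 9, 3)."""
    a = np.where(np.abs(normals[:, 2:3]) < 0.9, [[0.0, 0.0, 1.0]], [[1.0, 0.0, 0.0]])
    t1 = np.cross(normals, a)
    t1 /= np.linalg.norm(t1, axis=1, keepdims=True)
    t2 = np.cross(normals, t1)
    grid = (-1.0, -0.5, 0.0, 0.5, 1.0)
    offs = [(i, j) for i in grid for j in grid]
    return np.stack([patch_scale * (i * t1 + j * t2) for i, j in offs], axis=1)


def _star_offsets(mesh) -> np.ndarray:
    """Patch offsets from each vertex to its mesh neighbours, (V, S, 3).

    The sample star lies exactly on the mesh, so a mesh that coincides
    with the true surface is an exact fixed point of the photometric
    objective (a rigid tangent patch would bow off a curved surface).
    Rows are padded to the maximum vertex degree with zero offsets.
    """
    verts = mesh.vertices
    neigh = mesh.vertex_neighbors
    deg = max((len(nb) for nb in neigh), default=0)
    out = np.zeros((len(verts), deg + 1, 3))
    for i, nb in enumerate(neigh):
        if nb:
            out[i, 1 : 1 + len(nb)] = verts[nb] - verts[i]
    return out


def _photometric_cost(
    verts: np.ndarray,
    normals: np.ndarray,
    grays: list[np.ndarray],
    poses: list[Pose],
    intr: CameraIntrinsics,
    patch_scale: float,
    return_support: bool = False,
    border_margin: float = 16.0,
    offsets: np.ndarray | None = None,
):
    """Per-vertex median pairwise (1 - NCC) of projected patches.

    The patch around each vertex is either a rigid tangent-plane grid
    (``patch_scale``) or, when ``offsets`` is given, the vertex's own
    mesh-neighbourhood star translated with it.
    """
    n_v = len(verts)
    if offsets is None:
        offsets = _tangent_offsets(normals, patch_scale)
    pts = verts[:, None, :] + offsets  # (V, S, 3)
    h, w = grays[0].shape
    patches = []
    valid = []
    for gray, pose in zip(grays, poses):
        Xc = pts @ pose.R.T + pose.t
        z = Xc[:, :, 2]
        ok = (z > 1e-9).all(axis=1)
        z = np.where(np.abs(z) < 1e-9, 1e-9, z)
        us = intr.fx * Xc[:, :, 0] / z + intr.cx
        vs = intr.fy * Xc[:, :, 1] / z + intr.cy
        m = border_margin
        inb = ok & (
            (us >= m) & (us <= w - 1 - m) & (vs >= m) & (vs <= h - 1 - m)
        ).all(axis=1)
        vals = _bilinear(gray, us, vs)
        patches.append(vals)
        valid.append(inb)
    P = np.stack(patches)  # (views, V, 9)
    V = np.stack(valid)  # (views, V)
    mu = P.mean(axis=2, keepdims=True)
    sd = P.std(axis=2, keepdims=True)
    # a patch with no real signal (flat region) would be pure amplified
    # noise after normalization; require a variance floor per view
    gstd = np.array([g.std() for g in grays])[:, None]
    V = V & (sd[:, :, 0] > 0.05 * gstd)
    Z = (P - mu) / np.maximum(sd, 1e-8)
    nv = len(grays)
    pair_costs = []
    pair_valid = []
    for i in range(nv):
        for j in range(i + 1, nv):
            both = V[i] & V[j]
            ncc = np.mean(Z[i] * Z[j], axis=1)
            pair_costs.append(np.where(both, 1.0 - ncc, np.nan))
            pair_valid.append(both)
    PC = np.stack(pair_costs)  # (pairs, V)
    cnt = np.stack(pair_valid).sum(axis=0)
    with np.errstate(all="ignore"):
        # median over view pairs: one misbehaving view (border effects,
        # grazing geometry) cannot attract or repel the vertex
        out = np.where(cnt > 0, np.nanmedian(PC, axis=0), 0.0)
    out = np.where(np.isfinite(out), out, 0.0)
    if return_support:
        return out, cnt
    return out


def refine_mesh_photometric(
    mesh,
    frames: list[ImageFrame],
    poses: dict,
    intrinsics: CameraIntrinsics,
    config: LocalizeConfig | None = None,
):
    """Move vertices along their normals to maximize multi-view agreement.

    Objective per vertex: photometric_weight * mean pairwise (1 - NCC)
    of small projected tangent patches + smoothness_weight * squared
    distance to the neighbour centroid (umbrella Laplacian).  Vertices
    take discrete steps {-δ, 0, +δ} chosen greedily; a joint step is
    accepted only if the global objective decreases, otherwise δ is
    halved.  The objective is therefore non-increasing.
    With photometric_weight = 0 this reduces to pure Laplacian smoothing.
    """
    import trimesh as _trimesh

    from scipy.ndimage import gaussian_filter

    config = config or LocalizeConfig()
    mesh = mesh.copy()
    grays = [_gray(f) for f in frames]
    if config.highpass_sigma_px > 0 and config.photometric_weight > 0:
        grays = [g - gaussian_filter(g, config.highpass_sigma_px) for g in grays]
    pose_list = [poses[f.frame_id] for f in frames]
    neigh = mesh.vertex_neighbors
    lam_p, lam_s = config.photometric_weight, config.smoothness_weight

    # row-normalized vertex adjacency (sparse) for umbrella operators
    from scipy.sparse import csr_matrix

    rows, cols = [], []
    for i, nb in enumerate(neigh):
        if nb:
            rows.extend([i] * len(nb))
            cols.extend(nb)
        else:
            rows.append(i)
            cols.append(i)
    deg = np.bincount(rows, minlength=len(mesh.vertices)).astype(float)
    data = 1.0 / deg[np.array(rows)]
    A = csr_matrix((data, (rows, cols)), shape=(len(mesh.vertices),) * 2)

    def smooth_cost(verts):
        return np.sum((verts - A @ verts) ** 2, axis=1)

    v0 = mesh.vertices.copy()

    def smooth_disp_cost(verts):
        # umbrella Laplacian of the displacement field: zero whenever the
        # mesh is undeformed, so an initial mesh that already coincides
        # with the true surface is an exact fixed point
        d = verts - v0
        return np.sum((d - A @ d) ** 2, axis=1)

    def phot_cost(verts, normals):
        return _photometric_cost(
            verts, normals, grays, pose_list, intrinsics,
            config.patch_scale, border_margin=config.border_margin_px,
        )

    step = config.refine_step
    verts = mesh.vertices.copy()
    if lam_p == 0:
        # pure-smoothing mode: classical Laplacian shrinkage
        for _ in range(config.refine_iters):
            verts = verts + 0.5 * (A @ verts - verts)
        out = _trimesh.Trimesh(vertices=verts, faces=mesh.faces, process=False)
        return out

    vm0 = _trimesh.Trimesh(vertices=verts, faces=mesh.faces, process=False)
    _, support = _photometric_cost(
        verts, vm0.vertex_normals, grays, pose_list, intrinsics,
        config.patch_scale, return_support=True,
        border_margin=config.border_margin_px,
    )
    movable = support > 0
    for _ in range(config.refine_iters):
        vm = _trimesh.Trimesh(vertices=verts, faces=mesh.faces, process=False)
        normals = vm.vertex_normals.copy()
        base_p = lam_p * phot_cost(verts, normals)
        base = base_p + lam_s * smooth_disp_cost(verts)
        # signed photometric preference per vertex, diffused over the mesh
        # graph: a smooth deformation signals coherently across a region
        # and survives averaging, while per-vertex artifacts cancel out
        c_m = lam_p * phot_cost(verts - step * normals, normals)
        c_p = lam_p * phot_cost(verts + step * normals, normals)
        g = 0.5 * (c_p - c_m)
        for _ in range(6):
            g = 0.5 * g + 0.5 * (A @ g)
        kappa = lam_p * config.gradient_threshold * (step / config.refine_step)
        choice = np.where(np.abs(g) > kappa, -np.sign(g), 0.0)
        choice = np.where(movable, choice, 0.0)
        proposal = verts + choice[:, None] * step * normals
        new_total = (lam_p * phot_cost(proposal, normals)
                     + lam_s * smooth_disp_cost(proposal)).sum()
        if choice.any() and new_total < base.sum() - 1e-12:
            verts = proposal
        else:
            step = step * 0.5
            if step < 1e-6:
                break
    out = _trimesh.Trimesh(vertices=verts, faces=mesh.faces, process=False)
    return out


# ---------------------------------------------------------------------------
# composite pipeline


def local_pipeline(
    model: ReconstructionModel,
    tmesh: TexturedMesh,
    frames: list[ImageFrame],
    frame_id: int,
    n: int | None = None,
    config: LocalizeConfig | None = None,
) -> tuple[TexturedMesh, dict]:
    """Track-connected local refinement around one reference frame.

    Runs connected-frame retrieval, local plane-sweep MVS, fine-scale
    meshing of the fused cloud, photometric refinement and no-dye
    texturing.  The local output lives in the global model's coordinate
    frame, so it is directly consistent with the whole-organ mesh.
    """
    config = config or LocalizeConfig()
    n = n if n is not None else config.n_connected
    if n < 3:
        warnings.warn("fewer than 3 connected frames: MVS support is weak")
        n = max(n, 2)
    try:
        conn = connected_frames(model, frame_id, max(n, 2))
    except ValueError:
        conn = []
    use_ids = [frame_id] + conn
    frame_map = {f.frame_id: f for f in frames}
    use_frames = [frame_map[f] for f in use_ids if f in frame_map and f in model.poses]
    if len(use_frames) < 3:
        raise ValueError(
            f"local MVS needs >= 3 posed frames around frame {frame_id} "
            f"(stage: connected-frame retrieval)"
        )
    # depth range from the reference frame's own track points
    zs = []
    for tr in model.tracks:
        if tr.point is None:
            continue
        if any(f == frame_id for f, _ in tr.observations):
            zs.append(model.poses[frame_id].transform(tr.point)[0, 2])
    if zs:
        z = np.array(zs)
        depth_range = (
            max(float(np.quantile(z, 0.05)) * 0.9, 1e-3),
            float(np.quantile(z, 0.95)) * 1.15,
        )
    else:
        depth_range = (0.05, 5.0)
    depths, cloud = local_mvs(
        use_frames, model.poses, model.intrinsics, depth_range, config
    )
    if len(cloud) and config.crop_to_reference:
        # keep only the region the reference frame actually sees: the
        # local model is about the neighbourhood of that frame
        pr = model.poses[frame_id]
        Xc = cloud @ pr.R.T + pr.t
        zc = Xc[:, 2]
        okz = zc > 1e-9
        uu = np.where(okz, model.intrinsics.fx * Xc[:, 0] / np.where(okz, zc, 1) + model.intrinsics.cx, -1)
        vv = np.where(okz, model.intrinsics.fy * Xc[:, 1] / np.where(okz, zc, 1) + model.intrinsics.cy, -1)
        m = 10.0
        inref = okz & (uu >= -m) & (uu <= model.intrinsics.width - 1 + m) \
            & (vv >= -m) & (vv <= model.intrinsics.height - 1 + m)
        if inref.sum() >= 100:
            cloud = cloud[inref]
    if len(cloud) > config.max_cloud_points:
        sel = np.random.default_rng(0).choice(
            len(cloud), config.max_cloud_points, replace=False
        )
        cloud = cloud[sel]
    if len(cloud) < 100:
        raise ValueError(
            f"local MVS produced too few consistent points ({len(cloud)}) "
            "(stage: multi-view stereo)"
        )
    centers = np.array([model.poses[f].center for f in use_ids if f in model.poses])
    normals = estimate_normals(cloud, k=16, interior_point=centers.mean(axis=0))
    local_mesh = reconstruct_mesh(
        cloud, normals, depth=7 + config.mesh_depth_increment,
        max_grid=config.local_max_grid, smooth_sigma=config.local_smooth_sigma,
    )
    ref_center = model.poses[frame_id].center
    refine_frames = sorted(
        use_frames,
        key=lambda f: np.linalg.norm(model.poses[f.frame_id].center - ref_center),
    )[: config.refine_views]
    refined = refine_mesh_photometric(
        local_mesh, refine_frames, model.poses, model.intrinsics, config
    )
    textured = texture_mesh(
        refined, use_frames, model.poses, model.intrinsics, source_domain="no_dye"
    )
    info = {
        "connected": conn,
        "depth_range": depth_range,
        "n_cloud": len(cloud),
        "depths": depths,
        "cloud": cloud,
        "initial_mesh": local_mesh,
    }
    return textured, info
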