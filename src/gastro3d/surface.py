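"""From sparse points to a textured organ surface.

Outlier structures in endoscopic reconstructions are typically planar
(specular sheets, fluid surfaces, mis-triangulated clusters), so
cleaning is done by iterated plane-RANSAC: a fitted plane's support is
removed when it sits outside the robust radial envelope of the main
cloud.  Meshing reconstructs a watertight surface from the oriented
points through a signed-distance field sampled on a regular grid and
polygonized with marching cubes; texturing assigns each face the best
observing view (most frontal, closest, unoccluded).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree
from skimage.measure import marching_cubes

from .frames import ImageFrame
from .geometry import CameraIntrinsics, Pose

__all__ = [
    "TexturedMesh",
    "remove_outliers_plane_ransac",
    "estimate_normals",
    "reconstruct_mesh",
    "texture_mesh",
    "rasterize_depth",
    "visible_faces",
    "export_textured_mesh_obj",
]


# ---------------------------------------------------------------------------
# plane-RANSAC outlier removal


def _fit_plane_ransac(pts: np.ndarray, threshold: float, rng, iters: int = 300):
    """Best RANSAC plane (unit normal n, offset d with n.x = d); returns mask.

    Samples are localized: one seed point plus two of its 30 nearest
    neighbours.  A compact planar cluster is then found as soon as one
    seed lands on it, which a global 3-point draw almost never achieves.
    """
    n_pts = len(pts)
    k_local = min(30, n_pts - 1)
    tree = cKDTree(pts)
    _, nbrs = tree.query(pts, k=k_local + 1)
    best_mask, best_count = None, -1
    for _ in range(iters):
        i0 = rng.integers(n_pts)
        j = rng.choice(k_local, 2, replace=False) + 1
        idx = np.array([i0, nbrs[i0, j[0]], nbrs[i0, j[1]]])
        p0, p1, p2 = pts[idx]
        n = np.cross(p1 - p0, p2 - p0)
        norm = np.linalg.norm(n)
        if norm < 1e-12:
            continue
        n = n / norm
        d = n @ p0
        mask = np.abs(pts @ n - d) < threshold
        if mask.sum() > best_count:
            best_count, best_mask, best_plane = int(mask.sum()), mask, (n, d)
    if best_mask is None:
        return None, np.zeros(n_pts, bool)
    # least-squares refit on the consensus set
    sel = pts[best_mask]
    c = sel.mean(axis=0)
    _, _, Vt = np.linalg.svd(sel - c)
    n = Vt[-1]
    d = n @ c
    mask = np.abs(pts @ n - d) < threshold
    return (n, d), mask


def remove_outliers_plane_ransac(
    cloud: np.ndarray,
    threshold: float = 0.02,
    min_plane_support: int = 50,
    seed: int = 0,
    max_rounds: int = 5,
    envelope_k: float = 4.0,
) -> tuple[np.ndarray, np.ndarray, list]:
    """Iteratively remove planar clusters lying off the main cloud.

    A RANSAC plane qualifies for removal when its support points fall
    outside the robust radial envelope of the cloud — radii further than
    ``envelope_k`` scaled-MAD units from the median radius about the
    cloud centroid.  Structure belonging to the organ wall itself is
    inside the envelope and never removed.  Deterministic given ``seed``.

    Returns ``(filtered_cloud, removed_indices, removal_log)``.
    """
    cloud = np.asarray(cloud, float)
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if len(cloud) < min_plane_support:
        return cloud.copy(), np.zeros(0, dtype=int), []
    rng = np.random.default_rng(seed)
    keep = np.ones(len(cloud), dtype=bool)
    log = []
    for round_idx in range(max_rounds):
        pts = cloud[keep]
        if len(pts) < min_plane_support:
            break
        center = np.median(pts, axis=0)
        radii = np.linalg.norm(pts - center, axis=1)
        med = np.median(radii)
        mad = 1.4826 * np.median(np.abs(radii - med))
        lo, hi = med - envelope_k * mad, med + envelope_k * mad
        plane, mask = _fit_plane_ransac(pts, threshold, rng)
        if plane is None or mask.sum() < min_plane_support:
            break
        support_radii = radii[mask]
        # the plane is an outlier structure when its support lies outside
        # the robust envelope of the cloud's radial distribution
        frac_outside = float(np.mean((support_radii < lo) | (support_radii > hi)))
        if frac_outside < 0.5:
            break
        remove_local = mask & ((radii < lo) | (radii > hi))
        idx_global = np.nonzero(keep)[0][remove_local]
        keep[idx_global] = False
        log.append(
            {
                "round": round_idx,
                "normal": plane[0].tolist(),
                "offset": float(plane[1]),
                "removed": int(len(idx_global)),
            }
        )
    removed = np.nonzero(~keep)[0]
    return cloud[keep], removed, log


# ---------------------------------------------------------------------------
# normals


def estimate_normals(
    cloud: np.ndarray, k: int = 16, interior_point: np.ndarray | None = None
) -> np.ndarray:
    """Per-point unit normals from local PCA planes, consistently oriented.

    Normals are flipped to face ``interior_point`` (default: the cloud
    centroid) because the endoscope observes the organ from inside —
    every surface normal that matters points toward the lumen.
    Duplicate points are de-duplicated for the neighbour search.
    """
    cloud = np.asarray(cloud, float)
    if k < 3:
        raise ValueError("k must be >= 3")
    if len(cloud) < k + 1:
        raise ValueError(f"need at least k+1={k + 1} points")
    uniq, inverse = np.unique(cloud.round(decimals=12), axis=0, return_inverse=True)
    kk = min(k, len(uniq) - 1)
    tree = cKDTree(uniq)
    _, nbr = tree.query(uniq, k=kk + 1)
    normals_u = np.empty_like(uniq)
    for i in range(len(uniq)):
        block = uniq[nbr[i]]
        c = block.mean(axis=0)
        _, _, Vt = np.linalg.svd(block - c)
        normals_u[i] = Vt[-1]
    if interior_point is None:
        interior_point = cloud.mean(axis=0)
    to_interior = interior_point[None, :] - uniq
    flip = np.sum(normals_u * to_interior, axis=1) < 0
    normals_u[flip] *= -1.0
    normals = normals_u[inverse]
    return normals / np.linalg.norm(normals, axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# meshing


def reconstruct_mesh(
    cloud: np.ndarray,
    normals: np.ndarray,
    depth: int = 7,
    k_sdf: int = 8,
    smooth_sigma: float = 1.0,
    trim_quantile: float = 0.01,
    max_grid: int = 144,
    boundary_erosion: int = 2,
) -> trimesh.Trimesh:
    """Implicit-surface reconstruction from an oriented point cloud.

    A signed-distance field is evaluated on a regular grid — the
    distance of each grid node to the plane of its ``k_sdf`` nearest
    oriented points (inward-positive normals) — lightly smoothed, and
    polygonized with marching cubes.  ``depth`` plays the role of an
    octree depth: the grid cell size is ``extent / 2**depth`` (the node
    count per axis is capped at ``max_grid``).  Vertices far from any
    input point (beyond the ``1 - trim_quantile`` support-distance
    quantile, with a generous multiplier) are trimmed; on a fully
    sampled closed surface nothing is trimmed and the output is
    watertight.
    """
    cloud = np.asarray(cloud, float)
    normals = np.asarray(normals, float)
    if len(cloud) < 100:
        raise ValueError("too few points for surface reconstruction (< 100)")
    if len(cloud) != len(normals):
        raise ValueError("cloud and normals must have equal length")
    lo = cloud.min(axis=0)
    hi = cloud.max(axis=0)
    extent = float(np.max(hi - lo))
    pad = 0.15 * extent
    lo, hi = lo - pad, hi + pad
    cell = (extent + 2 * pad) / min(2**depth, max_grid)
    ns = np.maximum(((hi - lo) / cell).astype(int) + 1, 8)
    axes = [np.linspace(lo[d], lo[d] + (ns[d] - 1) * cell, ns[d]) for d in range(3)]
    G = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)

    tree = cKDTree(cloud)
    dist, idx = tree.query(G, k=min(k_sdf, len(cloud)))
    if idx.ndim == 1:
        dist, idx = dist[:, None], idx[:, None]
    # signed distance to the local tangent planes, inverse-distance weighted
    diff = G[:, None, :] - cloud[idx]
    signed = np.einsum("nkj,nkj->nk", diff, normals[idx])
    w = 1.0 / np.maximum(dist, 1e-12)
    sdf = np.sum(signed * w, axis=1) / np.sum(w, axis=1)
    sdf_grid = sdf.reshape(ns)
    if smooth_sigma > 0:
        sdf_grid = gaussian_filter(sdf_grid, smooth_sigma)
    try:
        verts, faces, _, _ = marching_cubes(sdf_grid, level=0.0, spacing=(cell,) * 3)
    except (ValueError, RuntimeError) as exc:
        raise ValueError(f"marching cubes found no surface: {exc}") from exc
    verts = verts + lo
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    # trim vertices with no data support (open-boundary extrapolation)
    dist_v, _ = tree.query(mesh.vertices, k=1)
    # support cutoff scales with the cloud's own sampling density: mesh
    # regions further than a few point spacings are extrapolation
    d_nn, _ = tree.query(cloud, k=2)
    spacing = float(np.median(d_nn[:, 1]))
    q = np.quantile(dist_v, 1.0 - trim_quantile)
    cutoff = max(2.5 * spacing, 2.0 * cell, min(1.5 * q, 4.0 * spacing))
    good = dist_v <= cutoff
    if not good.all():
        face_ok = good[mesh.faces].all(axis=1)
        mesh.update_faces(face_ok)
        mesh.remove_unreferenced_vertices()
    # keep the dominant connected component (marching-cubes debris removal)
    comps = mesh.split(only_watertight=False)
    if len(comps) > 1:
        mesh = max(comps, key=lambda m: len(m.faces))
    # erode open-boundary rings: the outermost strips of a trimmed mesh
    # are only half-supported by data (a watertight mesh is unaffected)
    for _ in range(max(boundary_erosion, 0)):
        edges = mesh.edges_sorted
        uniq, cnt = np.unique(edges, axis=0, return_counts=True)
        bverts = np.unique(uniq[cnt == 1])
        if len(bverts) == 0:
            break
        on_boundary = np.zeros(len(mesh.vertices), dtype=bool)
        on_boundary[bverts] = True
        face_ok = ~on_boundary[mesh.faces].any(axis=1)
        if face_ok.all() or face_ok.sum() < 50:
            break
        mesh.update_faces(face_ok)
        mesh.remove_unreferenced_vertices()
    return mesh


# ---------------------------------------------------------------------------
# texturing


@dataclass
class TexturedMesh:
    """Triangle mesh with a per-face source view and texture coordinates.

    ``face_frame[i]`` is the frame id texturing face ``i`` (-1 when no
    view sees the face); ``face_uv[i]`` holds the three vertex texture
    coordinates in that frame, normalized to [0, 1] x [0, 1].
    """

    mesh: trimesh.Trimesh
    face_frame: np.ndarray
    face_uv: np.ndarray  # (n_faces, 3, 2)
    frames: dict = field(default_factory=dict)  # frame_id -> ImageFrame

    @property
    def n_untextured(self) -> int:
        return int(np.sum(self.face_frame < 0))

    @property
    def untextured_fraction(self) -> float:
        return self.n_untextured / max(len(self.face_frame), 1)


def rasterize_depth(
    mesh: trimesh.Trimesh,
    pose: Pose,
    intrinsics: CameraIntrinsics,
) -> tuple[np.ndarray, np.ndarray]:
    """Software z-buffer: per-pixel depth and front-most face index (-1 = none)."""
    h, w = intrinsics.height, intrinsics.width
    zbuf = np.full((h, w), np.inf)
    fbuf = np.full((h, w), -1, dtype=int)
    Xc = mesh.vertices @ pose.R.T + pose.t
    z = Xc[:, 2]
    proj = np.full((len(Xc), 2), np.nan)
    ok = z > 1e-9
    proj[ok] = intrinsics.project(Xc[ok])
    tri = mesh.faces
    front = ok[tri].all(axis=1)
    for fi in np.nonzero(front)[0]:
        p = proj[tri[fi]]
        zf = z[tri[fi]]
        x0 = max(int(np.floor(p[:, 0].min())), 0)
        x1 = min(int(np.ceil(p[:, 0].max())), w - 1)
        y0 = max(int(np.floor(p[:, 1].min())), 0)
        y1 = min(int(np.ceil(p[:, 1].max())), h - 1)
        if x1 < x0 or y1 < y0:
            continue
        gx, gy = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
        # barycentric coordinates on the projected triangle
        d = (p[1, 1] - p[2, 1]) * (p[0, 0] - p[2, 0]) + (p[2, 0] - p[1, 0]) * (
            p[0, 1] - p[2, 1]
        )
        if abs(d) < 1e-12:
            continue
        l1 = ((p[1, 1] - p[2, 1]) * (gx - p[2, 0]) + (p[2, 0] - p[1, 0]) * (gy - p[2, 1])) / d
        l2 = ((p[2, 1] - p[0, 1]) * (gx - p[2, 0]) + (p[0, 0] - p[2, 0]) * (gy - p[2, 1])) / d
        l3 = 1.0 - l1 - l2
        inside = (l1 >= -1e-9) & (l2 >= -1e-9) & (l3 >= -1e-9)
        if not inside.any():
            continue
        # perspective-correct depth via inverse-z interpolation
        invz = l1 / zf[0] + l2 / zf[1] + l3 / zf[2]
        depth = np.where(invz > 0, 1.0 / np.maximum(invz, 1e-12), np.inf)
        sub_z = zbuf[y0 : y1 + 1, x0 : x1 + 1]
        sub_f = fbuf[y0 : y1 + 1, x0 : x1 + 1]
        win = inside & (depth < sub_z)
        sub_z[win] = depth[win]
        sub_f[win] = fi
    return zbuf, fbuf


def visible_faces(
    mesh: trimesh.Trimesh, pose: Pose, intrinsics: CameraIntrinsics,
    depth_tol: float = 0.02,
) -> np.ndarray:
    """Faces visible from a pose, by z-buffer.

    A face counts as visible when it wins at least one pixel, or — for
    faces smaller than a pixel — when its centroid's depth agrees with
    the z-buffer at the centroid's pixel to within ``depth_tol``
    (relative).
    """
    zbuf, fbuf = rasterize_depth(mesh, pose, intrinsics)
    vis = np.zeros(len(mesh.faces), dtype=bool)
    hit = np.unique(fbuf)
    vis[hit[hit >= 0]] = True
    cen = mesh.triangles_center
    Xc = cen @ pose.R.T + pose.t
    z = Xc[:, 2]
    ok = (~vis) & (z > 1e-9)
    if ok.any():
        px = intrinsics.project(Xc[ok])
        h, w = intrinsics.height, intrinsics.width
        ui = np.round(px[:, 0]).astype(int)
        vi = np.round(px[:, 1]).astype(int)
        inb = (ui >= 0) & (ui < w) & (vi >= 0) & (vi < h)
        zc = z[ok]
        zb = np.full(len(zc), np.inf)
        zb[inb] = zbuf[vi[inb], ui[inb]]
        close = inb & np.isfinite(zb) & (np.abs(zb - zc) <= depth_tol * zc)
        idx = np.nonzero(ok)[0]
        vis[idx[close]] = True
    return vis


def texture_mesh(
    mesh: trimesh.Trimesh,
    frames: list[ImageFrame],
    poses: dict,
    intrinsics: CameraIntrinsics,
    source_domain: str = "no_dye",
) -> TexturedMesh:
    """Assign each face its best observing frame and texture coordinates.

    The per-face score is cos(viewing angle) / depth² over frames whose
    image contains all three projected vertices with positive depth and
    whose z-buffer shows the face unoccluded.  Faces no view sees are
    left untextured and counted.
    """
    frame_map = {f.frame_id: f for f in frames if f.frame_id in poses}
    if not frame_map:
        raise ValueError("no supplied frame has a registered pose")
    fids = sorted(frame_map)
    n_faces = len(mesh.faces)
    centroids = mesh.triangles_center
    fnormals = mesh.face_normals
    h, w = frame_map[fids[0]].shape

    scores = np.full((len(fids), n_faces), -np.inf)
    uvs = np.zeros((len(fids), n_faces, 3, 2))
    for a, fid in enumerate(fids):
        pose = poses[fid]
        cc = pose.center
        tri_w = mesh.vertices[mesh.faces]  # (F, 3, 3)
        Xc = np.einsum("ij,fvj->fvi", pose.R, tri_w) + pose.t
        z_ok = (Xc[:, :, 2] > 1e-9).all(axis=1)
        flat = Xc.reshape(-1, 3)
        good = flat[:, 2] > 1e-9
        p = np.full((len(flat), 2), np.nan)
        p[good] = intrinsics.project(flat[good])
        proj = p.reshape(n_faces, 3, 2)
        inb = (
            (proj[:, :, 0] >= 0)
            & (proj[:, :, 0] <= w - 1)
            & (proj[:, :, 1] >= 0)
            & (proj[:, :, 1] <= h - 1)
        ).all(axis=1)
        view = cc[None, :] - centroids
        d2 = np.sum(view * view, axis=1)
        cosang = np.einsum("fj,fj->f", fnormals, view) / np.sqrt(
            np.maximum(d2, 1e-12)
        )
        # interior-viewing: mesh face normals may point either way after
        # marching cubes; use the absolute cosine
        s = np.abs(cosang) / np.maximum(d2, 1e-12)
        ok = z_ok & inb & visible_faces(mesh, pose, intrinsics)
        scores[a, ok] = s[ok]
        uvs[a, :, :, 0] = proj[:, :, 0] / (w - 1)
        uvs[a, :, :, 1] = proj[:, :, 1] / (h - 1)

    best = np.argmax(scores, axis=0)
    has_view = np.isfinite(scores[best, np.arange(n_faces)]) & (
        scores[best, np.arange(n_faces)] > -np.inf
    )
    face_frame = np.where(has_view, np.array(fids)[best], -1)
    face_uv = uvs[best, np.arange(n_faces)]
    face_uv[~has_view] = 0.0
    return TexturedMesh(
        mesh=mesh, face_frame=face_frame, face_uv=face_uv, frames=frame_map
    )


def sample_texture(tm: TexturedMesh, face_idx: int, bary: np.ndarray) -> np.ndarray:
    """Bilinear color lookup for a barycentric point of a textured face."""
    fid = tm.face_frame[face_idx]
    if fid < 0:
        return np.zeros(3)
    frame = tm.frames[fid]
    h, w = frame.shape
    uv = bary @ tm.face_uv[face_idx]
    x = np.clip(uv[0] * (w - 1), 0, w - 1)
    y = np.clip(uv[1] * (h - 1), 0, h - 1)
    x0, y0 = int(np.floor(x)), int(np.floor(y))
    x1, y1 = min(x0 + 1, w - 1), min(y0 + 1, h - 1)
    fx, fy = x - x0, y - y0
    img = frame.pixels if frame.is_rgb else frame.pixels[:, :, None]
    c = (
        img[y0, x0] * (1 - fx) * (1 - fy)
        + img[y0, x1] * fx * (1 - fy)
        + img[y1, x0] * (1 - fx) * fy
        + img[y1, x1] * fx * fy
    )
    return c if c.shape[-1] == 3 else np.repeat(c, 3)


def export_textured_mesh_obj(tm: TexturedMesh, path_prefix: str) -> dict:
    """Write OBJ + MTL with one material (and PNG atlas) per source frame."""
    import os

    import imageio.v3 as iio

    obj_path = path_prefix + ".obj"
    mtl_path = path_prefix + ".mtl"
    os.makedirs(os.path.dirname(os.path.abspath(obj_path)), exist_ok=True)
    used = sorted({int(f) for f in tm.face_frame if f >= 0})
    tex_files = {}
    with open(mtl_path, "w") as mtl:
        for fid in used:
            img = tm.frames[fid].pixels
            if img.ndim == 2:
                img = np.stack([img] * 3, axis=-1)
            tex_name = f"{os.path.basename(path_prefix)}_frame{fid:06d}.png"
            iio.imwrite(
                os.path.join(os.path.dirname(os.path.abspath(obj_path)), tex_name),
                (np.clip(img, 0, 1) * 255).astype(np.uint8),
            )
            tex_files[fid] = tex_name
            mtl.write(f"newmtl frame{fid:06d}\nKd 1 1 1\nmap_Kd {tex_name}\n\n")
    with open(obj_path, "w") as obj:
        obj.write(f"mtllib {os.path.basename(mtl_path)}\n")
        for v in tm.mesh.vertices:
            obj.write(f"v {v[0]:.8g} {v[1]:.8g} {v[2]:.8g}\n")
        vt_index = {}
        vt_lines = []
        f_lines_by_frame: dict[int, list] = {fid: [] for fid in used}
        f_untextured = []
        for fi, face in enumerate(tm.mesh.faces):
            fid = int(tm.face_frame[fi])
            if fid < 0:
                f_untextured.append("f " + " ".join(str(v + 1) for v in face))
                continue
            idxs = []
            for corner in range(3):
                u, vv = tm.face_uv[fi, corner]
                key = (round(float(u), 6), round(1.0 - float(vv), 6))
                if key not in vt_index:
                    vt_index[key] = len(vt_index) + 1
                    vt_lines.append(f"vt {key[0]} {key[1]}")
                idxs.append(vt_index[key])
            f_lines_by_frame[fid].append(
                "f "
                + " ".join(f"{v + 1}/{t}" for v, t in zip(face, idxs))
            )
        obj.write("\n".join(vt_lines) + "\n")
        for fid in used:
            obj.write(f"usemtl frame{fid:06d}\n")
            obj.write("\n".join(f_lines_by_frame[fid]) + "\n")
        if f_untextured:
            obj.write("\n".join(f_untextured) + "\n")
    return {"obj": obj_path, "mtl": mtl_path, "textures": tex_files}
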