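"""CT-to-ultrasound registration stand-in: bone echoes to posterior surface.

This module plays the role of the navigation system's registration engine.
It is an intentionally transparent stand-in, not a re-implementation of
the production algorithm: bone-surface points are extracted from the sweep
frames (deepest confirmed echo per column, shadow-checked, sub-pixel
refined), mapped to the reference space through the tracked poses, and
rigidly aligned to the first-hit posterior vertebral surface extracted
from the CT labelmap using trimmed iterative closest point (ICP).  The
initialization exploits the acquisition convention — a linear
caudo-cranial scan over the target level with the beam pointing
antero-posteriorly — exactly as the navigated workflow does.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .geometry import PointSet, RigidTransform, compose, fit_rigid_landmarks, invert
from .phantom import SpinePhantom, decode_label
from .ultrasound import TrackedFrame, TrackedSweep
from .volume import Volume

__all__ = [
    "BoneCloud",
    "CTSurface",
    "RegistrationResult",
    "EmptyCloudError",
    "extract_bone_points_frame",
    "sweep_to_cloud",
    "extract_ct_surface",
    "initialize_from_sweep",
    "icp_register",
    "register_sweep",
]


class EmptyCloudError(RuntimeError):
    """No bone echoes were extracted; registration cannot proceed."""


@dataclass
class BoneCloud:
    """Bone-surface candidates in reference space with provenance."""

    points: PointSet
    frame_index: np.ndarray
    column_index: np.ndarray
    intensity: np.ndarray

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class CTSurface:
    """First-hit posterior surface points of one level (CT space, mm)."""

    points: PointSet
    levels: np.ndarray  # level id per point (own level or included neighbor)
    normals: np.ndarray | None = None  # unit normals, estimated on demand

    def __len__(self) -> int:
        return len(self.points)

    def estimate_normals(self, k: int = 10) -> np.ndarray:
        """Local-PCA surface normals (sign not oriented; cached)."""
        if self.normals is None:
            pts = self.points.points
            tree = cKDTree(pts)
            _, nn = tree.query(pts, k=min(k, len(pts)))
            neigh = pts[nn] - pts[nn].mean(axis=1, keepdims=True)
            cov = np.einsum("nki,nkj->nij", neigh, neigh)
            _, vecs = np.linalg.eigh(cov)
            self.normals = vecs[:, :, 0]  # smallest-eigenvalue direction
        return self.normals


@dataclass
class RegistrationResult:
    transform: RigidTransform  # reference -> CT
    iterations: int
    final_rms_mm: float
    converged: bool
    rms_trace: list[float] = field(default_factory=list)


def extract_bone_points_frame(
    frame: TrackedFrame,
    config,
    echo_threshold: float = 0.4,
    shadow_ratio: float = 0.5,
) -> np.ndarray:
    """Per-column bone-echo positions in frame mm coordinates (u, v).

    For each column the deepest peak above ``echo_threshold`` is kept only
    if the mean intensity beyond it is below ``shadow_ratio`` times the
    peak (acoustic-shadow confirmation, which rejects bright structures
    with signal behind them).  Peak rows are refined to sub-pixel depth by
    a three-point parabolic fit.  Returns an (n, 3) array of
    (u_mm, v_mm, peak intensity); may be empty.
    """
    if not 0 < echo_threshold < 1 or not 0 < shadow_ratio < 1:
        raise ValueError("thresholds must lie in (0, 1)")
    img = frame.image
    n_rows, n_cols = img.shape
    pv, _ = config.pixel_spacing_mm
    u = config.column_positions_mm()
    out = []
    for j in range(n_cols):
        col = img[:, j]
        above = np.nonzero(col > echo_threshold)[0]
        if len(above) == 0:
            continue
        # peak of the deepest contiguous supra-threshold run
        runs = np.split(above, np.nonzero(np.diff(above) > 1)[0] + 1)
        deepest = runs[-1]
        r = deepest[np.argmax(col[deepest])]
        tail = col[min(r + 3, n_rows):]
        if tail.size and tail.mean() >= shadow_ratio * col[r]:
            continue
        if 0 < r < n_rows - 1:
            denom = col[r - 1] - 2 * col[r] + col[r + 1]
            delta = 0.5 * (col[r - 1] - col[r + 1]) / denom if abs(denom) > 1e-12 else 0.0
            delta = float(np.clip(delta, -0.5, 0.5))
        else:
            delta = 0.0
        out.append([u[j], (r + delta + 0.5) * pv, col[r]])
    return np.array(out).reshape(-1, 3)[:, :] if out else np.empty((0, 3))


def sweep_to_cloud(
    sweep: TrackedSweep, echo_threshold: float = 0.4, shadow_ratio: float = 0.5
) -> BoneCloud:
    """Extract bone points from every frame and map them to reference space."""
    pts, fidx, cidx, inten = [], [], [], []
    u = sweep.config.column_positions_mm()
    for i, frame in enumerate(sweep.frames):
        uv = extract_bone_points_frame(frame, sweep.config, echo_threshold, shadow_ratio)
        if len(uv) == 0:
            continue
        local = np.column_stack([uv[:, 0], uv[:, 1], np.zeros(len(uv))])
        pts.append(frame.pose.apply_points(local))
        # recover column indices from lateral offsets
        cidx.append(np.searchsorted(u, uv[:, 0] - 1e-9))
        fidx.append(np.full(len(uv), i))
        inten.append(uv[:, 2])
    if not pts:
        raise EmptyCloudError("no bone echoes above threshold in any frame")
    return BoneCloud(
        points=PointSet(np.vstack(pts), frame="reference"),
        frame_index=np.concatenate(fidx),
        column_index=np.concatenate(cidx),
        intensity=np.concatenate(inten),
    )


def extract_ct_surface(
    labelmap: Volume, level: int, include_neighbors: bool = True
) -> CTSurface:
    """Posterior first-hit surface of one vertebra from the labelmap.

    For every (x, z) voxel column the first voxel of the level's labels
    encountered marching posterior→anterior (decreasing y) is emitted as a
    surface point at its voxel center.  With ``include_neighbors`` the
    directly adjacent levels contribute their own first-hit surfaces too,
    which lets a badly initialized alignment latch onto the wrong level —
    the failure mode the robustness analysis needs to be able to produce.
    """
    lev, _ = decode_label(labelmap.array)
    lev = np.where(labelmap.array != 0, lev, 0)
    n_levels = int(lev.max())
    if not 1 <= level <= n_levels or not np.any(lev == level):
        raise ValueError(f"level {level} absent from labelmap")
    wanted = [level]
    if include_neighbors:
        wanted += [l for l in (level - 1, level + 1) if 1 <= l <= n_levels]

    pts, levels = [], []
    for lv in wanted:
        mask = lev == lv
        any_col = mask.any(axis=1)
        # first True along y scanning from the posterior side (max y index)
        rev = mask[:, ::-1, :]
        first = rev.argmax(axis=1)
        ny = mask.shape[1]
        ix, iz = np.nonzero(any_col)
        iy = ny - 1 - first[ix, iz]
        idx = np.column_stack([ix, iy, iz])
        pts.append(labelmap.index_to_world(idx))
        levels.append(np.full(len(idx), lv))
    return CTSurface(
        points=PointSet(np.vstack(pts), frame="CT"), levels=np.concatenate(levels)
    )


def initialize_from_sweep(
    sweep: TrackedSweep, phantom: SpinePhantom, level: int
) -> RigidTransform:
    """Initial reference→CT transform from the acquisition convention.

    The sweep's travel direction is mapped to the CT caudo-cranial (+z)
    axis and the mean image depth axis to the antero-posterior (−y) axis;
    the translation places the sweep midpoint on the probe standoff plane
    directly posterior of the level's labelmap centroid.
    """
    if len(sweep) < 2:
        raise ValueError("need at least 2 frames to determine the travel direction")
    origins = sweep.frame_origins_reference()
    travel = origins[-1] - origins[0]
    norm = np.linalg.norm(travel)
    if norm < 1e-9:
        raise ValueError("degenerate sweep: zero-length travel direction")
    travel /= norm
    depth_dirs = np.array([f.pose.rotation[:, 1] for f in sweep.frames])
    depth_mean = depth_dirs.mean(axis=0)
    depth_mean -= travel * (depth_mean @ travel)  # orthogonalize
    depth_mean /= np.linalg.norm(depth_mean)
    third = np.cross(travel, depth_mean)
    # reference basis (travel, depth, travel x depth) -> CT basis (+z, -y, ...)
    b_ref = np.column_stack([travel, depth_mean, third])
    b_ct = np.column_stack([[0, 0, 1], [0, -1, 0], np.cross([0, 0, 1], [0, -1, 0])])
    rot = b_ct @ b_ref.T
    u, _, vt = np.linalg.svd(rot)
    rot = u @ np.diag([1, 1, np.sign(np.linalg.det(u @ vt))]) @ vt

    centroid = phantom.level_centroid(level)
    target = np.array([centroid[0], phantom.probe_plane_y(), centroid[2]])
    midpoint = origins.mean(axis=0)
    return RigidTransform.from_rotation_translation(rot, target - rot @ midpoint)


def icp_register(
    cloud: BoneCloud,
    surface: CTSurface,
    init: RigidTransform,
    max_iter: int = 50,
    tol_mm: float = 1e-4,
    trim_fraction: float = 0.2,
) -> RegistrationResult:
    """Trimmed ICP of the bone cloud onto the CT surface.

    Correspondences are exact nearest neighbors on a k-d tree built once
    over the surface (ties broken by lowest surface index); each iteration
    discards the ``trim_fraction`` worst pairs, projects each matched
    surface point onto its local tangent plane (so the cloud may slide
    along the surface — plain point-to-point updates stall at a fraction
    of the voxel spacing on flat regions), and updates the transform with
    the closed-form rigid landmark fit.  The accepted-iteration RMS of
    point-to-surface distances is non-increasing by construction: a step
    that worsens it is reverted and the search stops.  Stops when the RMS
    improves by less than ``tol_mm``; non-convergence within ``max_iter``
    is reported through the ``converged`` flag, never as an exception.
    """
    if len(cloud) == 0 or len(surface) == 0:
        raise ValueError("ICP requires a non-empty cloud and surface")
    src = cloud.points.points
    surf_pts = surface.points.points
    normals = surface.estimate_normals()
    tree = cKDTree(surf_pts)
    keep = max(int(np.ceil(len(src) * (1.0 - trim_fraction))), 3)

    current = init
    trace: list[float] = []
    prev_rms = np.inf
    best = current
    for it in range(1, max_iter + 1):
        moved = current.apply_points(src)
        dist, nn = tree.query(moved, k=1)
        n = normals[nn]
        plane_dist = np.abs(np.sum((moved - surf_pts[nn]) * n, axis=1))
        order = np.argsort(plane_dist, kind="stable")[:keep]
        rms = float(np.sqrt(np.mean(plane_dist[order] ** 2)))
        if rms > prev_rms + 1e-12:
            # the step made things worse: revert and stop at the best state
            return RegistrationResult(best, it, prev_rms, True, trace)
        trace.append(rms)
        best = current
        if prev_rms - rms < tol_mm:
            return RegistrationResult(best, it, rms, True, trace)
        prev_rms = rms
        # project moved points onto the matched tangent planes: the rigid
        # fit then realizes a point-to-plane step via fit_rigid_landmarks
        signed = np.sum((moved[order] - surf_pts[nn[order]]) * n[order], axis=1)
        targets = moved[order] - signed[:, None] * n[order]
        update, _ = fit_rigid_landmarks(moved[order], targets)
        current = compose(update, current)
    return RegistrationResult(best, max_iter, prev_rms, False, trace)


def register_sweep(
    sweep: TrackedSweep,
    phantom: SpinePhantom,
    labelmap: Volume | None = None,
    echo_threshold: float = 0.4,
    shadow_ratio: float = 0.5,
    include_neighbors: bool = True,
    max_iter: int = 50,
    tol_mm: float = 1e-4,
    trim_fraction: float = 0.2,
) -> RegistrationResult:
    """Full stand-in pipeline for one acquisition: cloud → init → ICP."""
    cloud = sweep_to_cloud(sweep, echo_threshold, shadow_ratio)
    surface = extract_ct_surface(
        labelmap if labelmap is not None else phantom.labelmap,
        sweep.level,
        include_neighbors=include_neighbors,
    )
    init = initialize_from_sweep(sweep, phantom, sweep.level)
    return icp_register(cloud, surface, init, max_iter=max_iter, tol_mm=tol_mm,
                        trim_fraction=trim_fraction)
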