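"""Parametric lumbosacral spine phantom with CT-like volumes.

The phantom stands in for a physical specimen: six vertebrae (L1–L6)
rigidly fixed to a frame carrying four infrared-reflective fiducial
spheres.  Each vertebra is assembled from geometric primitives voxelized
at the base grid spacing:

* ``SP`` — spinous process: a posterior mid-sagittal fin;
* ``L``  — laminae: paired slabs flanking the spinous process;
* ``AP`` — articular processes: two superior and two inferior knobs that
  protrude posteriorly past the laminae;
* ``TP`` — transverse processes: deep lateral bars;
* ``VB`` — vertebral body and pedicles: a deep cylinder plus connecting
  bars.

Levels are indexed 1..n from superior (L1) to inferior (L6); the world
z axis points superiorly, y posteriorly, x to the left (LPS, mm).  The
spinous-process apices of successive levels are separated by configurable
gaps; the defaults are the measured inter-spinous distances of the study
specimen, listed caudally from L6/L5 to L2/L1, so that error-propagation
lever arms match the real geometry (L1–L6 span 221.74 mm).

Depth staging is deliberate: with the probe resting 5 mm above the
spinous apex, a 5 cm imaging depth reaches the spinous process, laminae
and articular processes, while the transverse processes and vertebral
body only enter the field at 7 cm — the visibility pattern of an open
posterior surgical approach.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import PointSet
from .volume import Volume

__all__ = [
    "REGIONS",
    "VertebraShape",
    "PhantomConfig",
    "SpinePhantom",
    "generate_phantom",
    "resample_ct",
    "region_code",
    "decode_label",
]

#: Region codes within a level, posterior to anterior.
REGIONS = {"SP": 1, "L": 2, "AP": 3, "TP": 4, "VB": 5}
_REGION_NAMES = {v: k for k, v in REGIONS.items()}

#: Default inter-spinous gaps (mm), caudal first: L6/L5, L5/L4, ..., L2/L1.
DEFAULT_GAPS_MM = (69.36, 35.33, 38.21, 39.38, 39.46)

LANDMARK_NAMES = (
    "spinous_apex",
    "lamina_left",
    "lamina_right",
    "superior_ap_left",
    "superior_ap_right",
    "transverse_tip_left",
    "transverse_tip_right",
)


def region_code(level: int, region: str) -> int:
    """Labelmap code for ``region`` of vertebra ``level`` (1-based)."""
    return (level - 1) * 5 + REGIONS[region]


def decode_label(code: np.ndarray | int) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`region_code`: (level, region-code-within-level)."""
    c = np.asarray(code)
    return (c - 1) // 5 + 1, (c - 1) % 5 + 1


@dataclass(frozen=True)
class VertebraShape:
    """Primitive dimensions (mm) of one vertebra, relative to its spinous apex.

    y offsets are posterior-positive with the apex at ``sp_y_range[1]``;
    z offsets are symmetric about the apex plane.
    """

    sp_half_x: float = 2.5
    sp_y_range: tuple[float, float] = (4.0, 22.0)
    sp_half_z: float = 7.0
    lam_x_range: tuple[float, float] = (2.0, 10.0)
    lam_y_range: tuple[float, float] = (-6.0, 4.0)
    lam_half_z: float = 8.0
    ap_x: float = 8.0
    ap_y: float = 2.0
    ap_dz: float = 11.0
    ap_radius: float = 6.0
    tp_x_range: tuple[float, float] = (11.0, 30.0)
    tp_y: float = -28.0
    tp_half_y: float = 3.5
    tp_half_z: float = 5.0
    vb_y: float = -34.0
    vb_radius: float = 10.0
    vb_half_z: float = 15.0

    @property
    def apex_y(self) -> float:
        return self.sp_y_range[1]

    @property
    def half_z_extent(self) -> float:
        return max(self.ap_dz + self.ap_radius, self.vb_half_z, self.sp_half_z)


@dataclass(frozen=True)
class PhantomConfig:
    n_levels: int = 6
    inter_level_distances_mm: tuple[float, ...] = DEFAULT_GAPS_MM
    base_spacing_mm: float = 0.5
    shape: VertebraShape = field(default_factory=VertebraShape)
    fiducial_centers_mm: tuple[tuple[float, float, float], ...] | None = None
    fiducial_radius_mm: float = 5.0
    hu_bone: float = 1200.0
    hu_soft: float = 40.0
    hu_sphere: float = 3200.0
    probe_standoff_mm: float = 5.0  # probe face above the spinous apex
    margin_mm: float = 8.0
    ct_smoothing_mm: float = 0.4  # PSF emulation in the rendered CT
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_levels < 1:
            raise ValueError("need at least one vertebral level")
        gaps = tuple(float(g) for g in self.inter_level_distances_mm)
        if len(gaps) != self.n_levels - 1:
            raise ValueError(
                f"expected {self.n_levels - 1} inter-level distances, got {len(gaps)}"
            )
        if any(g <= 0 for g in gaps):
            raise ValueError("inter-level distances must be positive")
        object.__setattr__(self, "inter_level_distances_mm", gaps)
        if self.base_spacing_mm <= 0:
            raise ValueError("base spacing must be positive")
        if self.fiducial_centers_mm is not None and len(self.fiducial_centers_mm) != 4:
            raise ValueError("the study frame carries exactly 4 fiducial spheres")

    def apex_z_positions(self) -> np.ndarray:
        """z of each spinous apex, superior (L1) first, caudal end anchored."""
        z0 = self.margin_mm + self.shape.half_z_extent + self.fiducial_radius_mm * 2 + 12.0
        caudal_to_cranial = np.concatenate([[z0], z0 + np.cumsum(self.inter_level_distances_mm)])
        return caudal_to_cranial[::-1].copy()  # index 0 = most superior level (L1)

    def default_fiducials(self) -> np.ndarray:
        """Frame fiducials near the caudal end (where the DRO sits), non-coplanar."""
        s = self.shape
        zf = self.margin_mm + self.fiducial_radius_mm
        x = s.tp_x_range[1] + 2.0
        return np.array(
            [
                [x, 15.0, zf + 1.0],
                [-x, 15.0, zf],
                [x, -30.0, zf],
                [-x, -30.0, zf + 8.0],
            ]
        )


@dataclass
class SpinePhantom:
    """Labelled synthetic spine: labelmap + CT renderings + fiducials + landmarks."""

    labelmap: Volume
    ct_volumes: dict[float, Volume]
    landmarks: dict[int, PointSet]  # level -> 7 ordered landmarks (CT mm)
    fiducials: PointSet
    config: PhantomConfig

    @property
    def base_ct(self) -> Volume:
        return self.ct_volumes[self.config.base_spacing_mm]

    def apex_positions(self) -> np.ndarray:
        """(n_levels, 3) spinous apex coordinates, level 1 first."""
        z = self.config.apex_z_positions()
        y = self.config.shape.apex_y
        return np.column_stack([np.zeros_like(z), np.full_like(z, y), z])

    def level_centroid(self, level: int) -> np.ndarray:
        """Centroid (mm) of all labelled voxels of one level."""
        lev, _ = decode_label(self.labelmap.array)
        mask = (self.labelmap.array != 0) & (lev == level)
        if not mask.any():
            raise ValueError(f"level {level} absent from labelmap")
        idx = np.argwhere(mask)
        return self.labelmap.index_to_world(idx).mean(axis=0)

    def probe_plane_y(self) -> float:
        """y of the probe face during acquisition (above the spinous apices)."""
        return self.config.shape.apex_y + self.config.probe_standoff_mm

    # -- persistence -------------------------------------------------------
    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.labelmap.save(d / "labelmap.nii.gz")
        for spacing, vol in self.ct_volumes.items():
            vol.save(d / f"ct_{spacing:g}mm.nii.gz")
        rows = []
        for level, ps in self.landmarks.items():
            for name, p in zip(LANDMARK_NAMES, ps.points):
                rows.append({"level": level, "name": name, "x": p[0], "y": p[1], "z": p[2]})
        pd.DataFrame(rows).to_csv(d / "landmarks.csv", index=False)
        fid = pd.DataFrame(self.fiducials.points, columns=["x", "y", "z"])
        fid.insert(0, "name", [f"sphere_{i}" for i in range(len(fid))])
        fid.to_csv(d / "fiducials.csv", index=False)


def _build_level_masks(cfg: PhantomConfig, grids: tuple[np.ndarray, np.ndarray, np.ndarray],
                       apex_z: float) -> dict[str, np.ndarray]:
    """Boolean masks of the five regions of one vertebra on the full grid."""
    s = cfg.shape
    x, y, z = grids  # open mesh (nx,1,1), (1,ny,1), (1,1,nz) of world mm
    dz = z - apex_z
    ax = np.abs(x)

    sp = (ax <= s.sp_half_x) & (y >= s.sp_y_range[0]) & (y <= s.sp_y_range[1]) & (
        np.abs(dz) <= s.sp_half_z
    )
    lam = (
        (ax >= s.lam_x_range[0]) & (ax <= s.lam_x_range[1])
        & (y >= s.lam_y_range[0]) & (y <= s.lam_y_range[1])
        & (np.abs(dz) <= s.lam_half_z)
    )
    ap = np.zeros(np.broadcast_shapes(x.shape, y.shape, z.shape), dtype=bool)
    for sx in (-1.0, 1.0):
        for sz in (-1.0, 1.0):
            ap |= (
                (x - sx * s.ap_x) ** 2 + (y - s.ap_y) ** 2 + (dz - sz * s.ap_dz) ** 2
                <= s.ap_radius**2
            )
    tp = (
        (ax >= s.tp_x_range[0]) & (ax <= s.tp_x_range[1])
        & (np.abs(y - s.tp_y) <= s.tp_half_y) & (np.abs(dz) <= s.tp_half_z)
    )
    vb = ((y - s.vb_y) ** 2 + x**2 <= s.vb_radius**2) & (np.abs(dz) <= s.vb_half_z)
    # pedicles: bars joining the body to the articular masses, pooled into VB
    ped = (
        (ax >= 4.0) & (ax <= s.ap_x + 2.0)
        & (y >= s.vb_y) & (y <= s.lam_y_range[0])
        & (np.abs(dz) <= 5.0)
    )
    vb = vb | ped
    return {"SP": sp, "L": lam, "AP": ap, "TP": tp, "VB": vb}


def _level_landmarks(cfg: PhantomConfig, apex_z: float) -> np.ndarray:
    """Seven surface landmarks of one vertebra, in the canonical order."""
    s = cfg.shape
    lam_y = np.mean(s.lam_y_range)
    lam_x = np.mean(s.lam_x_range)
    tp_tip = s.tp_x_range[1] - 1.5
    return np.array(
        [
            [0.0, s.apex_y - 1.0, apex_z],
            [lam_x, lam_y, apex_z],
            [-lam_x, lam_y, apex_z],
            [s.ap_x, s.ap_y, apex_z + s.ap_dz],
            [-s.ap_x, s.ap_y, apex_z + s.ap_dz],
            [tp_tip, s.tp_y, apex_z],
            [-tp_tip, s.tp_y, apex_z],
        ]
    )


def generate_phantom(config: PhantomConfig | None = None) -> SpinePhantom:
    """Voxelize the spine phantom at the base spacing and render its CT.

    Deterministic for a given config (the seed only feeds the CT noise
    texture).  Raises if vertebra primitives of different levels would
    overlap — a sign of an inconsistent gap/shape configuration.
    """
    cfg = config or PhantomConfig()
    s = cfg.shape
    sp = cfg.base_spacing_mm
    apex_z = cfg.apex_z_positions()

    fiducials = (
        np.asarray(cfg.fiducial_centers_mm, float)
        if cfg.fiducial_centers_mm is not None
        else cfg.default_fiducials()
    )

    m = cfg.margin_mm
    xmax = max(s.tp_x_range[1], np.abs(fiducials[:, 0]).max() + cfg.fiducial_radius_mm) + m
    ymin = min(s.vb_y - s.vb_radius, fiducials[:, 1].min() - cfg.fiducial_radius_mm) - m
    ymax = cfg.shape.apex_y + cfg.probe_standoff_mm + 10.0
    zmax = apex_z[0] + s.half_z_extent + m
    origin = np.array([-xmax, ymin, 0.0])
    shape = tuple(int(np.ceil(d / sp)) for d in (2 * xmax, ymax - ymin, zmax))

    labels = np.zeros(shape, dtype=np.int16)
    xs = origin[0] + sp * np.arange(shape[0])
    ys = origin[1] + sp * np.arange(shape[1])
    zs = origin[2] + sp * np.arange(shape[2])

    landmarks: dict[int, PointSet] = {}
    for level in range(1, cfg.n_levels + 1):
        az = apex_z[level - 1]
        # restrict voxel work to the slab this vertebra can occupy
        z_lo = np.searchsorted(zs, az - s.half_z_extent - sp)
        z_hi = np.searchsorted(zs, az + s.half_z_extent + sp)
        grids = (
            xs[:, None, None],
            ys[None, :, None],
            zs[None, None, z_lo:z_hi][:, None, :].reshape(1, 1, -1),
        )
        masks = _build_level_masks(cfg, grids, az)
        slab = labels[:, :, z_lo:z_hi]
        for region in ("VB", "TP", "AP", "L", "SP"):  # posterior regions win ties
            mask = masks[region]
            if np.any(slab[mask] != 0):
                clash = np.unique(slab[mask][slab[mask] != 0])
                lev_clash = np.unique(decode_label(clash)[0])
                if np.any(lev_clash != level):
                    raise ValueError(
                        f"vertebra primitives of level {level} overlap level(s) "
                        f"{[int(v) for v in lev_clash if v != level]}"
                    )
            slab[mask] = region_code(level, region)
        landmarks[level] = PointSet(_level_landmarks(cfg, az), frame="CT")

    labelmap = Volume(labels, np.full(3, sp), origin)

    # CT rendering: soft tissue + bone + bright fiducial spheres, mild PSF blur
    ct = np.full(shape, cfg.hu_soft, dtype=np.float32)
    ct[labels != 0] = cfg.hu_bone
    for c in fiducials:
        lo = np.maximum(
            ((c - cfg.fiducial_radius_mm - origin) / sp).astype(int) - 1, 0
        )
        hi = np.minimum(
            ((c + cfg.fiducial_radius_mm - origin) / sp).astype(int) + 2, shape
        )
        gx = xs[lo[0]:hi[0], None, None]
        gy = ys[None, lo[1]:hi[1], None]
        gz = zs[None, None, lo[2]:hi[2]]
        ball = (gx - c[0]) ** 2 + (gy - c[1]) ** 2 + (gz - c[2]) ** 2 <= cfg.fiducial_radius_mm**2
        ct[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]][ball] = cfg.hu_sphere
    if cfg.ct_smoothing_mm > 0:
        ndimage.gaussian_filter(ct, sigma=cfg.ct_smoothing_mm / sp, output=ct)
    rng = np.random.default_rng(cfg.seed)
    ct += rng.normal(0.0, 8.0, size=shape).astype(np.float32)

    phantom = SpinePhantom(
        labelmap=labelmap,
        ct_volumes={sp: Volume(ct, np.full(3, sp), origin)},
        landmarks=landmarks,
        fiducials=PointSet(fiducials, frame="CT"),
        config=cfg,
    )
    _validate_landmarks(phantom)
    return phantom


def _validate_landmarks(phantom: SpinePhantom) -> None:
    """Every landmark must lie within one voxel of its own level's labels."""
    lm = phantom.labelmap
    for level, ps in phantom.landmarks.items():
        labs = lm.sample_nearest_labels(ps.points)
        lev, _ = decode_label(labs)
        bad = (labs == 0) | (lev != level)
        if np.any(bad):
            # tolerate voxel-rounding: search the 3^3 neighborhood
            idx = np.rint(lm.world_to_index(ps.points[bad])).astype(int)
            for i in idx:
                neigh = lm.array[
                    max(i[0] - 1, 0): i[0] + 2,
                    max(i[1] - 1, 0): i[1] + 2,
                    max(i[2] - 1, 0): i[2] + 2,
                ]
                lv = decode_label(neigh[neigh != 0])[0] if np.any(neigh != 0) else []
                if level not in lv:
                    raise ValueError(
                        f"landmark of level {level} at {i} is not on that level's surface"
                    )


def resample_ct(phantom: SpinePhantom, spacing_mm: float) -> Volume:
    """Resample the base CT onto an isotropic grid of coarser spacing.

    Linear interpolation; the new grid shares the base origin and covers
    the same physical extent.  The result is cached on the phantom.
    """
    if spacing_mm <= 0:
        raise ValueError("spacing must be positive")
    base = phantom.base_ct
    if spacing_mm < phantom.config.base_spacing_mm - 1e-12:
        raise ValueError("cannot resample below the base spacing")
    if spacing_mm in phantom.ct_volumes:
        return phantom.ct_volumes[spacing_mm]
    if abs(spacing_mm - phantom.config.base_spacing_mm) < 1e-12:
        return base

    extent = np.array(base.shape) * base.spacing
    new_shape = np.maximum(np.floor(extent / spacing_mm).astype(int), 1)
    scale = spacing_mm / base.spacing
    coords = [
        (np.arange(n) * scale[i]) for i, n in enumerate(new_shape)
    ]
    grid = np.meshgrid(*coords, indexing="ij")
    out = ndimage.map_coordinates(
        base.array.astype(np.float32), np.array(grid), order=1, mode="nearest"
    )
    vol = Volume(out.astype(np.float32), np.full(3, float(spacing_mm)), base.origin)
    phantom.ct_volumes[float(spacing_mm)] = vol
    return vol


def resample_labelmap(phantom: SpinePhantom, spacing_mm: float) -> Volume:
    """Nearest-neighbor resample of the labelmap onto a coarser grid.

    Used to derive the CT surface at each reconstruction resolution; the
    grid matches :func:`resample_ct` at the same spacing.
    """
    if spacing_mm <= 0:
        raise ValueError("spacing must be positive")
    base = phantom.labelmap
    if spacing_mm < phantom.config.base_spacing_mm - 1e-12:
        raise ValueError("cannot resample below the base spacing")
    if abs(spacing_mm - phantom.config.base_spacing_mm) < 1e-12:
        return base
    extent = np.array(base.shape) * base.spacing
    new_shape = np.maximum(np.floor(extent / spacing_mm).astype(int), 1)
    idx = [np.rint(np.arange(n) * spacing_mm / base.spacing[i]).astype(int)
           for i, n in enumerate(new_shape)]
    idx = [np.clip(a, 0, base.shape[i] - 1) for i, a in enumerate(idx)]
    out = base.array[np.ix_(idx[0], idx[1], idx[2])]
    return Volume(out, np.full(3, float(spacing_mm)), base.origin)
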