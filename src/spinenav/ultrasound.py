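"""Tracked freehand ultrasound sweep simulation over the spine phantom.

A sweep emulates the study's acquisition protocol: the linear probe
(14 mm contact width) rests a few millimetres above the spinous apex,
oriented antero-posteriorly, and travels caudo-cranially across one
vertebral level.  Each frame is an axial B-mode-like image: image rows
run along the beam (depth) axis, columns along the probe's lateral axis.

Image formation is deliberately simple — straight rays per column, a
Gaussian-profile hyperechoic response at the first bone voxel, acoustic
shadow below it, and seeded speckle elsewhere.  Frequency narrows the
echo and increases depth attenuation; depth changes the imaged range and
row spacing, never the 14 mm field width.  No refraction, no transverse
wave component, no soft-tissue layering.

Randomness is split per sweep into two independent streams (pose jitter
vs. speckle texture) derived from one sweep seed, so acquisition-pose
variability and image texture can be controlled separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import raycast
from .geometry import RigidTransform, compose, invert
from .phantom import SpinePhantom
from .volume import Volume

__all__ = [
    "SweepConfig",
    "TrackedFrame",
    "TrackedSweep",
    "plan_sweep_poses",
    "simulate_frame",
    "simulate_sweep",
]

STUDY_DEPTHS_CM = (5, 7)
STUDY_FREQUENCIES_MHZ = (6, 12)


@dataclass(frozen=True)
class SweepConfig:
    """Acquisition settings for one sweep (the study grid restricts
    depth to 5/7 cm and frequency to 6/12 MHz)."""

    depth_cm: float = 5.0
    frequency_mhz: float = 12.0
    n_frames: int = 24
    frame_width_mm: float = 14.0
    n_cols: int = 64
    n_rows: int = 128
    sweep_span_mm: float = 40.0
    # pose jitter (per-repetition variability of the operator)
    tilt_jitter_deg: float = 2.0
    lateral_jitter_mm: float = 1.0
    frame_wobble_deg: float = 0.15
    speed_jitter: float = 0.3
    # image formation
    echo_amplitude: float = 0.95
    echo_sigma_scale_mm_mhz: float = 4.8  # sigma_mm = scale / frequency
    attenuation_per_mm_mhz: float = 0.0006
    speckle_mean: float = 0.07
    speckle_std: float = 0.03
    speckle_ceiling: float = 0.25
    shadow_residual: float = 0.05
    ray_step_mm: float = 0.25
    seed: int = 0
    pose_seed: int | None = None  # override the derived pose stream
    speckle_seed: int | None = None

    def __post_init__(self) -> None:
        if self.depth_cm not in STUDY_DEPTHS_CM:
            raise ValueError(f"depth must be one of {STUDY_DEPTHS_CM} cm")
        if self.frequency_mhz not in STUDY_FREQUENCIES_MHZ:
            raise ValueError(f"frequency must be one of {STUDY_FREQUENCIES_MHZ} MHz")
        if min(self.tilt_jitter_deg, self.lateral_jitter_mm, self.frame_wobble_deg,
               self.speed_jitter) < 0:
            raise ValueError("jitter magnitudes must be non-negative")
        if self.n_frames < 1 or self.n_cols < 1 or self.n_rows < 1:
            raise ValueError("frame counts and image dimensions must be positive")

    @property
    def depth_mm(self) -> float:
        return 10.0 * self.depth_cm

    @property
    def pixel_spacing_mm(self) -> tuple[float, float]:
        """(row spacing along depth, column spacing along width)."""
        return self.depth_mm / self.n_rows, self.frame_width_mm / self.n_cols

    @property
    def echo_sigma_mm(self) -> float:
        return self.echo_sigma_scale_mm_mhz / self.frequency_mhz

    def column_positions_mm(self) -> np.ndarray:
        """Lateral pixel-center offsets u_j from the probe center."""
        _, pu = self.pixel_spacing_mm
        return -self.frame_width_mm / 2 + (np.arange(self.n_cols) + 0.5) * pu

    def row_depths_mm(self) -> np.ndarray:
        """Depth v_r of each row's pixel center below the probe face."""
        pv, _ = self.pixel_spacing_mm
        return (np.arange(self.n_rows) + 0.5) * pv

    def derived_seeds(self) -> tuple[int, int]:
        pose, speckle = (int(x) for x in np.random.SeedSequence(self.seed).generate_state(2))
        p = self.pose_seed if self.pose_seed is not None else pose
        s = self.speckle_seed if self.speckle_seed is not None else speckle
        return p, s


@dataclass
class TrackedFrame:
    """One ultrasound frame with its tracked pose.

    ``pose`` maps in-frame mm coordinates (lateral offset u, depth v, 0)
    to the reference (DRO) space, probe calibration already folded in.
    """

    image: np.ndarray  # (n_rows, n_cols) in [0, 1]
    pose: RigidTransform

    def __post_init__(self) -> None:
        img = np.asarray(self.image, dtype=np.float32)
        if img.ndim != 2:
            raise ValueError("frame image must be 2D")
        if img.size and (img.min() < -1e-6 or img.max() > 1 + 1e-6):
            raise ValueError("frame intensities must lie in [0, 1]")
        self.image = img


@dataclass
class TrackedSweep:
    """Ordered caudo-cranial frames over one vertebral level."""

    frames: list[TrackedFrame]
    config: SweepConfig
    level: int

    def __len__(self) -> int:
        return len(self.frames)

    def frame_origins_reference(self) -> np.ndarray:
        return np.array([f.pose.translation for f in self.frames])

    # -- persistence -------------------------------------------------------
    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        stack = np.stack([f.image for f in self.frames], axis=-1)
        pv, pu = self.config.pixel_spacing_mm
        Volume(stack, np.array([pv, pu, 1.0]), np.zeros(3)).save(d / "frames.nii.gz")
        rows = [
            {"frame_index": i, **{f"m{k}": v for k, v in enumerate(f.pose.matrix.ravel())}}
            for i, f in enumerate(self.frames)
        ]
        pd.DataFrame(rows).to_csv(d / "poses.csv", index=False)
        meta = {
            "level": int(self.level),
            "depth_cm": float(self.config.depth_cm),
            "frequency_mhz": float(self.config.frequency_mhz),
            "n_frames": int(self.config.n_frames),
            "seed": int(self.config.seed),
        }
        (d / "sweep.yaml").write_text(yaml.safe_dump(meta))

    @staticmethod
    def load(directory: str | Path, config: SweepConfig | None = None) -> "TrackedSweep":
        d = Path(directory)
        meta = yaml.safe_load((d / "sweep.yaml").read_text())
        cfg = config or SweepConfig(
            depth_cm=meta["depth_cm"],
            frequency_mhz=meta["frequency_mhz"],
            n_frames=meta["n_frames"],
            seed=meta["seed"],
        )
        stack = Volume.load(d / "frames.nii.gz").array
        poses = pd.read_csv(d / "poses.csv").sort_values("frame_index")
        frames = [
            TrackedFrame(
                stack[:, :, i],
                RigidTransform(np.array(row[[f"m{k}" for k in range(16)]], float).reshape(4, 4)),
            )
            for i, (_, row) in enumerate(poses.iterrows())
        ]
        return TrackedSweep(frames=frames, config=cfg, level=int(meta["level"]))


def _probe_rotation(tilt_deg: float) -> np.ndarray:
    """Image-axes → CT rotation: lateral → +x, depth → −y, tilted about z."""
    c, s = np.cos(np.radians(tilt_deg)), np.sin(np.radians(tilt_deg))
    lateral = np.array([c, s, 0.0])
    depth = np.array([s, -c, 0.0])
    normal = np.cross(lateral, depth)
    return np.column_stack([lateral, depth, normal])


def plan_sweep_poses(
    phantom: SpinePhantom, level: int, config: SweepConfig
) -> list[RigidTransform]:
    """Caudo-cranial probe poses over one level, in CT space (image → CT).

    The probe face sits at the standoff plane above the spinous apices,
    centered laterally on the spine; frame z positions progress strictly
    from the inferior to the superior aspect of the level.  Pose jitter
    (a per-repetition left-right tilt, lateral offset, per-frame wobble
    and speed variation) is drawn from the config's pose stream.
    """
    if not 1 <= level <= phantom.config.n_levels:
        raise ValueError(f"level {level} out of range 1..{phantom.config.n_levels}")
    pose_seed, _ = config.derived_seeds()
    rng = np.random.default_rng(pose_seed)

    apex = phantom.apex_positions()[level - 1]
    y0 = phantom.probe_plane_y()
    n = config.n_frames
    half = config.sweep_span_mm / 2

    if n == 1:
        z_pos = np.array([apex[2]])
    else:
        inc = 1.0 + config.speed_jitter * rng.uniform(-1.0, 1.0, size=n - 1)
        z_pos = np.concatenate([[0.0], np.cumsum(inc)])
        z_pos = apex[2] - half + z_pos / z_pos[-1] * (2 * half)

    tilt = rng.normal(0.0, config.tilt_jitter_deg)
    x_off = rng.normal(0.0, config.lateral_jitter_mm)
    wobble = rng.normal(0.0, config.frame_wobble_deg, size=n)
    drift = rng.normal(0.0, 0.1 * config.lateral_jitter_mm, size=n)
    if config.tilt_jitter_deg == 0:
        tilt, wobble = 0.0, np.zeros(n)
    if config.lateral_jitter_mm == 0:
        x_off, drift = 0.0, np.zeros(n)

    poses = []
    for i in range(n):
        rot = _probe_rotation(tilt + wobble[i])
        origin = np.array([apex[0] + x_off + drift[i], y0, z_pos[i]])
        poses.append(RigidTransform.from_rotation_translation(rot, origin))
    return poses


def simulate_frame(
    pose_ct: RigidTransform,
    phantom: SpinePhantom,
    config: SweepConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one frame for a probe pose given in CT space.

    Per image column a ray is cast along the depth axis; the first
    bone-labelled voxel produces a Gaussian echo whose width shrinks with
    frequency and whose amplitude decays with depth x frequency; pixels
    beyond the interface are shadowed; everything else is speckle.
    Returns the (n_rows, n_cols) image in [0, 1].
    """
    if rng is None:
        _, speckle_seed = config.derived_seeds()
        rng = np.random.default_rng(speckle_seed)
    u = config.column_positions_mm()
    v = config.row_depths_mm()
    lateral = pose_ct.rotation[:, 0]
    depth_dir = pose_ct.rotation[:, 1]
    origins = pose_ct.translation[None, :] + u[:, None] * lateral[None, :]
    hits = raycast.first_hit(
        phantom.labelmap, origins, depth_dir[None, :], config.ray_step_mm, config.depth_mm
    )

    img = np.abs(rng.normal(config.speckle_mean, config.speckle_std,
                            size=(config.n_rows, config.n_cols)))
    np.clip(img, 0.0, config.speckle_ceiling, out=img)

    sigma = config.echo_sigma_mm
    for j in np.nonzero(hits.hit)[0]:
        d = hits.distance_mm[j]
        amp = config.echo_amplitude * np.exp(
            -config.attenuation_per_mm_mhz * config.frequency_mhz * d
        )
        echo = amp * np.exp(-0.5 * ((v - d) / sigma) ** 2)
        col = img[:, j]
        col[v > d + sigma] *= config.shadow_residual
        img[:, j] = col + echo
    return np.clip(img, 0.0, 1.0).astype(np.float32)


def simulate_sweep(
    phantom: SpinePhantom,
    level: int,
    config: SweepConfig,
    reference_to_ct: RigidTransform | None = None,
) -> TrackedSweep:
    """Plan poses and render frames for one acquisition.

    ``reference_to_ct`` is the (ground-truth) transform between the DRO
    reference space and CT space; stored frame poses are expressed in the
    reference space, as a tracker would report them.  Deterministic for a
    given config seed.
    """
    t_gt = reference_to_ct or RigidTransform.identity()
    ct_to_ref = invert(t_gt)
    poses_ct = plan_sweep_poses(phantom, level, config)
    _, speckle_seed = config.derived_seeds()
    rng = np.random.default_rng(speckle_seed)
    frames = [
        TrackedFrame(simulate_frame(p, phantom, config, rng), compose(ct_to_ref, p))
        for p in poses_ct
    ]
    return TrackedSweep(frames=frames, config=config, level=level)
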