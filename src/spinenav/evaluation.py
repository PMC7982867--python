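"""Accuracy and robustness metrics for navigated alignments.

Target registration error (TRE) is the RMS Euclidean distance at the
seven per-vertebra surface landmarks between an evaluated alignment and
the ground-truth alignment.  An alignment is a *success* when its TRE is
strictly below 2 mm (the clinical threshold for spinal navigation), a
*level mismatch* when TRE ≥ 10 mm (registration latched onto the wrong
vertebra), and a *failure* in between.  Error propagation across levels
is summarized as a matrix of median TREs (acquisition level × measured
level) and regressed against inter-spinous distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import PointSet, RigidTransform
from .volume import Volume

__all__ = [
    "EvaluationConfig",
    "TREResult",
    "PropagationMatrix",
    "DistanceFit",
    "IntensityProfile",
    "compute_tre",
    "classify_alignment",
    "summarize_rates",
    "propagation_matrix",
    "cumulative_level_distances",
    "fit_tre_vs_distance",
    "intensity_profile",
    "sample_sweep_profile",
    "profile_ensemble_stats",
    "CLASS_SUCCESS",
    "CLASS_FAILURE",
    "CLASS_MISMATCH",
]

CLASS_SUCCESS = "success"
CLASS_FAILURE = "failure"
CLASS_MISMATCH = "level_mismatch"


@dataclass(frozen=True)
class EvaluationConfig:
    """Classification thresholds (mm).  Success is strict (< 2 mm,
    'below 2 mm'); mismatch is tre ≥ 10 mm (the negative mismatch
    response is 'lower than 10 mm')."""

    success_threshold_mm: float = 2.0
    mismatch_threshold_mm: float = 10.0

    def __post_init__(self) -> None:
        if not 0 < self.success_threshold_mm < self.mismatch_threshold_mm:
            raise ValueError("need 0 < success threshold < mismatch threshold")


@dataclass
class TREResult:
    """Per-acquisition outcome: RMS TRE at every measured level plus the
    classification at the acquisition's own level."""

    level: int
    depth_cm: float
    frequency_mhz: float
    repetition: int
    resolution_mm: float
    tre_by_level: dict[int, float]
    classification: str = field(init=False)
    converged: bool = True

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.tre_by_level.values()):
            raise ValueError("TRE values must be non-negative")
        self.classification = classify_alignment(self.own_tre, EvaluationConfig())

    @property
    def own_tre(self) -> float:
        return self.tre_by_level[self.level]


@dataclass
class PropagationMatrix:
    """cells[i, j] = median TRE measured at level j over acquisitions at
    level i (both 1-based levels in ``levels``)."""

    levels: list[int]
    cells: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.levels)
        if self.cells.shape != (n, n):
            raise ValueError("propagation matrix must be square over the levels")
        if np.any(self.cells < 0):
            raise ValueError("median TREs must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        names = [f"L{l}" for l in self.levels]
        return pd.DataFrame(self.cells, index=names, columns=names)


@dataclass
class DistanceFit:
    slope: float  # mm TRE per mm of inter-level distance
    intercept: float  # mm
    residual_rms: float
    n: int


@dataclass
class IntensityProfile:
    positions_mm: np.ndarray  # distance along the segment, strictly increasing
    values: np.ndarray
    iqr: np.ndarray | None = None  # Q3 - Q1 per position, for ensembles

    def __post_init__(self) -> None:
        if np.any(np.diff(self.positions_mm) <= 0):
            raise ValueError("profile positions must be strictly increasing")
        if self.iqr is not None and np.any(self.iqr < 0):
            raise ValueError("IQR must be non-negative")


def compute_tre(
    t_est: RigidTransform, t_gt: RigidTransform, landmarks: PointSet | np.ndarray
) -> float:
    """RMS over landmarks of ‖t_est(x) − t_gt(x)‖ in mm.

    With landmarks expressed in the reference space and both transforms
    mapping reference→CT, this is the displacement of the CT landmarks
    under the evaluated alignment relative to ground truth.
    """
    pts = landmarks.points if isinstance(landmarks, PointSet) else np.atleast_2d(landmarks)
    if len(pts) == 0:
        raise ValueError("landmark set is empty")
    d = t_est.apply_points(pts) - t_gt.apply_points(pts)
    return float(np.sqrt(np.mean(np.sum(d**2, axis=1))))


def classify_alignment(tre_mm: float, config: EvaluationConfig | None = None) -> str:
    """Map a TRE to success / failure / level_mismatch (partitions [0, inf))."""
    cfg = config or EvaluationConfig()
    if tre_mm < 0 or not np.isfinite(tre_mm):
        raise ValueError(f"TRE must be finite and non-negative, got {tre_mm}")
    if tre_mm < cfg.success_threshold_mm:
        return CLASS_SUCCESS
    if tre_mm >= cfg.mismatch_threshold_mm:
        return CLASS_MISMATCH
    return CLASS_FAILURE


def _quantiles(x: np.ndarray) -> tuple[float, float]:
    """Median and IQR with the linear-interpolation quantile definition."""
    q1, q2, q3 = np.quantile(x, [0.25, 0.5, 0.75], method="linear")
    return float(q2), float(q3 - q1)


def summarize_rates(
    results: list[TREResult], strata: tuple[str, ...] = ("resolution", "depth_frequency")
) -> pd.DataFrame:
    """Stratified robustness/accuracy table (percentages on the 0–100 scale).

    One row per stratum value: n, success %, failure %, mismatch %, median
    TRE and IQR at the acquisition's own level.  All acquisitions are
    pooled within each stratum; rounding happens only at presentation.
    """
    if not results:
        raise ValueError("no results to summarize")
    df = pd.DataFrame(
        {
            "level": r.level,
            "depth_cm": r.depth_cm,
            "frequency_mhz": r.frequency_mhz,
            "resolution_mm": r.resolution_mm,
            "tre_mm": r.own_tre,
            "classification": r.classification,
        }
        for r in results
    )
    keymap = {
        "resolution": ["resolution_mm"],
        "depth_frequency": ["depth_cm", "frequency_mhz"],
        "level": ["level"],
    }
    rows = []
    for stratum in strata:
        for key, grp in df.groupby(keymap[stratum]):
            med, iqr = _quantiles(grp["tre_mm"].to_numpy())
            n = len(grp)
            rows.append(
                {
                    "stratum": stratum,
                    "value": key if len(keymap[stratum]) > 1 else key[0],
                    "n": n,
                    "success_pct": 100.0 * (grp["classification"] == CLASS_SUCCESS).sum() / n,
                    "failure_pct": 100.0 * (grp["classification"] == CLASS_FAILURE).sum() / n,
                    "mismatch_pct": 100.0 * (grp["classification"] == CLASS_MISMATCH).sum() / n,
                    "median_tre_mm": med,
                    "iqr_mm": iqr,
                }
            )
    return pd.DataFrame(rows)


def propagation_matrix(results: list[TREResult]) -> PropagationMatrix:
    """Median TRE per (acquisition level, measured level) cell."""
    if not results:
        raise ValueError("no results")
    levels = sorted({r.level for r in results})
    for r in results:
        missing = [l for l in levels if l not in r.tre_by_level]
        if missing:
            raise ValueError(f"acquisition at level {r.level} lacks TRE at levels {missing}")
    cells = np.zeros((len(levels), len(levels)))
    for i, li in enumerate(levels):
        at_i = [r for r in results if r.level == li]
        for j, lj in enumerate(levels):
            cells[i, j] = np.median([r.tre_by_level[lj] for r in at_i])
    return PropagationMatrix(levels=levels, cells=cells)


def cumulative_level_distances(gaps_mm: list[float] | np.ndarray) -> np.ndarray:
    """Pairwise inter-level distance table from successive spinous gaps.

    ``gaps_mm`` lists the n−1 successive inter-spinous distances; the
    returned (n, n) table has distance(i, j) = sum of the gaps between
    levels i and j (symmetric, zero diagonal).
    """
    gaps = np.asarray(gaps_mm, float)
    if np.any(gaps <= 0):
        raise ValueError("inter-level gaps must be positive")
    pos = np.concatenate([[0.0], np.cumsum(gaps)])
    return np.abs(pos[:, None] - pos[None, :])


def fit_tre_vs_distance(matrix: PropagationMatrix, distances: np.ndarray) -> DistanceFit:
    """Ordinary least squares of propagation-matrix cells on distance.

    Regresses every cell's median TRE on the distance between the
    acquisition level and the measured level; returns slope (mm/mm),
    intercept (mm) and residual RMS.
    """
    d = np.asarray(distances, float)
    n = len(matrix.levels)
    if d.shape != (n, n):
        raise ValueError("distance table must match the propagation matrix levels")
    x = d.ravel()
    y = matrix.cells.ravel()
    if np.ptp(x) < 1e-12:
        raise ValueError("degenerate regression: all distances identical")
    design = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return DistanceFit(
        slope=float(coef[0]),
        intercept=float(coef[1]),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        n=len(x),
    )


def intensity_profile(
    volume: Volume, p0, p1, n_samples: int = 100
) -> IntensityProfile:
    """Trilinear intensity samples at n equally spaced points on a segment."""
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    if np.linalg.norm(p1 - p0) < 1e-12:
        raise ValueError("degenerate segment: endpoints coincide")
    t = np.linspace(0.0, 1.0, n_samples)
    pts = p0[None, :] + t[:, None] * (p1 - p0)[None, :]
    if not (volume.contains(pts[:1])[0] and volume.contains(pts[-1:])[0]):
        raise ValueError("profile segment extends outside the volume")
    vals = volume.sample_linear(pts)
    return IntensityProfile(positions_mm=t * np.linalg.norm(p1 - p0), values=vals)


def sample_sweep_profile(
    sweep, reference_to_ct: RigidTransform, p0, p1, n_samples: int = 100
) -> IntensityProfile:
    """Ultrasound intensity along a fixed CT-space segment for one sweep.

    Each sample point is mapped into every frame's image plane through the
    ground-truth alignment and the tracked pose; the frame with the
    smallest out-of-plane offset supplies the value (bilinear in-plane
    interpolation, zero outside the imaged field).  This lets the same
    anatomical line — e.g. one crossing a lamina into the cavity — be
    compared across acquisitions.
    """
    from scipy.ndimage import map_coordinates

    from .geometry import compose, invert

    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    seg = p1 - p0
    if np.linalg.norm(seg) < 1e-12:
        raise ValueError("degenerate segment: endpoints coincide")
    t = np.linspace(0.0, 1.0, n_samples)
    pts_ct = p0[None, :] + t[:, None] * seg[None, :]

    cfg = sweep.config
    pv, pu = cfg.pixel_spacing_mm
    n_rows, n_cols = cfg.n_rows, cfg.n_cols
    best_w = np.full(n_samples, np.inf)
    values = np.zeros(n_samples)
    for frame in sweep.frames:
        to_image = invert(compose(reference_to_ct, frame.pose))
        local = to_image.apply_points(pts_ct)  # (u, v, w) frame mm
        rows = local[:, 1] / pv - 0.5
        cols = (local[:, 0] + cfg.frame_width_mm / 2) / pu - 0.5
        inside = (rows > -0.5) & (rows < n_rows - 0.5) & (cols > -0.5) & (
            cols < n_cols - 0.5
        )
        w = np.abs(local[:, 2])
        better = inside & (w < best_w)
        if better.any():
            vals = map_coordinates(
                frame.image.astype(float),
                [rows[better], cols[better]], order=1, mode="constant",
            )
            values[better] = vals
            best_w[better] = w[better]
    return IntensityProfile(positions_mm=t * np.linalg.norm(seg), values=values)


def profile_ensemble_stats(profiles: list[IntensityProfile]) -> IntensityProfile:
    """Per-position median and interquartile range across acquisitions."""
    if not profiles:
        raise ValueError("empty profile ensemble")
    pos = profiles[0].positions_mm
    for p in profiles[1:]:
        if p.values.shape != profiles[0].values.shape or not np.allclose(
            p.positions_mm, pos
        ):
            raise ValueError("profiles are on mismatched sampling grids")
    stack = np.array([p.values for p in profiles])
    q1, q2, q3 = np.quantile(stack, [0.25, 0.5, 0.75], axis=0, method="linear")
    return IntensityProfile(positions_mm=pos.copy(), values=q2, iqr=q3 - q1)
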