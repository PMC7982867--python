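"""Rigid-body transforms and closed-form landmark registration.

All coordinates are in millimetres in a right-handed LPS anatomical
convention (+x left, +y posterior, +z superior).  A :class:`RigidTransform`
is a 4x4 homogeneous matrix whose rotation block is orthonormal with
determinant +1; transforms map points from one coordinate space (e.g. the
tracked reference space defined by the dynamic reference object) to another
(e.g. CT image space).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "RigidTransform",
    "PointSet",
    "compose",
    "invert",
    "apply_transform",
    "fit_rigid_landmarks",
    "perturb_transform",
    "rotation_about_axis",
    "DegenerateConfigurationError",
]

_ORTHO_TOL = 1e-9


class DegenerateConfigurationError(ValueError):
    """Raised when a landmark configuration cannot determine a rigid fit."""


@dataclass(frozen=True)
class RigidTransform:
    """A 4x4 homogeneous rigid-body map (rotation + translation, mm).

    The constructor validates rigidity: the 3x3 rotation block must be
    orthonormal with determinant +1 (tolerance 1e-9) and the last row must
    be exactly ``(0, 0, 0, 1)``.
    """

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError(f"expected a 4x4 matrix, got shape {m.shape}")
        if not np.all(np.isfinite(m)):
            raise ValueError("transform matrix contains non-finite entries")
        if not np.array_equal(m[3], [0.0, 0.0, 0.0, 1.0]):
            raise ValueError("last row of a rigid transform must be (0,0,0,1)")
        r = m[:3, :3]
        if not np.allclose(r.T @ r, np.eye(3), atol=_ORTHO_TOL):
            raise ValueError("rotation block is not orthonormal")
        if np.linalg.det(r) < 0:
            raise ValueError("rotation block has determinant -1 (reflection)")
        object.__setattr__(self, "matrix", m)
        m.flags.writeable = False

    # -- constructors ------------------------------------------------------
    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(4))

    @staticmethod
    def from_rotation_translation(
        rotation: np.ndarray, translation: Sequence[float]
    ) -> "RigidTransform":
        m = np.eye(4)
        m[:3, :3] = rotation
        m[:3, 3] = translation
        return RigidTransform(m)

    @staticmethod
    def from_translation(translation: Sequence[float]) -> "RigidTransform":
        return RigidTransform.from_rotation_translation(np.eye(3), translation)

    # -- accessors ---------------------------------------------------------
    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    def apply_points(self, points: np.ndarray) -> np.ndarray:
        """Map an (n, 3) array of points through the transform."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.rotation.T + self.translation

    def rotation_angle_deg(self) -> float:
        """Rotation magnitude in degrees (angle of the axis-angle form)."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))

    # -- serialization -----------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Write as a plain-text 4x4 row-major matrix, one row per line."""
        np.savetxt(path, self.matrix, fmt="%.17g")

    @staticmethod
    def load(path: str | Path) -> "RigidTransform":
        m = np.loadtxt(path)
        return RigidTransform(m)  # validation happens in the constructor


@dataclass
class PointSet:
    """Ordered 3D points (mm) tagged with the coordinate space they live in.

    Order is semantically meaningful: landmark registration pairs the i-th
    moving point with the i-th fixed point.
    """

    points: np.ndarray
    frame: str = "CT"

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"points must be (n, 3), got {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise ValueError("point coordinates must be finite")
        self.points = pts

    def __len__(self) -> int:
        return len(self.points)


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """Transform mapping x -> a(b(x))."""
    return RigidTransform(a.matrix @ b.matrix)


def invert(t: RigidTransform) -> RigidTransform:
    r = t.rotation.T
    return RigidTransform.from_rotation_translation(r, -r @ t.translation)


def apply_transform(
    t: RigidTransform, p: PointSet, expected_frame: str | None = None, out_frame: str | None = None
) -> PointSet:
    """Map a point set through ``t``; optionally enforce its coordinate space."""
    if expected_frame is not None and p.frame != expected_frame:
        raise ValueError(f"point set is in frame {p.frame!r}, expected {expected_frame!r}")
    return PointSet(t.apply_points(p.points), frame=out_frame or p.frame)


def rotation_about_axis(angle_deg: float, axis: Sequence[float]) -> np.ndarray:
    """Rodrigues rotation matrix for an angle (degrees) about a unit axis."""
    ax = np.asarray(axis, dtype=float)
    n = np.linalg.norm(ax)
    if n < 1e-12:
        raise ValueError("rotation axis has zero norm")
    ax = ax / n
    th = np.radians(angle_deg)
    k = np.array(
        [[0, -ax[2], ax[1]], [ax[2], 0, -ax[0]], [-ax[1], ax[0], 0]]
    )
    return np.eye(3) + np.sin(th) * k + (1 - np.cos(th)) * (k @ k)


def perturb_transform(
    t: RigidTransform,
    angle_deg: float,
    axis: Sequence[float],
    translation_mm: Sequence[float],
    pivot: Sequence[float],
) -> RigidTransform:
    """Compose a rotation about ``pivot`` plus a translation with ``t``.

    The perturbation acts in the output space of ``t``: the result maps
    x -> R (t(x) - pivot) + pivot + translation.  Used to inject controlled
    misalignments (e.g. a pure angular ground-truth error) for lever-arm
    analyses.
    """
    r = rotation_about_axis(angle_deg, axis)
    pv = np.asarray(pivot, dtype=float)
    delta = RigidTransform.from_rotation_translation(
        r, pv - r @ pv + np.asarray(translation_mm, dtype=float)
    )
    return compose(delta, t)


def fit_rigid_landmarks(
    moving: PointSet | np.ndarray, fixed: PointSet | np.ndarray
) -> tuple[RigidTransform, float]:
    """Least-squares rigid fit of paired landmarks (Horn's problem, via SVD).

    Returns the rigid transform mapping ``moving`` onto ``fixed`` together
    with the fiducial registration error (FRE), the RMS of the residual
    norms in mm.  The reflection case (det = -1 of the SVD rotation) is
    corrected by flipping the sign of the smallest singular vector.

    Raises
    ------
    DegenerateConfigurationError
        For fewer than 3 point pairs or a collinear configuration.
    """
    mv = moving.points if isinstance(moving, PointSet) else np.atleast_2d(np.asarray(moving, float))
    fx = fixed.points if isinstance(fixed, PointSet) else np.atleast_2d(np.asarray(fixed, float))
    if mv.shape != fx.shape:
        raise ValueError(f"point sets differ in shape: {mv.shape} vs {fx.shape}")
    n = len(mv)
    if n < 3:
        raise DegenerateConfigurationError(f"need at least 3 point pairs, got {n}")

    mc, fc = mv.mean(axis=0), fx.mean(axis=0)
    a, b = mv - mc, fx - fc
    # collinearity check: second singular value of the centred moving set
    sv = np.linalg.svd(a, compute_uv=False)
    if sv[1] <= 1e-9 * max(sv[0], 1.0):
        raise DegenerateConfigurationError("landmarks are collinear")

    h = a.T @ b
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    s = np.diag([1.0, 1.0, d])
    r = vt.T @ s @ u.T
    t = fc - r @ mc
    transform = RigidTransform.from_rotation_translation(r, t)
    residuals = transform.apply_points(mv) - fx
    fre = float(np.sqrt(np.mean(np.sum(residuals**2, axis=1))))
    return transform, fre
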