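"""Vectorized first-hit ray marching through a label volume.

Both the ultrasound image formation model and the acquisition-coverage
metric reduce to the same primitive: march a bundle of parallel-ish rays
through the labelmap with a fixed step and report, per ray, the first
voxel carrying a non-background label.  Rays model straight longitudinal
ultrasound propagation along image columns; there is no refraction and no
penetration past the first bone voxel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import Volume

__all__ = ["RayHits", "first_hit"]


@dataclass
class RayHits:
    """Per-ray first-hit result. ``hit`` masks rays that struck a label."""

    hit: np.ndarray  # (n,) bool
    distance_mm: np.ndarray  # (n,) float; NaN where no hit
    voxel_index: np.ndarray  # (n, 3) int; -1 rows where no hit
    label: np.ndarray  # (n,) label value at the hit voxel; 0 where no hit


def first_hit(
    labels: Volume,
    origins: np.ndarray,
    directions: np.ndarray,
    step_mm: float,
    max_distance_mm: float,
) -> RayHits:
    """March rays from ``origins`` along unit ``directions``.

    Sampling positions are ``origin + (k + 0.5) * step * direction`` for
    k = 0, 1, ...; the first sample whose nearest voxel is labelled wins.
    ``step_mm`` must not exceed half the smallest voxel spacing so that no
    voxel along the ray can be stepped over.
    """
    if step_mm <= 0:
        raise ValueError("step_mm must be positive")
    if step_mm > float(np.min(labels.spacing)) / 2 + 1e-12:
        raise ValueError(
            f"step_mm={step_mm} exceeds half the minimum voxel spacing "
            f"({float(np.min(labels.spacing)) / 2} mm)"
        )
    origins = np.atleast_2d(np.asarray(origins, float))
    directions = np.atleast_2d(np.asarray(directions, float))
    if directions.shape[0] == 1 and origins.shape[0] > 1:
        directions = np.broadcast_to(directions, origins.shape)
    n = origins.shape[0]
    n_steps = int(np.ceil(max_distance_mm / step_mm))
    t = (np.arange(n_steps) + 0.5) * step_mm  # sample at step midpoints

    # (n, n_steps, 3) sample positions; memory ~ n*n_steps*24 bytes
    pos = origins[:, None, :] + t[None, :, None] * directions[:, None, :]
    idx = np.rint((pos - labels.origin) / labels.spacing).astype(np.int64)
    shape = np.array(labels.shape)
    inside = np.all((idx >= 0) & (idx < shape), axis=2)
    flat = np.zeros((n, n_steps), dtype=labels.array.dtype)
    ii = idx[inside]
    flat[inside] = labels.array[ii[:, 0], ii[:, 1], ii[:, 2]]

    labelled = flat != 0
    any_hit = labelled.any(axis=1)
    first = np.where(any_hit, labelled.argmax(axis=1), 0)

    dist = np.full(n, np.nan)
    vox = np.full((n, 3), -1, dtype=np.int64)
    lab = np.zeros(n, dtype=labels.array.dtype)
    rows = np.arange(n)[any_hit]
    dist[any_hit] = t[first[any_hit]]
    vox[any_hit] = idx[rows, first[any_hit]]
    lab[any_hit] = flat[rows, first[any_hit]]
    return RayHits(hit=any_hit, distance_mm=dist, voxel_index=vox, label=lab)
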