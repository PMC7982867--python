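import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from spinenav.geometry import PointSet, RigidTransform, rotation_about_axis
from spinenav.phantom import PhantomConfig, SpinePhantom, generate_phantom
from spinenav.volume import Volume


def random_rigid(rng: np.random.Generator, max_angle_deg: float = 180.0,
                 max_translation_mm: float = 50.0) -> RigidTransform:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(-max_angle_deg, max_angle_deg)
    t = rng.uniform(-max_translation_mm, max_translation_mm, size=3)
    return RigidTransform.from_rotation_translation(rotation_about_axis(angle, axis), t)


@pytest.fixture(scope="session")
def study_phantom() -> SpinePhantom:
    """The default six-level phantom used by the full-study tests."""
    return generate_phantom(PhantomConfig())


@pytest.fixture(scope="session")
def small_phantom() -> SpinePhantom:
    """A coarse three-level phantom for fast unit tests."""
    return generate_phantom(
        PhantomConfig(n_levels=3, inter_level_distances_mm=(40.0, 38.0),
                      base_spacing_mm=1.0)
    )


def slab_phantom(y_surface_mm: float = -10.0, thickness_mm: float = 4.0,
                 spacing: float = 1.0, label: int = 2) -> SpinePhantom:
    """A flat bone slab at constant y, wide in x/z, for beam-geometry tests.

    The slab's posterior surface plane passes through the voxel centers at
    ``y_surface_mm``.  The returned object reuses the SpinePhantom container
    but carries no meaningful landmarks or fiducials (synthetic stand-in
    scene, not a spine).
    """
    shape = (60, 80, 60)
    origin = np.array([-30.0, -50.0, -30.0])
    labels = np.zeros(shape, dtype=np.int16)
    ys = origin[1] + spacing * np.arange(shape[1])
    sel = (ys <= y_surface_mm) & (ys > y_surface_mm - thickness_mm)
    labels[:, sel, :] = label
    vol = Volume(labels, np.full(3, spacing), origin)
    cfg = PhantomConfig(n_levels=1, inter_level_distances_mm=(), base_spacing_mm=spacing)
    ct = Volume(np.where(labels > 0, cfg.hu_bone, cfg.hu_soft).astype(np.float32),
                np.full(3, spacing), origin)
    return SpinePhantom(labelmap=vol, ct_volumes={spacing: ct}, landmarks={},
                        fiducials=PointSet(np.zeros((4, 3))), config=cfg)
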