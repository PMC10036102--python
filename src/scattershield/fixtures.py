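"""Synthetic-data generators: analytic test scenes, noisy calibration sets
and scaled-down operating-room scenes.

Every fixture is reproducible from (name, parameters, seed) alone and logs
the parameters it resolved into its manifest.  The scaled OR scenes shrink
only the room (air-grid) extent; the clinically meaningful distances -- SSD,
SID, field size, shield placement, staff stance, ROI heights -- stay at full
scale so shielding ratios remain comparable to the full-size room.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, replace

import numpy as np

from .scene import (SceneConfig, ShieldSpec, SourceGeometry, StaffPhantom,
                    VoxelScene)

MAX_SCALED_VOXELS = 2_000_000


@dataclass(frozen=True)
class FixtureSpec:
    """Name + parameters + seed identifying one synthetic fixture."""

    name: str
    parameters: dict
    seed: int | None = None

    def manifest(self) -> str:
        return json.dumps({"fixture": self.name, "seed": self.seed,
                           "parameters": self.parameters}, sort_keys=True)


@dataclass(frozen=True)
class IsotropicSource:
    """Bare point source emitting uniformly over 4 pi (for oracle scenes)."""

    position: np.ndarray

    @property
    def solid_angle_sr(self) -> float:
        return 4 * math.pi

    def sample_directions(self, rng: np.random.Generator, n: int) -> np.ndarray:
        w = 2 * rng.random(n) - 1
        phi = 2 * math.pi * rng.random(n)
        s = np.sqrt(1 - w ** 2)
        return np.column_stack([s * np.cos(phi), s * np.sin(phi), w])


def make_slab_scene(material: str, thickness_cm: float, spacing_cm: float = 0.5,
                    lateral_m: float = 0.8, gap_m: float = 0.3,
                    pencil: bool = True):
    """A single slab normal to +z in vacuum with an axial beam.

    Returns (VoxelScene, SourceGeometry, FixtureSpec).  The slab spans
    ``[gap, gap + thickness)`` in z; the source sits on the axis at z = 0
    aiming up.  With ``pencil`` the collimation is a 1 mm field, otherwise
    the clinical 156.5 mm field.
    """
    if thickness_cm < 0:
        raise ValueError("thickness must be >= 0")
    sp = spacing_cm / 100.0
    t = thickness_cm / 100.0
    if t > 0:
        # snap the pitch so the voxelized slab is exactly the requested
        # thickness; otherwise transmission oracles see a rounded slab
        n_slab = max(1, round(t / sp))
        sp = t / n_slab
    lz = gap_m + t + gap_m
    dims = (max(int(math.ceil(lateral_m / sp)), 1),
            max(int(math.ceil(lateral_m / sp)), 1),
            max(int(math.ceil(lz / sp)), 1))
    scene = VoxelScene(origin=np.array([-lateral_m / 2, -lateral_m / 2, 0.0]),
                       spacing=np.array([sp, sp, sp]),
                       materials=np.zeros(dims, dtype=np.uint8),
                       registry=[("vacuum", 0.0)])
    if t > 0:
        mid = scene.material_id(material)
        zc = scene.voxel_centers(2)
        in_slab = (zc >= gap_m) & (zc < gap_m + t)
        scene.materials[:, :, in_slab] = mid
    src = SourceGeometry(position=np.array([0.0, 0.0, 1e-6]),
                         axis=np.array([0.0, 0.0, 1.0]),
                         sid_m=lz, field_side_m=(0.001 if pencil else 0.1565))
    spec = FixtureSpec("slab_scene", {
        "material": material, "thickness_cm": thickness_cm,
        "spacing_cm": spacing_cm, "pencil": pencil, "gap_m": gap_m})
    return scene, src, spec


def make_air_box(side_m: float = 2.0, spacing_m: float = 0.05,
                 density_g_cm3: float = 1.205e-9):
    """An air cube with an isotropic source at its centre.

    The default density is a near-vacuum trace of air: track-length kerma
    scoring uses the mass coefficient, so the kerma map is unchanged, while
    attenuation and scatter buildup become negligible -- the configuration
    the point-source 1/r^2 oracle assumes.  Pass the real air density for a
    physically attenuating box.
    """
    n = int(round(side_m / spacing_m))
    scene = VoxelScene(origin=np.array([0.0, 0.0, 0.0]),
                       spacing=np.array([spacing_m] * 3),
                       materials=np.zeros((n, n, n), dtype=np.uint8),
                       registry=[("air", density_g_cm3)])
    src = IsotropicSource(position=np.array([side_m / 2] * 3))
    return scene, src, FixtureSpec("air_box", {"side_m": side_m,
                                               "spacing_m": spacing_m,
                                               "density_g_cm3": density_g_cm3})


def make_noisy_calibration(true_slope: float = 1.10, cv: float = 0.05,
                           seed: int = 0, x: np.ndarray | None = None):
    """Paired (simulated, measured) doses emulating the 12-condition design.

    ``x`` defaults to canned positive doses following inverse-square falloff
    with SSD and near-exponential decline with depth over the design grid;
    ``y = true_slope * x * (1 + eps)`` with eps ~ N(0, cv).  Returns
    (x, y, FixtureSpec).
    """
    if true_slope <= 0:
        raise ValueError("true_slope must be positive")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    from .calibration import generate_conditions

    conditions = generate_conditions()
    if x is None:
        x = np.array([(60.0 / c.ssd_cm) ** 2 * math.exp(-c.depth_cm / 5.0)
                      for c in conditions])
    rng = np.random.default_rng(seed)
    y = true_slope * x * (1 + cv * rng.standard_normal(len(x)))
    spec = FixtureSpec("noisy_calibration",
                       {"true_slope": true_slope, "cv": cv, "n": len(x)},
                       seed=seed)
    return np.asarray(x, dtype=float), y, spec


def make_scaled_or_scene(scale: float = 0.5, spacing_cm: float | None = None,
                         **config_overrides):
    """Scaled-down operating-room scene configuration for desk-size runs.

    The room extent is multiplied by ``scale`` in x and y (heights stay
    full-scale so ROI bands keep their clinical meaning) and the voxel pitch
    is coarsened, by default to the smallest pitch keeping the scene at or
    under two million voxels.  Returns (SceneConfig, spacing_m, FixtureSpec).
    """
    if not 0.25 <= scale <= 1.0:
        raise ValueError("scale must be within [0.25, 1]")
    base = SceneConfig()
    room = (base.room_size_m[0] * scale, base.room_size_m[1] * scale,
            base.room_size_m[2])
    cfg = replace(base, room_size_m=room, **config_overrides)
    if spacing_cm is None:
        volume = room[0] * room[1] * room[2]
        spacing_m = (volume / MAX_SCALED_VOXELS) ** (1 / 3)
        spacing_m = math.ceil(spacing_m * 400) / 400  # round up to 2.5 mm steps
    else:
        spacing_m = spacing_cm / 100.0
        if math.prod(int(math.ceil(d / spacing_m)) for d in room) > MAX_SCALED_VOXELS:
            raise ValueError("requested spacing exceeds the voxel budget")
    spec = FixtureSpec("scaled_or_scene", {
        "scale": scale, "spacing_m": spacing_m, "room_size_m": list(room),
        "full_scale_distances": ["ssd", "sid", "field", "shield", "stance",
                                 "roi_heights"],
        "overrides": {k: repr(v) for k, v in config_overrides.items()}})
    return cfg, spacing_m, spec
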