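"""Voxelized operating-room scenes.

Coordinate convention: right-handed, z up, z = 0 at the finished floor;
heights in configuration values are centimetres from the floor, all internal
geometry is in metres.  The patient lies supine along +y with the head toward
+y; the patient's right side is -x.  Voxel intervals are half-open
``[origin + i*s, origin + (i+1)*s)`` and solids are rasterised by
voxel-centre sampling with the priority order

    shield > staff phantom > patient > table > floor/walls > air.

The shield is a thin vertical panel beyond the patient's head plane.  Because
its physical thickness (1 mm lead) is below any practical voxel pitch, shield
voxels carry a density-homogenised lead entry that preserves areal density
along the panel normal.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .materials import Material, get_material

PATTERNS = ("absent", "large", "small", "none_aperture")

#: aperture height bands (cm from floor): (echo side, anesthesia side)
APERTURE_BANDS_CM = {
    "large": ((100.0, 140.0), (90.0, 130.0)),
    "small": ((105.0, 125.0), (95.0, 115.0)),
}
#: default aperture widths per side (cm)
APERTURE_WIDTHS_CM = {"large": 35.0, "small": 25.0}

PROJECTIONS = {
    "PA": (0.0, 0.0),
    "cusp_overlap": (9.0, -1.0),      # RAO 9, caudal 1
    "perpendicular": (-16.0, 13.0),   # LAO 16, cranial 13
}


@dataclass(frozen=True)
class ShieldSpec:
    """Perforated-shield geometry: pattern plus panel and aperture layout."""

    pattern: str = "absent"
    thickness_mm: float = 1.0
    material: str = "lead"
    panel_width_m: float = 1.0
    panel_height_m: float = 1.8
    floor_offset_m: float = 0.0
    #: lateral centre of each aperture, measured from the panel centre (m);
    #: echo side is the patient's right (-x), anesthesia side +x
    aperture_offset_m: float = 0.25

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(f"pattern must be one of {PATTERNS}")
        if self.thickness_mm <= 0:
            raise ValueError("shield thickness must be positive")

    def aperture_rects(self) -> list[tuple[float, float, float, float]]:
        """(x_lo, x_hi, z_lo, z_hi) rectangles in panel coordinates, metres.

        x is lateral offset from the panel centre, z is height from floor.
        """
        if self.pattern not in APERTURE_BANDS_CM:
            return []
        (echo_band, anes_band) = APERTURE_BANDS_CM[self.pattern]
        w = APERTURE_WIDTHS_CM[self.pattern] / 100.0
        rects = []
        for band, x_c in ((echo_band, -self.aperture_offset_m),
                          (anes_band, +self.aperture_offset_m)):
            z_lo, z_hi = band[0] / 100.0, band[1] / 100.0
            rect = (x_c - w / 2, x_c + w / 2, z_lo, z_hi)
            if rect[0] < -self.panel_width_m / 2 or rect[1] > self.panel_width_m / 2 \
                    or z_lo < self.floor_offset_m \
                    or z_hi > self.floor_offset_m + self.panel_height_m:
                raise ValueError("aperture lies outside the shield panel")
            rects.append(rect)
        return rects


@dataclass(frozen=True)
class StaffPhantom:
    """Stylized standing adult phantom (stacked elliptical segments)."""

    height_cm: float = 160.8
    stance_deg: float = 45.0
    #: standing position of the body axis (m, room frame)
    position_xy: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not 140.0 <= self.height_cm <= 200.0:
            raise ValueError("staff height must be within [140, 200] cm")


#: ROI height bands in cm from the floor for the default 160.8 cm phantom;
#: bands scale linearly with phantom height.
ROI_BANDS_CM = {
    "lens": (145.0, 150.0),
    "neck": (130.0, 135.0),
    "chest": (110.0, 120.0),
    "waist": (80.0, 85.0),
}
REFERENCE_HEIGHT_CM = 160.8


@dataclass(frozen=True)
class SceneConfig:
    """Full description of one operating-room simulation scene."""

    #: outer dimensions of the concrete box; the 20 cm walls lie inside it,
    #: so the air interior is smaller by twice the wall thickness per axis
    room_size_m: tuple[float, float, float] = (8.1, 7.3, 3.4)
    wall_thickness_m: float = 0.20
    #: with walls the scene is the full concrete room (air-dose-map
    #: geometry); without, only the concrete floor remains and the sides and
    #: ceiling are open air (the staff-exposure geometry, where wall
    #: backscatter plays no role)
    include_walls: bool = True
    table_height_m: float = 1.00
    table_size_m: tuple[float, float] = (0.50, 2.20)  # width (x), length (y)
    table_slab_m: float = 0.02
    table_density: float = 0.30  # carbon-fibre-like water-equivalent slab
    ssd_m: float = 0.60
    sid_m: float = 1.00
    field_side_m: float = 0.1565  # square field at the receptor plane
    projection: str | tuple[float, float] = "PA"
    shield: ShieldSpec = field(default_factory=ShieldSpec)
    #: gap between the patient's head plane and the shield panel (m)
    shield_gap_m: float = 0.30
    staff: StaffPhantom | None = field(default_factory=StaffPhantom)
    patient_height_cm: float = 170.0
    include_patient: bool = True

    def __post_init__(self) -> None:
        if self.ssd_m >= self.sid_m:
            raise ValueError("SSD must be smaller than SID")
        if self.field_side_m <= 0:
            raise ValueError("field side must be positive")

    # ---- derived geometry (m, room frame) ------------------------------
    @property
    def interior_size_m(self) -> tuple[float, float, float]:
        wt = self.wall_thickness_m
        return tuple(d - 2 * wt for d in self.room_size_m)

    @property
    def room_center_xy(self) -> tuple[float, float]:
        lx, ly, _ = self.interior_size_m
        return lx / 2, ly / 2

    @property
    def table_top_z(self) -> float:
        return self.table_height_m

    @property
    def patient_trunk_half_depth(self) -> float:
        return 0.10

    @property
    def patient_entrance_z(self) -> float:
        """Posterior (table-side) surface of the supine patient."""
        return self.table_top_z + self.table_slab_m

    @property
    def isocenter(self) -> np.ndarray:
        cx, cy = self.room_center_xy
        z = self.patient_entrance_z + self.patient_trunk_half_depth
        return np.array([cx, cy, z])

    @property
    def head_plane_y(self) -> float:
        """y of the cranial end of the patient."""
        cy = self.room_center_xy[1]
        return cy + 0.30 + 0.26 + 0.24  # trunk half + neck/shoulder + head

    @property
    def shield_plane_y(self) -> float:
        return self.head_plane_y + self.shield_gap_m


@dataclass
class VoxelScene:
    """Material-indexed voxel grid plus registry of (material, density)."""

    origin: np.ndarray          # m, lower corner of voxel (0,0,0)
    spacing: np.ndarray         # m per axis
    materials: np.ndarray       # uint8, shape (nx, ny, nz)
    registry: list[tuple[str, float]]  # index -> (material name, density g/cm3)
    config: SceneConfig | None = None
    roi_set: "ROISet | None" = None

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive")
        if self.materials.max() >= len(self.registry):
            raise ValueError("material index outside registry")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.materials.shape

    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.spacing) * 1e6)

    def voxel_centers(self, axis: int) -> np.ndarray:
        n = self.materials.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing[axis]

    def material_id(self, name: str, density: float | None = None) -> int:
        """Index of (name, density) in the registry, appending if new."""
        if density is None:
            density = get_material(name).density
        for i, (n, d) in enumerate(self.registry):
            if n == name and abs(d - density) < 1e-12:
                return i
        self.registry.append((name, density))
        if len(self.registry) > 255:
            raise ValueError("too many scene materials")
        return len(self.registry) - 1

    def densities_g_cm3(self) -> np.ndarray:
        return np.array([d for _, d in self.registry])

    def voxel_mass_g(self) -> np.ndarray:
        """Per-voxel mass (g), same shape as ``materials``."""
        return self.densities_g_cm3()[self.materials] * self.voxel_volume_cm3()

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(self.origin.tobytes())
        h.update(self.spacing.tobytes())
        h.update(np.ascontiguousarray(self.materials).tobytes())
        h.update(repr(self.registry).encode())
        return h.hexdigest()[:16]

    def to_nrrd(self, path) -> None:
        """Export the material grid for inspection (requires SimpleITK)."""
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.ascontiguousarray(
            self.materials.transpose(2, 1, 0)))
        img.SetSpacing(tuple(self.spacing))
        img.SetOrigin(tuple(self.origin))
        sitk.WriteImage(img, str(path))


@dataclass(frozen=True)
class SourceGeometry:
    """Point source with ideal rectangular collimation."""

    position: np.ndarray     # m
    axis: np.ndarray         # unit central-axis direction
    sid_m: float
    field_side_m: float      # square field side at the receptor plane

    @property
    def solid_angle_sr(self) -> float:
        """Solid angle of the collimated square field."""
        a = self.field_side_m / 2 / self.sid_m
        # exact solid angle of a square pyramid of half-tangent a
        return 4 * math.asin(a * a / (1 + a * a))

    def basis(self) -> tuple[np.ndarray, np.ndarray]:
        """In-plane orthonormal basis of the receptor plane."""
        ref = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(ref, self.axis)) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        u = np.cross(self.axis, ref)
        u /= np.linalg.norm(u)
        v = np.cross(self.axis, u)
        return u, v

    def sample_directions(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Unit directions uniformly covering the receptor square."""
        u, v = self.basis()
        a = (rng.random(n) - 0.5) * self.field_side_m
        b = (rng.random(n) - 0.5) * self.field_side_m
        pts = (self.position[None, :] + self.sid_m * self.axis[None, :]
               + a[:, None] * u[None, :] + b[:, None] * v[None, :])
        d = pts - self.position[None, :]
        return d / np.linalg.norm(d, axis=1, keepdims=True)


def projection_angles(projection) -> tuple[float, float]:
    """Resolve a named projection or explicit (rao_lao, cra_cau) pair."""
    if isinstance(projection, str):
        try:
            return PROJECTIONS[projection]
        except KeyError:
            raise ValueError(
                f"unknown projection {projection!r}; valid: {sorted(PROJECTIONS)}")
    rao_lao, cra_cau = projection
    return float(rao_lao), float(cra_cau)


def set_projection(config: SceneConfig,
                   projection=None) -> SourceGeometry:
    """Place the undertable source for a named or explicit angulation.

    The central axis starts at +z (PA, tube facing straight up), is rotated
    by the RAO/LAO angle about the patient's longitudinal axis (y), then by
    the CRA/CAU angle about the lateral axis (x).  RAO > 0 swings the
    receptor toward the patient's right (-x); CRA > 0 toward the head (+y).
    The source sits on the rotated axis at fixed distance from the isocenter,
    chosen so the PA source-to-surface distance equals the configured SSD.
    """
    rao_lao, cra_cau = projection_angles(
        config.projection if projection is None else projection)
    if abs(rao_lao) > 45 or abs(cra_cau) > 45:
        raise ValueError("angulations beyond +/-45 degrees are unsupported")
    # axis = Rx(cra_cau) @ Ry(-rao_lao) @ ez ; minus sign maps RAO>0 to -x
    c1, s1 = math.cos(math.radians(rao_lao)), math.sin(math.radians(rao_lao))
    ry = np.array([[c1, 0, -s1], [0, 1, 0], [s1, 0, c1]])
    c2, s2 = math.cos(math.radians(cra_cau)), math.sin(math.radians(cra_cau))
    rx = np.array([[1, 0, 0], [0, c2, s2], [0, -s2, c2]])  # CRA>0 tilts axis to +y
    axis = rx @ ry @ np.array([0.0, 0.0, 1.0])
    axis /= np.linalg.norm(axis)
    iso = config.isocenter
    r_iso = config.ssd_m + config.patient_trunk_half_depth
    return SourceGeometry(position=iso - r_iso * axis, axis=axis,
                          sid_m=config.sid_m, field_side_m=config.field_side_m)


# --------------------------------------------------------------------------
# rasterisation helpers


def _grid_axes(origin, spacing, dims):
    return [origin[i] + (np.arange(dims[i]) + 0.5) * spacing[i] for i in range(3)]


def build_shield(spec: ShieldSpec, config: SceneConfig,
                 origin, spacing, dims) -> np.ndarray:
    """Boolean occupancy of shield voxels on the given grid."""
    occ = np.zeros(dims, dtype=bool)
    if spec.pattern == "absent":
        return occ
    xs, ys, zs = _grid_axes(origin, spacing, dims)
    cx = config.room_center_xy[0]
    y0 = config.shield_plane_y
    # panel occupies the single voxel layer containing the panel plane
    j = np.searchsorted(ys - spacing[1] / 2, y0) - 1
    if j < 0 or j >= dims[1]:
        raise ValueError("shield plane outside the scene grid")
    in_x = np.abs(xs - cx) <= spec.panel_width_m / 2
    in_z = (zs >= spec.floor_offset_m) & (zs <= spec.floor_offset_m + spec.panel_height_m)
    occ[np.ix_(in_x, [j], in_z)] = True
    for (x_lo, x_hi, z_lo, z_hi) in spec.aperture_rects():
        hole_x = (xs - cx >= x_lo) & (xs - cx <= x_hi)
        hole_z = (zs >= z_lo) & (zs < z_hi)
        occ[np.ix_(hole_x, [j], hole_z)] = False
    return occ


def _elliptic_cylinder_mask(xs, ys, zs, center_xy, half_axes_xy, z_range,
                            angle_deg=0.0):
    """Vertical elliptical cylinder, optionally rotated about its own axis."""
    x = xs[:, None] - center_xy[0]
    y = ys[None, :] - center_xy[1]
    if angle_deg:
        c, s = math.cos(math.radians(angle_deg)), math.sin(math.radians(angle_deg))
        x, y = c * x + s * y, -s * x + c * y
    r2 = (x / half_axes_xy[0]) ** 2 + (y / half_axes_xy[1]) ** 2
    in_xy = r2 <= 1.0
    in_z = (zs >= z_range[0]) & (zs < z_range[1])
    return in_xy[:, :, None] & in_z[None, None, :]


def build_staff_phantom(config: SceneConfig, origin, spacing, dims):
    """Rasterise the standing staff phantom; returns (mask dict, ROISet).

    The body is water with a one-voxel skin shell, concentric bone cores and
    eye-lens patches on the face side.  ROI bands scale linearly with height.
    """
    staff = config.staff
    xs, ys, zs = _grid_axes(origin, spacing, dims)
    f = staff.height_cm / REFERENCE_HEIGHT_CM
    h = staff.height_cm / 100.0

    if staff.position_xy is not None:
        px, py = staff.position_xy
    else:
        px = config.room_center_xy[0] + 0.20
        py = config.shield_plane_y + 0.35

    ang = staff.stance_deg
    # anthropometric landmarks for the 160.8 cm reference: acromion ~81% of
    # stature (1.30 m), chin ~87% (1.40 m), so the 130-135 cm band falls on
    # the neck and 145-150 cm on the face
    segments = [  # (half_axes (m), z_lo, z_hi) at reference height, scaled
        ((0.16, 0.10), 0.00, 0.80),    # legs / pelvis block
        ((0.16, 0.11), 0.80, 1.30),    # trunk to the shoulder line
        ((0.055, 0.055), 1.30, 1.40),  # neck
        ((0.080, 0.100), 1.40, 1.608),  # head
    ]
    body = np.zeros(dims, dtype=bool)
    core = np.zeros(dims, dtype=bool)
    for (ax_, ay_), z_lo, z_hi in segments:
        body |= _elliptic_cylinder_mask(
            xs, ys, zs, (px, py), (ax_ * f, ay_ * f), (z_lo * f, z_hi * f), ang)
        core |= _elliptic_cylinder_mask(
            xs, ys, zs, (px, py), (0.35 * ax_ * f, 0.35 * ay_ * f),
            (z_lo * f, z_hi * f), ang)

    # one-voxel skin shell = body voxels with a non-body 6-neighbour
    interior = body.copy()
    for axis in range(3):
        interior &= np.roll(body, 1, axis=axis) & np.roll(body, -1, axis=axis)
    skin = body & ~interior
    bone = core & interior

    # lens patches: two skin patches on the face side at the lens band
    lens_band = tuple(b / 100.0 * f for b in ROI_BANDS_CM["lens"])
    c, s = math.cos(math.radians(ang)), math.sin(math.radians(ang))
    face_dir = np.array([-s, -c, 0.0])  # unrotated phantom faces the patient (-y)
    lateral = np.array([c, -s, 0.0])
    lens = np.zeros(dims, dtype=bool)
    in_band = (zs >= lens_band[0]) & (zs < lens_band[1])
    if in_band.any():
        dx = xs[:, None] - px
        dy = ys[None, :] - py
        frontness = dx * face_dir[0] + dy * face_dir[1]
        lat = dx * lateral[0] + dy * lateral[1]
        eye_xy = (frontness > 0) & (np.abs(np.abs(lat) - 0.032 * f) < 0.018 * f)
        lens = skin & eye_xy[:, :, None] & in_band[None, None, :]

    rois = build_roi_set(skin, lens, xs, ys, zs, (px, py), ang, f)
    return {"body": body, "skin": skin, "bone": bone, "lens": lens}, rois


@dataclass(frozen=True)
class ROISet:
    """Named boolean masks of surface voxels on the staff phantom."""

    masks: dict[str, np.ndarray]

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def names(self) -> list[str]:
        return list(self.masks)


def build_roi_set(skin, lens, xs, ys, zs, center_xy, stance_deg, height_factor):
    """Surface-band ROIs, split left/right by the phantom's sagittal plane.

    Every ROI is the full ring of surface voxels (skin shell plus the
    eye-lens patches) whose centres fall in the named height band; the lens
    band at 145-150 cm covers the eye level of the reference-height phantom.
    """
    c, s = math.cos(math.radians(stance_deg)), math.sin(math.radians(stance_deg))
    lateral = np.array([c, -s])  # phantom left direction in room frame
    dx = xs[:, None] - center_xy[0]
    dy = ys[None, :] - center_xy[1]
    side = dx * lateral[0] + dy * lateral[1]
    left_xy = side > 0
    surface = skin | lens
    masks: dict[str, np.ndarray] = {}
    for name, (lo_cm, hi_cm) in ROI_BANDS_CM.items():
        lo, hi = lo_cm / 100.0 * height_factor, hi_cm / 100.0 * height_factor
        in_band = (zs >= lo) & (zs < hi)
        band_mask = surface & in_band[None, None, :]
        if name in ("lens", "chest"):
            masks[f"{name}_left"] = band_mask & left_xy[:, :, None]
            masks[f"{name}_right"] = band_mask & ~left_xy[:, :, None]
        else:
            masks[name] = band_mask
    return ROISet(masks)


def _build_patient(config: SceneConfig, xs, ys, zs):
    """Supine stylized patient: water body, skin shell, spine core."""
    cx, cy = config.room_center_xy
    z0 = config.patient_entrance_z
    hf = config.patient_height_cm / 170.0
    body = np.zeros((len(xs), len(ys), len(zs)), dtype=bool)

    def horizontal_cylinder(half_x, half_z, y_lo, y_hi, z_center):
        x = (xs[:, None, None] - cx) / half_x
        z = (zs[None, None, :] - z_center) / half_z
        in_y = (ys >= y_lo) & (ys < y_hi)
        return (x ** 2 + z ** 2 <= 1.0) & in_y[None, :, None]

    trunk_half_depth = config.patient_trunk_half_depth
    z_c = z0 + trunk_half_depth
    body |= horizontal_cylinder(0.17, trunk_half_depth, cy - 0.30 * hf,
                                cy + 0.30 * hf, z_c)
    body |= horizontal_cylinder(0.06, 0.06, cy + 0.30 * hf, cy + 0.56 * hf, z0 + 0.08)
    body |= horizontal_cylinder(0.08, 0.09, cy + 0.56 * hf, cy + 0.80 * hf, z0 + 0.09)
    body |= horizontal_cylinder(0.15, 0.08, cy - 0.95 * hf, cy - 0.30 * hf, z0 + 0.08)

    interior = body.copy()
    for axis in range(3):
        interior &= np.roll(body, 1, axis=axis) & np.roll(body, -1, axis=axis)
    skin = body & ~interior
    spine = horizontal_cylinder(0.02, 0.02, cy - 0.30 * hf, cy + 0.56 * hf,
                                z0 + 0.035) & interior
    return body, skin, spine


def build_room_scene(config: SceneConfig, spacing_m: float) -> VoxelScene:
    """Rasterise the full scene at uniform ``spacing_m``.

    Deterministic for a given config: air interior, 20 cm concrete shell,
    table slab, supine patient, optional staff phantom and shield.
    """
    sp = np.array([spacing_m] * 3)
    wt = config.wall_thickness_m
    lx, ly, lz = config.interior_size_m
    origin = np.array([-wt, -wt, -wt])
    dims = tuple(int(math.ceil(d / spacing_m)) for d in config.room_size_m)
    scene = VoxelScene(origin=origin, spacing=sp,
                       materials=np.zeros(dims, dtype=np.uint8),
                       registry=[("air", get_material("air").density)],
                       config=config)
    xs, ys, zs = _grid_axes(origin, sp, dims)

    # concrete shell: full room, or floor slab only for the open
    # staff-exposure geometry
    concrete = scene.material_id("concrete")
    if config.include_walls:
        outside = ((xs[:, None, None] < 0) | (xs[:, None, None] >= lx)
                   | (ys[None, :, None] < 0) | (ys[None, :, None] >= ly)
                   | (zs[None, None, :] < 0) | (zs[None, None, :] >= lz))
        scene.materials[outside] = concrete
    else:
        scene.materials[:, :, zs < 0] = concrete

    # table slab; thinner than the voxel pitch it is homogenised into the
    # single layer containing it, preserving areal density
    cx, cy = config.room_center_xy
    tw, tl = config.table_size_m
    in_x = np.abs(xs - cx) <= tw / 2
    in_y = np.abs(ys - cy) <= tl / 2
    if config.table_slab_m >= spacing_m:
        rho_t = config.table_density
        in_z = (zs >= config.table_height_m) & (zs < config.table_height_m + config.table_slab_m)
    else:
        rho_t = config.table_density * config.table_slab_m / spacing_m
        k = int((config.table_height_m + config.table_slab_m / 2 - origin[2]) // spacing_m)
        in_z = np.zeros(dims[2], dtype=bool)
        in_z[k] = True
    table = scene.material_id("water", rho_t)
    scene.materials[np.ix_(in_x, in_y, in_z)] = table

    if config.include_patient:
        water = scene.material_id("water")
        skin_id = scene.material_id("skin")
        bone_id = scene.material_id("bone")
        body, skin, spine = _build_patient(config, xs, ys, zs)
        scene.materials[body] = water
        scene.materials[skin] = skin_id
        scene.materials[spine] = bone_id

    rois = None
    if config.staff is not None:
        water = scene.material_id("water")
        skin_id = scene.material_id("skin")
        bone_id = scene.material_id("bone")
        lens_id = scene.material_id("eye_lens")
        masks, rois = build_staff_phantom(config, origin, sp, dims)
        scene.materials[masks["body"]] = water
        scene.materials[masks["skin"]] = skin_id
        scene.materials[masks["bone"]] = bone_id
        scene.materials[masks["lens"]] = lens_id

    shield_occ = build_shield(config.shield, config, origin, sp, dims)
    if shield_occ.any():
        rho_shield = (get_material(config.shield.material).density
                      * config.shield.thickness_mm / 1000.0 / spacing_m)
        shield_id = scene.material_id(config.shield.material, rho_shield)
        scene.materials[shield_occ] = shield_id

    scene.roi_set = rois
    return scene
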