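"""Dose tallies: per-voxel dose, ROI dose rates and air-map slices.

Two estimators feed this module.  In-phantom (and generally in-scene) doses
come from analog energy deposition on the scene grid; the coarse air map uses
the track-length collision-kerma estimator, which has far lower variance in
the thin air at desk-scale history counts.

Dose-rate conversion follows the calibration chain: dose per photon x
photons per mAs into the field x scaling factor x (mA x 3600 s/h).  The tube
current is interpreted as time-averaged current, so 3.0 mA means
3.0 x 3600 mAs per hour of beam-on time; the pulse rate (fps) is carried as
metadata only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .materials import lookup_mu_en
from .scene import SceneConfig, VoxelScene
from .transport import TransportResult
from . import _kernels

KEV_TO_J = 1.602176634e-16
AIR_DENSITY = 1.205e-3  # g/cm^3

#: preconfigured air-map height bands, cm from floor
HEIGHT_BANDS_CM = {
    "lens": (145.0, 150.0),
    "thyroid": (130.0, 135.0),
    "ovary": (80.0, 85.0),
}


@dataclass(frozen=True)
class ConversionMeta:
    """Everything needed to turn dose-per-photon into an absolute dose rate."""

    photons_per_mAs: float
    mA: float = 3.0
    scaling_factor: float | None = 1.10
    fps: float = 3.75  # metadata only; mA is time-averaged

    def __post_init__(self) -> None:
        if self.photons_per_mAs <= 0 or self.mA <= 0:
            raise ValueError("photons_per_mAs and mA must be positive")

    @property
    def photons_per_hour(self) -> float:
        if self.scaling_factor is None:
            raise ValueError(
                "no calibration scaling factor set: fit one with the "
                "calibration module or supply scaling_factor explicitly")
        return self.photons_per_mAs * self.scaling_factor * self.mA * 3600.0


@dataclass
class TallyGrid:
    """Per-voxel energy scores with batch statistics.

    ``batch_data`` has shape (n_batches, nx, ny, nz).  For analog tallies the
    values are summed deposits in keV and ``voxel_mass_g`` must be set; for
    track-length air tallies the values are keV * cm^2/g * cm and doses
    divide by the voxel volume instead.
    """

    origin: np.ndarray
    spacing: np.ndarray
    batch_data: np.ndarray
    n_per_batch: np.ndarray
    kind: str = "analog"            # "analog" | "air_kerma"
    voxel_mass_g: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("analog", "air_kerma"):
            raise ValueError("kind must be 'analog' or 'air_kerma'")
        if np.any(np.asarray(self.batch_data) < 0):
            raise ValueError("tally energies must be non-negative")
        if len(self.n_per_batch) != self.batch_data.shape[0]:
            raise ValueError("batch count mismatch")

    @property
    def dims(self):
        return self.batch_data.shape[1:]

    @property
    def n_histories(self) -> int:
        return int(np.sum(self.n_per_batch))

    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.spacing) * 1e6)

    def total(self) -> np.ndarray:
        return self.batch_data.sum(axis=0, dtype=np.float64)

    # ---- dose conversion ----------------------------------------------
    def dose_per_photon(self, voxel=None) -> np.ndarray | float:
        """Mean absorbed dose in Gy per source photon (per voxel or one voxel)."""
        total = self.total()
        if self.kind == "analog":
            if self.voxel_mass_g is None:
                raise ValueError("analog tally needs voxel masses")
            mass = self.voxel_mass_g
            if voxel is not None:
                if mass[voxel] <= 0:
                    raise ValueError("zero-mass voxel cannot be scored")
                return float(total[voxel] * KEV_TO_J / (mass[voxel] * 1e-3)
                             / self.n_histories)
            with np.errstate(divide="ignore", invalid="ignore"):
                d = total * KEV_TO_J / (mass * 1e-3) / self.n_histories
            return np.where(mass > 0, d, 0.0)
        # track-length kerma: value / voxel volume = keV/g
        d = self.total() / self.voxel_volume_cm3() * KEV_TO_J * 1e3 / self.n_histories
        return float(d[voxel]) if voxel is not None else d

    def batch_dose_per_photon(self) -> np.ndarray:
        """(nb, ...) per-batch dose per photon, for variance estimation."""
        nb = self.batch_data.shape[0]
        out = np.empty_like(self.batch_data, dtype=np.float64)
        for b in range(nb):
            if self.kind == "analog":
                with np.errstate(divide="ignore", invalid="ignore"):
                    d = (self.batch_data[b] * KEV_TO_J
                         / (self.voxel_mass_g * 1e-3) / self.n_per_batch[b])
                out[b] = np.where(self.voxel_mass_g > 0, d, 0.0)
            else:
                out[b] = (self.batch_data[b] / self.voxel_volume_cm3()
                          * KEV_TO_J * 1e3 / self.n_per_batch[b])
        return out


def body_tally(result: TransportResult, scene: VoxelScene) -> TallyGrid:
    """Analog deposition tally on the scene grid."""
    return TallyGrid(origin=scene.origin.copy(), spacing=scene.spacing.copy(),
                     batch_data=result.body_batches,
                     n_per_batch=result.n_per_batch, kind="analog",
                     voxel_mass_g=scene.voxel_mass_g())


def kerma_tally(result: TransportResult, scene: VoxelScene) -> TallyGrid:
    """Collision-kerma tally on the scene grid.

    Unbiased for the same kerma-approximation dose as analog deposition but
    with far lower variance in thinly-hit regions (skin shells, small ROIs),
    because every tentative delta-tracking collision contributes, not only
    the accepted interactions.  Preferred for surface-ROI dose reporting;
    the analog tally remains the conservation ledger.
    """
    return TallyGrid(origin=scene.origin.copy(), spacing=scene.spacing.copy(),
                     batch_data=result.kerma_batches,
                     n_per_batch=result.n_per_batch, kind="air_kerma")


def air_tally(result: TransportResult) -> TallyGrid:
    """Track-length collision-kerma tally on the coarse air mesh."""
    return TallyGrid(origin=result.air_origin.copy(),
                     spacing=result.air_spacing.copy(),
                     batch_data=result.air_batches,
                     n_per_batch=result.n_per_batch, kind="air_kerma")


def to_dose_rate(dose_per_photon, conversion: ConversionMeta):
    """Convert Gy per photon to uGy/h using the calibration chain."""
    return np.asarray(dose_per_photon) * conversion.photons_per_hour * 1e6


def track_length_kerma_score(p0, p1, energy_keV: float, grid_origin,
                             grid_spacing, grid_dims, weight: float = 1.0):
    """Track-length kerma additions for one flight segment through air.

    Returns (flat voxel indices, contributions in keV*cm^2/g*cm): each
    traversed voxel receives E * (mu_en/rho)_air(E) * chord * weight.  Chord
    lengths come from half-open voxel traversal of the segment.
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    dims = np.asarray(grid_dims, dtype=np.int64)
    cap = int(np.abs((p1 - p0) / np.asarray(grid_spacing)).sum() + 8)
    idx = np.empty(cap, dtype=np.int64)
    lens = np.empty(cap, dtype=np.float64)
    n = _kernels.trace_segment(p0, p1, np.asarray(grid_origin, dtype=float),
                               np.asarray(grid_spacing, dtype=float),
                               dims, idx, lens)
    muen = lookup_mu_en("air", energy_keV)
    return idx[:n], energy_keV * muen * lens[:n] * 100.0 * weight


def roi_dose_rate(tally: TallyGrid, roi_mask: np.ndarray,
                  conversion: ConversionMeta) -> tuple[float, float]:
    """Mass-weighted mean ROI dose rate and its 1-sigma, in uGy/h.

    The mean is over ROI voxels weighted by voxel mass; sigma is the standard
    error of the mean estimated from the between-batch variance.
    """
    if not roi_mask.any():
        raise ValueError("empty ROI mask")
    if roi_mask.shape != tally.dims:
        raise ValueError("ROI mask does not match the tally grid")
    if tally.kind == "analog":
        mass = tally.voxel_mass_g[roi_mask]
        if np.any(mass <= 0):
            raise ValueError("ROI contains zero-mass voxels")
        weights = mass / mass.sum()
    else:
        weights = np.full(int(roi_mask.sum()), 1.0 / roi_mask.sum())
    batch = tally.batch_dose_per_photon()[:, roi_mask]
    batch_means = batch @ weights
    mean = float(batch_means.mean())
    nb = len(batch_means)
    sigma = float(batch_means.std(ddof=1) / math.sqrt(nb))
    return (to_dose_rate(mean, conversion), to_dose_rate(sigma, conversion))


def height_slice_map(air: TallyGrid, band_cm: tuple[float, float],
                     conversion: ConversionMeta):
    """Mean dose-rate map (uGy/h) over the voxel layers in a height band.

    Returns (2-D map over x,y, z-layer indices used).  The band is in cm
    from the floor; layers whose centres fall inside the half-open band are
    averaged.
    """
    z_lo, z_hi = band_cm[0] / 100.0, band_cm[1] / 100.0
    nz = air.dims[2]
    z_centers = air.origin[2] + (np.arange(nz) + 0.5) * air.spacing[2]
    layers = np.where((z_centers >= z_lo) & (z_centers < z_hi))[0]
    if len(layers) == 0:
        raise ValueError(f"height band {band_cm} cm intersects no voxel layer")
    dpp = tally_mean_map(air, layers)
    return to_dose_rate(dpp, conversion), layers


def tally_mean_map(air: TallyGrid, layers) -> np.ndarray:
    d = air.dose_per_photon()
    return d[:, :, layers].mean(axis=2)


def export_slice_csv(path, dose_map: np.ndarray) -> None:
    np.savetxt(path, dose_map, delimiter=",", fmt="%.6e")


def export_nrrd(path, tally: TallyGrid, conversion: ConversionMeta | None = None):
    """3-D dose grid export with spacing/origin metadata (requires SimpleITK)."""
    import SimpleITK as sitk

    data = tally.dose_per_photon()
    if conversion is not None:
        data = to_dose_rate(data, conversion)
    img = sitk.GetImageFromArray(np.ascontiguousarray(
        np.asarray(data).transpose(2, 1, 0)))
    img.SetSpacing(tuple(tally.spacing))
    img.SetOrigin(tuple(tally.origin))
    sitk.WriteImage(img, str(path))


def contour_area_above(dose_map: np.ndarray, spacing_m, level_uGy_h: float = 50.0):
    """Area (m^2) of the map at or above a dose-rate level (default 50 uGy/h)."""
    cell_area = float(spacing_m[0] * spacing_m[1])
    return float(np.count_nonzero(dose_map >= level_uGy_h) * cell_area)


# --------------------------------------------------------------------------
# shield shadow analysis


def _shielded_mask(scene_cfg: SceneConfig, air: TallyGrid, layers) -> np.ndarray:
    """Cells of the slice geometrically occluded from the focal spot.

    A cell is shadowed when the ray from the source focal point to the cell
    centre (at the slice height) crosses the shield panel outside any
    aperture.
    """
    from .scene import set_projection

    src = set_projection(scene_cfg).position
    spec = scene_cfg.shield
    y_panel = scene_cfg.shield_plane_y
    cx_room = scene_cfg.room_center_xy[0]
    nx, ny = air.dims[0], air.dims[1]
    xs = air.origin[0] + (np.arange(nx) + 0.5) * air.spacing[0]
    ys = air.origin[1] + (np.arange(ny) + 0.5) * air.spacing[1]
    z_c = float(np.mean(air.origin[2] + (np.asarray(layers) + 0.5) * air.spacing[2]))

    X, Y = np.meshgrid(xs, ys, indexing="ij")
    dy = Y - src[1]
    shadowed = np.zeros((nx, ny), dtype=bool)
    behind = dy * (y_panel - src[1]) > 0  # same side as the panel
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(dy != 0, (y_panel - src[1]) / dy, np.inf)
    crosses = behind & (t > 0) & (t < 1)
    x_hit = src[0] + t * (X - src[0])
    z_hit = src[2] + t * (z_c - src[2])
    in_panel = (np.abs(x_hit - cx_room) <= spec.panel_width_m / 2) \
        & (z_hit >= spec.floor_offset_m) \
        & (z_hit <= spec.floor_offset_m + spec.panel_height_m)
    blocked = crosses & in_panel
    for (x_lo, x_hi, z_lo, z_hi) in spec.aperture_rects():
        in_hole = ((x_hit - cx_room >= x_lo) & (x_hit - cx_room <= x_hi)
                   & (z_hit >= z_lo) & (z_hit < z_hi))
        blocked &= ~in_hole
    shadowed[:] = blocked
    return shadowed


@dataclass(frozen=True)
class ShadowReport:
    """With/without dose-rate ratios for shadowed vs open map cells."""

    shadowed_ratio: float
    shadowed_sigma: float
    open_ratio: float
    open_sigma: float
    n_shadowed: int
    n_open: int


def shadow_analysis(air_with: TallyGrid, air_without: TallyGrid,
                    scene_cfg: SceneConfig,
                    band_cm: tuple[float, float] = HEIGHT_BANDS_CM["lens"],
                    exclude_m: float = 1.0,
                    solid_outline: bool = False) -> ShadowReport:
    """Classify slice cells as shadowed/open and compare dose-rate ratios.

    Ratios are (dose with shield) / (dose without) averaged per class;
    sigmas propagate between-batch variances of the two class means.  Cells
    within ``exclude_m`` of the beam axis are dropped so the primary-beam
    region does not dominate the open class.

    With ``solid_outline`` the shadow region ignores the apertures (the
    occlusion of the full panel rectangle).  That is the right region for
    comparing aperture wrap-around across patterns, because it is identical
    for every pattern: radiation passing through an aperture and reaching
    the backside raises the shadowed-class ratio instead of being
    reclassified as open.
    """
    if air_with.dims != air_without.dims:
        raise ValueError("maps do not share a geometry")
    if solid_outline:
        from dataclasses import replace as _replace
        scene_cfg = _replace(scene_cfg,
                             shield=_replace(scene_cfg.shield,
                                             pattern="none_aperture"))
    z_lo, z_hi = band_cm[0] / 100.0, band_cm[1] / 100.0
    nz = air_with.dims[2]
    z_centers = air_with.origin[2] + (np.arange(nz) + 0.5) * air_with.spacing[2]
    layers = np.where((z_centers >= z_lo) & (z_centers < z_hi))[0]
    shadowed = _shielded_mask(scene_cfg, air_with, layers)

    iso = scene_cfg.isocenter
    xs = air_with.origin[0] + (np.arange(air_with.dims[0]) + 0.5) * air_with.spacing[0]
    ys = air_with.origin[1] + (np.arange(air_with.dims[1]) + 0.5) * air_with.spacing[1]
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    far = np.hypot(X - iso[0], Y - iso[1]) > exclude_m

    def class_means(tally):
        batch = tally.batch_dose_per_photon()[:, :, :, layers].mean(axis=3)
        return batch  # (nb, nx, ny)

    bw = class_means(air_with)
    bo = class_means(air_without)

    def ratio(mask):
        sel = mask & far
        n = int(sel.sum())
        if n == 0:
            return math.nan, math.nan, 0
        w_means = bw[:, sel].mean(axis=1)
        o_means = bo[:, sel].mean(axis=1)
        r = w_means.mean() / o_means.mean()
        nb = len(w_means)
        var = (w_means.std(ddof=1) ** 2 / w_means.mean() ** 2
               + o_means.std(ddof=1) ** 2 / o_means.mean() ** 2)
        return float(r), float(abs(r) * math.sqrt(var / nb)), n

    r_sh, s_sh, n_sh = ratio(shadowed)
    r_op, s_op, n_op = ratio(~shadowed)
    return ShadowReport(r_sh, s_sh, r_op, s_op, n_sh, n_op)
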