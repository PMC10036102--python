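"""Dose-conversion scaling factor: measured-vs-simulated regression.

The transport engine produces relative dose (per source photon, normalised
per mAs by the spectrum model).  The scaling factor that converts it to
absolute dose is the slope of a zero-intercept least-squares line through
(simulated, measured) dose pairs over a 12-condition design: three
source-to-surface distances (60, 65, 70 cm) crossed with four depths
(0, 5, 10, 15 cm) in a water phantom, a dosimeter at the centre of the field
each time.  The published factor for the modelled installation is 1.10 with
r = 0.995, and that constant is the package default whenever no fresh fit is
supplied.

``r_squared`` is deliberately the square of Pearson's product-moment
correlation (not the through-origin regression R^2); both conventions exist
and the former is what the reference analysis reports.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .scene import SourceGeometry, VoxelScene
from .spectrum import Spectrum
from .transport import RunConfig, run_histories

DEFAULT_SCALING_FACTOR = 1.10

SSD_GRID_CM = (60.0, 65.0, 70.0)
DEPTH_GRID_CM = (0.0, 5.0, 10.0, 15.0)


@dataclass(frozen=True)
class CalibrationCondition:
    """One measurement condition: SSD and dosimeter depth, field centre."""

    ssd_cm: float
    depth_cm: float

    def __post_init__(self) -> None:
        if not 60.0 <= self.ssd_cm <= 70.0:
            raise ValueError("SSD outside the 60-70 cm design range")
        if not 0.0 <= self.depth_cm <= 15.0:
            raise ValueError("depth outside the 0-15 cm design range")


@dataclass(frozen=True)
class CalibrationFit:
    """Zero-intercept regression result."""

    slope: float
    pearson_r: float
    r_squared: float
    n_points: int
    residuals: np.ndarray

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("need at least two points")
        if not -1.0 - 1e-12 <= self.pearson_r <= 1.0 + 1e-12:
            raise ValueError("invalid correlation")

    def slope_stderr(self) -> float:
        """Standard error of the through-origin slope."""
        x = self.residuals_x
        dof = max(self.n_points - 1, 1)
        s2 = float(self.residuals @ self.residuals) / dof
        return math.sqrt(s2 / float(x @ x))

    @property
    def residuals_x(self) -> np.ndarray:
        return self._x

    def to_json(self, path=None) -> str:
        doc = json.dumps({"slope": self.slope, "pearson_r": self.pearson_r,
                          "r_squared": self.r_squared,
                          "n_points": self.n_points}, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(doc)
        return doc


def fit_zero_intercept(x, y) -> CalibrationFit:
    """Least-squares line through the origin: slope = sum(xy) / sum(x^2).

    ``x`` are simulated doses, ``y`` measured doses.  ``pearson_r`` is the
    ordinary product-moment correlation and ``r_squared`` its square.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if len(x) < 2:
        raise ValueError("need at least two points")
    sxx = float(x @ x)
    if sxx == 0.0:
        raise ValueError("degenerate fit: all simulated doses are zero")
    slope = float(x @ y) / sxx
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(x, y)[0, 1])
    fit = CalibrationFit(slope=slope, pearson_r=r, r_squared=r * r,
                         n_points=len(x), residuals=y - slope * x)
    object.__setattr__(fit, "_x", x)
    return fit


def generate_conditions() -> list[CalibrationCondition]:
    """The deterministic 12-condition design: 3 SSDs x 4 depths."""
    return [CalibrationCondition(ssd, depth)
            for ssd in SSD_GRID_CM for depth in DEPTH_GRID_CM]


def _calibration_scene(condition: CalibrationCondition, spacing_cm: float = 1.0):
    """Water-slab phantom at the given SSD with an axial scoring column.

    The phantom is a 30 x 30 x 20 cm water block in vacuum; the source sits
    below it on the central axis, aiming up with the clinical field.
    """
    sp = spacing_cm / 100.0
    ssd = condition.ssd_cm / 100.0
    lat = 0.40
    phantom_t = 0.20
    lz = ssd + phantom_t + 0.05
    dims = (int(round(lat / sp)), int(round(lat / sp)), int(math.ceil(lz / sp)))
    scene = VoxelScene(origin=np.array([-lat / 2, -lat / 2, 0.0]),
                       spacing=np.array([sp] * 3),
                       materials=np.zeros(dims, dtype=np.uint8),
                       registry=[("vacuum", 0.0)])
    water = scene.material_id("water")
    zc = scene.voxel_centers(2)
    half = 0.15
    xc = scene.voxel_centers(0)
    yc = scene.voxel_centers(1)
    in_x = np.abs(xc) <= half
    in_y = np.abs(yc) <= half
    in_z = (zc >= ssd) & (zc < ssd + phantom_t)
    scene.materials[np.ix_(in_x, in_y, in_z)] = water
    src = SourceGeometry(position=np.array([0.0, 0.0, 1e-6]),
                         axis=np.array([0.0, 0.0, 1.0]),
                         sid_m=1.0, field_side_m=0.1565)
    # scoring voxel: centre of field at the requested depth
    k = np.searchsorted(zc, ssd + condition.depth_cm / 100.0 + sp / 2)
    k = min(max(k, 0), dims[2] - 1)
    voxel = (dims[0] // 2, dims[1] // 2, int(k))
    return scene, src, voxel


def simulate_calibration_doses(conditions, spectrum: Spectrum, run: RunConfig,
                               spacing_cm: float = 1.0):
    """Simulated dose per photon (with 1-sigma) for each condition.

    Each condition gets its own transport run on a water-slab scene; the
    dose is the analog deposit in the scoring voxel at the centre of the
    field at the condition's depth.  Returns (doses, sigmas) in Gy/photon.
    """
    from .tally import body_tally

    doses = np.empty(len(conditions))
    sigmas = np.empty(len(conditions))
    for i, cond in enumerate(conditions):
        scene, src, voxel = _calibration_scene(cond, spacing_cm)
        sub = RunConfig(n_histories=run.n_histories, n_batches=run.n_batches,
                        seed=run.seed + i, cutoff_keV=run.cutoff_keV)
        result = run_histories(sub, scene, spectrum, src)
        tally = body_tally(result, scene)
        doses[i] = tally.dose_per_photon(voxel)
        batch = tally.batch_dose_per_photon()[(slice(None), *voxel)]
        sigmas[i] = batch.std(ddof=1) / math.sqrt(len(batch))
    return doses, sigmas
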