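# Methods

## Problem and model

During fluoroscopy-guided structural-heart procedures (TAVR, TEER) the
anesthesiologist stands at the patient's head and is irradiated almost
entirely by Compton-scattered photons from the patient, table and floor.
The package evaluates a freestanding perforated radiation shield — a 1 mm
lead (or 1 mm lead-equivalent acrylic) panel with work apertures on both
sides — by Monte Carlo photon transport through a voxelized operating-room
scene.  Four shield configurations are compared: no shield, large apertures,
small apertures, and a solid panel.  The reported quantities are
absorbed-dose rates (uGy/h) on surface regions of a standing staff phantom
and air-kerma maps over room-height slices.

The transport model is photon-only in the diagnostic range (5–150 keV):

- **Photoelectric absorption** deposits the full photon energy locally and
  emits no fluorescence.  Electron transport is suppressed (kerma
  approximation): with an 80 kVp endpoint the secondary-electron ranges are
  sub-millimetre, below the voxel pitch, and the lead K-edge (88 keV) is
  never reached, so K-fluorescence cannot occur; lead L-fluorescence
  (10–14 keV) is close to the cutoff and is neglected.
- **Incoherent scattering** samples the free-electron Klein–Nishina
  distribution by Kahn's composition–rejection method; the energy loss
  deposits at the interaction voxel.  No incoherent scattering function or
  Doppler broadening is applied to the *angular* sampling (a few-percent
  shape effect at these energies), although the incoherent *cross sections*
  in the material tables are S(q,Z)-corrected.
- **Coherent scattering** uses the Thomson angular law (no form-factor
  sharpening of the angular distribution).
- Photons falling below the 5 keV cutoff deposit their remaining energy
  locally.

## Tracking

Flights use Woodcock (delta) tracking against a **cell-local majorant**: the
room is overlaid with a coarse mesh (5 cm cells by default), each cell
storing the maximum linear attenuation of the materials present in the cell
and its neighbours, maximised over 5 keV energy bins.  Free paths are
sampled from the local majorant and capped at the cell boundary; tentative
collisions are accepted with probability mu_local/mu_majorant.  A global
majorant would be useless here — lead exceeds air by five orders of
magnitude — while the cell-local variant keeps the virtual-collision rate
near unity in air and confines the short steps to cells that actually
contain dense material.  A pure-Python reference tracker with a global
majorant implements the same physics for oracle tests and trajectory
logging.

Because the majorant mesh coincides with the air-map grid, every movement
substep lies inside one air-map cell; substeps whose midpoint is in air are
scored on the fly with the **track-length kerma estimator**
(E · (mu_en/rho)_air · chord), which at desk-scale history counts has far
lower variance in thin air than analog deposition (the estimator-equivalence
test measures a >5x variance advantage).

Three estimators are tallied on every run:

- **analog deposition** on the scene grid — the exact energy ledger, used
  for conservation checks and 3-D dose export;
- **track-length air kerma** on the coarse mesh — the air-dose maps;
- **collision kerma** on the scene grid — every tentative delta-tracking
  collision (real or virtual) scores E · (mu_en/rho)_material / mu_majorant,
  whose expectation per unit track length is the kerma density.  Under
  suppressed electron transport, kerma *is* the model's absorbed dose, so
  this estimator is unbiased for the same quantity as analog deposition but
  every photon crossing a voxel contributes instead of only the rare
  accepted interactions.  Surface-ROI dose rates (a skin shell is one voxel
  thick and sees few analog events even at millions of histories) are
  reported from this estimator; the equivalence of the two is itself a test.

Determinism: a run is a pure function of (seed, configuration).  Batch b
draws from a `SeedSequence(seed)` child stream, and the kernel is
sequential, so reruns reproduce every tally bit for bit regardless of host.

## Cross-section data

Packaged CSV tables (5–150 keV, log-spaced grid plus the Pb L/K and Cu/Fe
K edge points) carry total, energy-absorption and partial mass attenuation
coefficients for 11 materials and 17 elements.  They are generated once by
`scripts/make_xsec_tables.py` from public reference physics: photoelectric
cross sections from Cromer–Liberman f'' via the optical theorem, incoherent
from Klein–Nishina integrated with the S(q,Z) = Z[1 − (F/Z)^2]
approximation, coherent from Thomson weighted by squared IT92 atomic form
factors (hydrogenically damped beyond the fit's validity range), and
mu_en as photoelectric plus the Klein–Nishina mean energy-transfer fraction
of the incoherent part (radiative losses and fluorescence escape
neglected).  The generator's `--check` mode compares against published NIST
values; in the range that matters for an 80 kVp beam the tables agree with
NIST to ~2% for light materials and ~3% for lead at 60 keV.  Tissue
compositions follow ICRU-44; concrete is NIST ordinary concrete at
2.3 g/cm^3; 1 mm lead-equivalent acrylic is modelled as 1 mm lead.

## Source model

The tube spectrum is Kramers-law bremsstrahlung for a tungsten anode with
1 mmAl inherent filtration and semi-empirical W K-lines (3% of fluence at
80 kVp), filtered by the clinical stack 2.5 mmAl + 0.4 mmCu + 1.0 mmAl.
The filtered beam has mean energy ~54.9 keV and aluminum HVL ~6.9 mm; the
same model with conventional Al-only filtration (no copper) lands in the
textbook 2.5–4.5 mm HVL range for 80 kVp, which is the configuration used
as the realism bracket — 0.4 mm of copper is strong hardening and roughly
doubles the HVL of any physical 80 kVp beam.

Absolute output (photons per mAs per steradian) comes from the Kramers
efficiency constant with a 50% anode self-absorption allowance.  This
constant is deliberately crude: the simulation computes *relative* dose per
photon, and the absolute scale is fixed by the calibration scaling factor,
mirroring how a relative Monte Carlo system is calibrated against physical
dosimeter measurements.  The tube current (3.0 mA) is treated as
time-averaged, so one beam-on hour is 3.0 × 3600 mAs; the pulse rate
(3.75 fps) is metadata only.

## Calibration

The dose-conversion factor is the slope of a zero-intercept least-squares
line through (simulated, measured) dose pairs over a 12-condition design:
SSD ∈ {60, 65, 70} cm × depth ∈ {0, 5, 10, 15} cm in a water phantom (the
design count and ranges are fixed; the specific grid is this package's
choice).  `r_squared` is reported as the square of Pearson's r, not the
through-origin regression R².  No physical measurements exist inside the
package, so the synthetic-measurement generator produces
y = slope · x · (1 + eps), eps ~ N(0, CV), with CV 5% as the realistic
dosimeter repeatability; the published factor 1.10 is the default constant
whenever no fresh fit is supplied.  Dosimeter energy response is not
modelled.

## Scene and phantoms

Two scene geometries are used, matching the two halves of the study design:

- **Staff-exposure geometry** (`include_walls=False`): undertable source,
  table, supine patient, standing staff phantom and shield over a concrete
  floor, in open air.  Dose to the staff is dominated by single and double
  scatter off the patient, table and floor; there are no walls to
  backscatter around the shield.  All surface-ROI dose results use this
  geometry.
- **Air-dose-map geometry** (`include_walls=True`, the default): the full
  concrete room.  Height-slice air-kerma maps and the shield shadow
  analyses use this geometry.

The distinction matters quantitatively: in a walled room,
concrete-backscatter bypasses the shield and dominates the behind-shield
dose at head height, several-fold above the open-geometry value, so
shielding ratios measured in the walled room are much more pessimistic than
the staff-exposure results.

Right-handed coordinates, z up, z = 0 at the floor surface; configuration
heights are centimetres from the floor.  The room is a concrete box
(default outer size 8.1 × 7.3 × 3.4 m, 20 cm walls inside that envelope);
the table is a 2 cm carbon-fibre-like slab (water at 0.30 g/cm³,
homogenised into its voxel layer when thinner than the pitch) at 1.0 m; the
patient is a supine stylized 170 cm body of water with a one-voxel skin
shell and a spine core; the staff phantom is a stack of elliptical
segments (legs, trunk, neck, head — 160.8 cm default) of water with skin
shell, bone cores and eye-lens patches, standing at 45° to the patient axis
beyond the shield.  Rasterisation is by voxel-centre sampling with priority
shield > staff > patient > table > walls > air.

Surface ROIs are full rings of surface voxels in height bands that scale
with phantom height: lens 145–150 cm (eye level of the 160.8 cm reference),
neck 130–135 cm, chest 110–120 cm, waist 80–85 cm; lens and chest are split
left/right by the sagittal plane.  The chest band limits and the aperture
widths (35 cm large / 25 cm small per side) are package choices — the
device's aperture *height* bands are fixed: large 100–140 cm (echo side) /
90–130 cm (anesthesia side), small 105–125 / 95–115 cm.

The shield panel (1.0 m × 1.8 m, lower edge on the floor, 30 cm beyond the
patient's head plane) is thinner than any practical voxel, so shield voxels
carry a density-homogenised lead entry preserving areal density along the
panel normal; transmission error for oblique crossings is second order.

The undertable source is a point with ideal rectangular collimation
(156.5 mm square defined at the receptor, SID 1.0 m; SSD 60 cm at PA).
RAO/LAO rotates the axis about the patient's longitudinal axis, CRA/CAU
about the lateral axis, keeping the source-isocenter distance fixed;
Cusp-overlap is RAO 9° + CAU 1°, Perpendicular LAO 16° + CRA 13°.

## Scaled scenes and problem sizes

Desk-scale runs use `fixtures.make_scaled_or_scene`: the room extent shrinks
in x and y while every clinically meaningful distance — SSD, SID, field
size, shield placement, stance, ROI heights, full room height — stays at
full scale, and the voxel pitch is the smallest that keeps the scene at or
under two million voxels (3 cm at half scale).  The default shielding runs
use 8 million histories in ten batches, air-map runs 2 million; ROI sigmas
are between-batch standard errors of the ROI mean.

Scaling the room extent is harmless in the exposure geometry (open air
carries no scatter back) but shortens wall paths in the walled geometry, so
walled-room results are used only for *internal* comparisons (with/without
shield on identical geometry), which are insensitive to the absolute wall
distance.

## Known limitations

- Stylized phantoms instead of reference voxel anatomies; organ doses are
  surface-band doses, not organ-averaged.
- Free-electron Compton angles and Thomson coherent angles (no momentum-
  dependent corrections to the sampled angles).
- No C-arm hardware, monitors or second staff member in the scene.
- The absolute dose scale rests on the semi-empirical tube-output constant
  times the calibration factor; relative quantities (shielding ratios,
  pattern comparisons, map shapes) are insensitive to it.
- Air maps score collision kerma, reported as absorbed dose to air; at
  these energies the difference is negligible.
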