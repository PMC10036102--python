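# scattershield

Voxel Monte Carlo photon transport for occupational scatter dosimetry in
fluoroscopy-guided structural-heart interventions — specifically, for
evaluating how much a freestanding **perforated radiation shield** (a 1 mm
lead or lead-equivalent panel with work apertures on both sides) reduces the
dose to the anesthesiologist standing at the patient's head.

During TAVR and TEER procedures the anesthesiologist works beside the
patient's head while an undertable X-ray tube irradiates the chest; nearly
all of their dose is Compton scatter from the patient, table and floor.  A
solid protective panel blocks that scatter but also blocks access to the
airway; a perforated panel with aperture cartridges promises both access
and protection.  This package answers *how much* protection, by simulation:

- diagnostic-range (5–150 keV) photon transport — photoelectric absorption,
  Klein–Nishina Compton scattering, Thomson coherent scattering — through
  voxelized scenes, with Woodcock delta tracking against a cell-local
  majorant and a 5 keV cutoff (electron transport suppressed: kerma
  approximation);
- an 80 kVp tungsten-anode beam model with the clinical filtration
  2.5 mmAl + 0.4 mmCu + 1.0 mmAl, field 156.5 mm × 156.5 mm at SID 1.0 m,
  SSD 60 cm, in PA, Cusp-overlap (RAO 9°/CAU 1°) and Perpendicular
  (LAO 16°/CRA 13°) projections;
- stylized supine patient and standing staff phantoms (ICRU-44 lens, bone,
  skin compositions; other tissue water), surface-band ROIs at lens
  (145–150 cm), neck (130–135 cm), chest and waist (80–85 cm) heights;
- the four shield patterns compared in the study design: no shield, large
  apertures (echo side 100–140 cm / anesthesia side 90–130 cm), small
  apertures (105–125 / 95–115 cm) and a solid panel;
- absorbed-dose-rate conversion via a zero-intercept calibration regression
  (simulated vs measured dose; the reference factor is 1.10) and the tube
  technique 3.0 mA, so results print in μGy per hour of beam-on time;
- air-kerma maps on a 5 cm grid over room-height slices, with shadow and
  aperture wrap-around analysis behind the shield.

Dose rate for a region is computed as

    D [μGy/h] = D_photon [Gy/photon] × N_mAs [photons/mAs] × f × I [mA] × 3600 × 1e6

with `f` the calibration scaling factor and `D_photon` estimated either by
analog energy deposition or by fluence-based (track-length / collision)
kerma estimators — see `docs/methods.md`.

## Worked example

Run the four shield patterns for the PA projection on the desk-scale
(half-extent) staff-exposure scene:

```python
from scattershield import StudyConfig, run_shield_study, compare_patterns
from scattershield.fixtures import make_scaled_or_scene
from scattershield.transport import RunConfig

scene, spacing, fixture = make_scaled_or_scene(0.5, include_walls=False)
study = StudyConfig(scene=scene, spacing_m=spacing, projections=("PA",),
                    run=RunConfig(n_histories=8_000_000, seed=1))
result = run_shield_study(study)
print(compare_patterns(result.report, baseline="absent")
      .query("roi in ('lens_left','lens_right','waist')")
      .to_string(index=False))
```

```
      pattern projection        roi  percent_of_baseline  sigma_percent  undefined_ratio
       absent         PA  lens_left           100.000000      13.567248            False
       absent         PA lens_right           100.000000      15.766777            False
       absent         PA      waist           100.000000       6.771161            False
        large         PA  lens_left            28.359071       6.993271            False
        large         PA lens_right            32.309076       7.456163            False
        large         PA      waist             5.199133       0.655129            False
        small         PA  lens_left            15.114720       4.003514            False
        small         PA lens_right            12.231442       5.173855            False
        small         PA      waist             5.581601       1.069833            False
none_aperture         PA  lens_left             4.883133       2.394366            False
none_aperture         PA lens_right             5.450796       2.619420            False
none_aperture         PA      waist             4.363474       0.740839            False
```

Reading it: with no shield the eye-lens and waist bands define the 100%
baselines.  The solid panel cuts the lens-band dose rate to ~5% and the
waist to ~4% of the unshielded case (±1σ from ten independent batches);
the small apertures raise the lens band only to ~12–15% while leaving the
waist essentially at the solid-panel level, whereas the large apertures
leak noticeably more at eye level (~30%) — the quantitative case that the
small work apertures cost little protection.  Absolute rates (μGy/h) are
in `result.report`; air-map slices at lens, thyroid and ovary heights are
written next to the ROI table when `out_dir` is set.

The same study runs from the shell:

```sh
scattershield study --scale 0.5 --n-histories 1000000 --seed 1 --out study_out
scattershield report study_out/roi_dose_rates.csv --baseline absent
```

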