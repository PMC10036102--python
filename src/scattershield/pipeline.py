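"""Study orchestration: shield patterns x beam projections.

``run_shield_study`` executes one transport run per (pattern, projection)
cell of the study grid, producing the ROI dose-rate table, air-map height
slices and a JSON manifest that pins every resolved default, the seed and
the scene hashes so a rerun reproduces every output byte for byte.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import DEFAULT_SCALING_FACTOR
from .scene import (PATTERNS, SceneConfig, ShieldSpec, build_room_scene,
                    set_projection)
from .spectrum import Spectrum, table1_beam
from .tally import (ConversionMeta, HEIGHT_BANDS_CM, TallyGrid, air_tally,
                    body_tally, export_slice_csv, height_slice_map,
                    kerma_tally, roi_dose_rate)
from .transport import RunConfig, run_histories


@dataclass(frozen=True)
class StudyConfig:
    """The full study grid and its run parameters."""

    scene: SceneConfig = field(default_factory=SceneConfig)
    spacing_m: float = 0.03
    patterns: tuple[str, ...] = PATTERNS
    projections: tuple[str, ...] = ("PA", "cusp_overlap", "perpendicular")
    run: RunConfig = field(default_factory=lambda: RunConfig(n_histories=1_000_000))
    scaling_factor: float = DEFAULT_SCALING_FACTOR
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if not self.patterns or not self.projections:
            raise ValueError("need at least one pattern and one projection")
        for p in self.patterns:
            if p not in PATTERNS:
                raise ValueError(f"unknown pattern {p!r}")


@dataclass
class StudyResult:
    """Dose-report table plus per-cell air tallies and manifest."""

    report: pd.DataFrame
    air_maps: dict[tuple[str, str], TallyGrid]
    body_tallies: dict[tuple[str, str], TallyGrid]    # analog deposition
    kerma_tallies: dict[tuple[str, str], TallyGrid]   # collision kerma (ROI source)
    scene_configs: dict[tuple[str, str], SceneConfig]
    manifest: dict


def run_shield_study(study: StudyConfig,
                     spectrum: Spectrum | None = None) -> StudyResult:
    """Run every (pattern, projection) cell and assemble the dose report.

    The ROI table covers {lens L/R, neck, chest L/R, waist} for each cell;
    air maps are tallied per cell for the preconfigured height bands.  A
    failure in any cell aborts the study with the cell named.
    """
    beam = spectrum if spectrum is not None else table1_beam()
    rows = []
    air_maps: dict[tuple[str, str], TallyGrid] = {}
    body_tallies: dict[tuple[str, str], TallyGrid] = {}
    kerma_tallies: dict[tuple[str, str], TallyGrid] = {}
    scene_cfgs: dict[tuple[str, str], SceneConfig] = {}
    cells = {}
    for pattern in study.patterns:
        # the voxel scene depends only on the pattern; projections move the
        # source, so scene and physics tables are built once per pattern
        base_cfg = replace(study.scene,
                           shield=replace(study.scene.shield, pattern=pattern))
        pattern_scene = build_room_scene(base_cfg, study.spacing_m)
        physics = None
        for projection in study.projections:
            key = (pattern, projection)
            try:
                cfg = replace(base_cfg, projection=projection)
                scene = pattern_scene
                source = set_projection(cfg)
                if physics is None:
                    from .transport import compile_physics
                    physics = compile_physics(scene)
                conv = ConversionMeta(
                    photons_per_mAs=beam.photons_per_mAs(source.solid_angle_sr),
                    scaling_factor=study.scaling_factor)
                result = run_histories(study.run, scene, beam, source,
                                       physics=physics)
                bt = body_tally(result, scene)
                kt = kerma_tally(result, scene)
                air_maps[key] = air_tally(result)
                body_tallies[key] = bt
                kerma_tallies[key] = kt
                scene_cfgs[key] = cfg
                for roi in scene.roi_set.names():
                    dose, sigma = roi_dose_rate(kt, scene.roi_set[roi], conv)
                    rows.append({"pattern": pattern, "projection": projection,
                                 "roi": roi, "dose_rate_uGy_h": dose,
                                 "sigma_uGy_h": sigma})
                cells[f"{pattern}/{projection}"] = {
                    "scene_hash": scene.content_hash(),
                    "n_histories": result.n_histories,
                    "n_corrupted": result.n_corrupted,
                    "energy_balance_max": float(
                        np.abs(result.energy_balance()).max()),
                }
            except Exception as exc:
                raise RuntimeError(
                    f"study cell {key} failed: {exc}") from exc
    report = pd.DataFrame(rows)
    manifest = {
        "version": __version__,
        "seed": study.run.seed,
        "n_histories": study.run.n_histories,
        "n_batches": study.run.n_batches,
        "spacing_m": study.spacing_m,
        "patterns": list(study.patterns),
        "projections": list(study.projections),
        "scaling_factor": study.scaling_factor,
        "photons_per_mAs_sr": beam.photons_per_mAs_sr,
        "cells": cells,
    }
    out = StudyResult(report=report, air_maps=air_maps,
                      body_tallies=body_tallies, kerma_tallies=kerma_tallies,
                      scene_configs=scene_cfgs, manifest=manifest)
    if study.out_dir is not None:
        write_outputs(out, study)
    return out


def write_outputs(result: StudyResult, study: StudyConfig) -> None:
    out = Path(study.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.report.to_csv(out / "roi_dose_rates.csv", index=False,
                         float_format="%.6e")
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
    beam_conv = None
    for key, air in result.air_maps.items():
        pattern, projection = key
        cfg = result.scene_configs[key]
        source = set_projection(cfg)
        beam = table1_beam()
        conv = ConversionMeta(
            photons_per_mAs=beam.photons_per_mAs(source.solid_angle_sr),
            scaling_factor=study.scaling_factor)
        for band_name, band in HEIGHT_BANDS_CM.items():
            dose_map, _ = height_slice_map(air, band, conv)
            export_slice_csv(
                out / f"airmap_{pattern}_{projection}_{band_name}.csv",
                dose_map)


def compare_patterns(report: pd.DataFrame, baseline: str = "absent") -> pd.DataFrame:
    """Express each cell as a percentage of the baseline pattern's dose.

    Sigmas follow the first-order ratio-variance formula.  A zero baseline
    dose flags the row as undefined (NaN percentage) instead of failing.
    """
    if baseline not in set(report["pattern"]):
        raise ValueError(f"baseline pattern {baseline!r} not in report")
    base = report[report["pattern"] == baseline].set_index(["projection", "roi"])
    rows = []
    for _, row in report.iterrows():
        b = base.loc[(row["projection"], row["roi"])]
        if b["dose_rate_uGy_h"] > 0:
            pct = 100.0 * row["dose_rate_uGy_h"] / b["dose_rate_uGy_h"]
            if row["dose_rate_uGy_h"] > 0:
                rel = math.hypot(row["sigma_uGy_h"] / row["dose_rate_uGy_h"],
                                 b["sigma_uGy_h"] / b["dose_rate_uGy_h"])
                sig = abs(pct) * rel
            else:
                sig = 100.0 * row["sigma_uGy_h"] / b["dose_rate_uGy_h"]
            undefined = False
        else:
            pct, sig, undefined = math.nan, math.nan, True
        rows.append({"pattern": row["pattern"], "projection": row["projection"],
                     "roi": row["roi"], "percent_of_baseline": pct,
                     "sigma_percent": sig, "undefined_ratio": undefined})
    return pd.DataFrame(rows)
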