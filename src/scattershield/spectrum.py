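"""Fluoroscopic X-ray source spectra.

The source term is a semi-empirical tungsten-anode model: Kramers-law
bremsstrahlung attenuated by the tube's inherent filtration, plus the W
K-characteristic lines above the 69.5 keV K-edge with a small fluence
fraction.  The clinical beam of interest is 80 kVp filtered by
2.5 mmAl + 0.4 mmCu + 1.0 mmAl; its realism is checked through beam-quality
diagnostics (mean energy, aluminum half-value layer) rather than absolute
output, because the absolute dose scale is fixed downstream by the
measured-vs-simulated calibration factor.

``photons_per_mAs_sr`` carries the model's absolute normalisation as photons
per milliampere-second per steradian; multiplying by a collimation solid
angle gives photons per mAs into the field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .materials import Material, get_material, lookup_mu, lookup_mu_en

MEC2_KEV = 510.99895

#: tungsten K lines: energy (keV) and relative intensity within the K series
W_K_LINES = ((59.318, 1.00), (57.982, 0.575), (67.244, 0.33))
W_K_EDGE_KEV = 69.525

# Kramers efficiency constant: fraction of electron energy converted to
# bremsstrahlung is ~ 9.2e-10 * Z * V.  Half the yield is assumed to survive
# anode self-absorption and leave through the port, isotropically over 4 pi.
KRAMERS_K = 9.2e-10  # per volt
ANODE_Z = 74
ELECTRONS_PER_MAS = 6.241509e15


@dataclass(frozen=True)
class FiltrationStack:
    """Ordered beam-filtration layers of (material, thickness in mm)."""

    layers: tuple[tuple[Material, float], ...]

    def __post_init__(self) -> None:
        for _, t in self.layers:
            if t < 0:
                raise ValueError("filter thickness must be >= 0")

    @classmethod
    def from_spec(cls, spec) -> "FiltrationStack":
        """Build from [(name_or_material, mm), ...]."""
        layers = tuple(
            (m if isinstance(m, Material) else get_material(m), float(t))
            for m, t in spec)
        return cls(layers)


#: the clinical filtration of the modelled fluoroscope
TABLE_FILTRATION = (("aluminum", 2.5), ("copper", 0.4), ("aluminum", 1.0))


@dataclass(frozen=True)
class Spectrum:
    """Binned photon-fluence spectrum.

    ``bin_edges`` are ascending (keV, default 1 keV wide); ``weights`` are the
    relative photons per bin and always normalised to sum to one;
    ``photons_per_mAs_sr`` is the absolute normalisation.
    """

    bin_edges: np.ndarray
    weights: np.ndarray
    photons_per_mAs_sr: float
    kvp: float | None = None

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if edges.ndim != 1 or len(edges) != len(w) + 1:
            raise ValueError("need len(bin_edges) == len(weights) + 1")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be ascending")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        if w.sum() <= 0:
            raise ValueError("spectrum has no fluence")
        if self.kvp is not None and np.any((w > 0) & (edges[1:] > self.kvp + 1e-9)):
            raise ValueError("fluence above the kVp endpoint")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "weights", w / w.sum())

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def mean_energy(self) -> float:
        """Fluence-weighted mean photon energy, keV."""
        return float(np.sum(self.weights * self.bin_centers))

    def photons_per_mAs(self, solid_angle_sr: float) -> float:
        """Photons per mAs emitted into a collimated field of ``solid_angle_sr``."""
        return self.photons_per_mAs_sr * solid_angle_sr

    def to_csv(self, path) -> None:
        np.savetxt(path, np.column_stack([self.bin_centers, self.weights]),
                   delimiter=",", header="energy_keV,relative_fluence",
                   comments="", fmt="%.6e")

    @classmethod
    def from_csv(cls, path, photons_per_mAs_sr: float = 1.0) -> "Spectrum":
        raw = np.genfromtxt(path, delimiter=",", names=True)
        e = np.atleast_1d(raw["energy_keV"])
        w = np.atleast_1d(raw["relative_fluence"])
        width = np.diff(e).mean() if len(e) > 1 else 1.0
        edges = np.concatenate([[e[0] - width / 2], e + width / 2])
        return cls(edges, w, photons_per_mAs_sr)


def generate_spectrum(kvp: float, anode_angle_deg: float = 12.0,
                      inherent_filtration_mmAl: float = 1.0,
                      bin_width_keV: float = 1.0) -> Spectrum:
    """Kramers-form bremsstrahlung + W K-lines, after inherent filtration.

    ``anode_angle_deg`` is carried for interface completeness; the model has
    no heel effect, so it only has to be a plausible target angle.
    """
    if not 40.0 <= kvp <= 150.0:
        raise ValueError(f"kVp must be in [40, 150], got {kvp}")
    if not 5.0 <= anode_angle_deg <= 30.0:
        raise ValueError("anode angle outside the plausible 5-30 degree range")

    edges = np.arange(5.0, kvp + bin_width_keV, bin_width_keV)
    edges = edges[edges <= kvp + 1e-9]
    if edges[-1] < kvp:
        edges = np.append(edges, kvp)
    centers = 0.5 * (edges[:-1] + edges[1:])
    widths = np.diff(edges)

    # Kramers: photon number spectrum per energy ~ (kVp - E) / E
    n_rel = np.clip(kvp - centers, 0, None) / centers * widths

    # absolute normalisation before filtration (photons / mAs / sr)
    e_total_kev = KRAMERS_K * ANODE_Z * kvp * 1e3 * kvp * ELECTRONS_PER_MAS
    mean_e = np.sum(n_rel * centers) / np.sum(n_rel)
    photons_total = e_total_kev / mean_e * 0.5 / (4 * math.pi)

    spec = Spectrum(edges, n_rel, photons_total, kvp=kvp)
    if inherent_filtration_mmAl > 0:
        spec = apply_filtration(
            spec, FiltrationStack.from_spec([("aluminum", inherent_filtration_mmAl)]))

    if kvp > W_K_EDGE_KEV:
        # semi-empirical K-line fluence fraction of the filtered bremsstrahlung
        frac = 0.9 * ((kvp - W_K_EDGE_KEV) / kvp) ** 1.65
        w = spec.weights.copy()
        line_total = frac * w.sum() / sum(i for _, i in W_K_LINES)
        for e_line, intensity in W_K_LINES:
            idx = np.searchsorted(spec.bin_edges, e_line) - 1
            w[idx] += line_total * intensity
        spec = Spectrum(spec.bin_edges, w,
                        spec.photons_per_mAs_sr * (1 + frac), kvp=kvp)
    return spec


def apply_filtration(spectrum: Spectrum, stack: FiltrationStack) -> Spectrum:
    """Beer-Lambert attenuation of each bin through the filtration stack."""
    if not stack.layers:
        return spectrum
    e = spectrum.bin_centers
    atten = np.zeros_like(e)
    for mat, t_mm in stack.layers:
        mu_lin = np.asarray(lookup_mu(mat, e)) * mat.density  # 1/cm
        atten += mu_lin * t_mm * 0.1
    trans = np.exp(-atten)
    new_w = spectrum.weights * trans
    survived = new_w.sum()
    if survived <= 0:
        raise ValueError("filtration removed the entire spectrum")
    return Spectrum(spectrum.bin_edges, new_w,
                    spectrum.photons_per_mAs_sr * survived, kvp=spectrum.kvp)


def table1_beam() -> Spectrum:
    """The clinical 80 kVp beam with 2.5 mmAl + 0.4 mmCu + 1.0 mmAl filtration."""
    spec = generate_spectrum(80.0)
    return apply_filtration(spec, FiltrationStack.from_spec(TABLE_FILTRATION))


def air_kerma_per_fluence(spectrum: Spectrum) -> float:
    """Air-kerma response weight of the spectrum, keV * cm^2/g per photon."""
    e = spectrum.bin_centers
    return float(np.sum(spectrum.weights * e * lookup_mu_en("air", e)))


def half_value_layer(spectrum: Spectrum, material: Material | str) -> float:
    """Thickness (mm) of ``material`` halving the beam's air kerma."""
    mat = material if isinstance(material, Material) else get_material(material)
    e = spectrum.bin_centers
    response = spectrum.weights * e * np.asarray(lookup_mu_en("air", e))
    k0 = response.sum()
    if k0 <= 0:
        raise ValueError("spectrum carries no air kerma")
    mu_lin = np.asarray(lookup_mu(mat, e)) * mat.density  # 1/cm

    def transmitted_fraction(t_mm: float) -> float:
        return float(np.sum(response * np.exp(-mu_lin * t_mm * 0.1)) / k0) - 0.5

    if transmitted_fraction(100.0) > 0:
        raise ValueError("no half-value bracket within [0, 100] mm")
    return float(brentq(transmitted_fraction, 0.0, 100.0, xtol=0.01))


def sample_energy(spectrum: Spectrum, rng: np.random.Generator, n: int) -> np.ndarray:
    """Draw ``n`` photon energies by inverse-CDF sampling over the bins.

    Energies are uniform within a bin; the sequence is reproducible for a
    given generator state.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    cdf = np.cumsum(spectrum.weights)
    cdf /= cdf[-1]
    u = rng.random(n)
    idx = np.searchsorted(cdf, u, side="right")
    lo = spectrum.bin_edges[idx]
    hi = spectrum.bin_edges[idx + 1]
    return lo + rng.random(n) * (hi - lo)
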