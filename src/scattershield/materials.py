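"""Photon cross-section and material library for the diagnostic energy range.

Attenuation data are packaged as plain-text CSV tables (one per material or
element) spanning 5-150 keV, with columns

    energy_keV, mu_total, mu_en, mu_photo, mu_incoh, mu_coh

all mass coefficients in cm^2/g.  Lookups use log-log interpolation between
bracketing grid points, which reproduces stored values exactly at grid nodes
and keeps interpolation error below ~1% on this grid density.  Tables are
regenerated by ``scripts/make_xsec_tables.py``; the registry below is the
single source of truth for densities and elemental compositions.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np

ENERGY_MIN_KEV = 5.0
ENERGY_MAX_KEV = 150.0

#: density (g/cm^3) and elemental mass composition of every registered
#: material.  Tissues follow the ICRU-44 reference compositions; concrete is
#: NIST "ordinary concrete"; 1 mm lead-equivalent acrylic is modelled as 1 mm
#: of lead (the stated equivalence) and shares the lead table.
COMPOSITIONS: dict[str, tuple[float, dict[str, float]]] = {
    "water": (1.000, {"H": 0.111894, "O": 0.888106}),
    "air": (1.205e-3, {"C": 0.000124, "N": 0.755267, "O": 0.231781, "Ar": 0.012827}),
    "aluminum": (2.699, {"Al": 1.0}),
    "copper": (8.960, {"Cu": 1.0}),
    "lead": (11.35, {"Pb": 1.0}),
    "lead_acrylic": (11.35, {"Pb": 1.0}),
    "concrete": (2.300, {"H": 0.010, "C": 0.001, "O": 0.529107, "Na": 0.016,
                         "Mg": 0.002, "Al": 0.033872, "Si": 0.337021,
                         "K": 0.013, "Ca": 0.044, "Fe": 0.014}),
    "eye_lens": (1.07, {"H": 0.096, "C": 0.195, "N": 0.057, "O": 0.646,
                        "Na": 0.001, "P": 0.001, "S": 0.003, "Cl": 0.001}),
    "bone": (1.92, {"H": 0.034, "C": 0.155, "N": 0.042, "O": 0.435,
                    "Na": 0.001, "Mg": 0.002, "P": 0.103, "S": 0.003,
                    "Ca": 0.225}),
    "skin": (1.09, {"H": 0.100, "C": 0.204, "N": 0.042, "O": 0.645,
                    "Na": 0.002, "P": 0.001, "S": 0.002, "Cl": 0.003,
                    "K": 0.001}),
    "soft_tissue": (1.06, {"H": 0.102, "C": 0.143, "N": 0.034, "O": 0.708,
                           "Na": 0.002, "P": 0.003, "S": 0.003, "Cl": 0.002,
                           "K": 0.003}),
}

#: reference densities for the packaged pure-element tables (g/cm^3, NTP for
#: gases).  Elements resolve through :func:`get_material` too, mainly so that
#: mixture arithmetic can be cross-checked against the compound tables.
ELEMENT_DENSITIES: dict[str, float] = {
    "H": 8.375e-5, "C": 1.700, "N": 1.165e-3, "O": 1.332e-3,
    "Na": 0.971, "Mg": 1.740, "Al": 2.699, "Si": 2.330, "P": 2.200,
    "S": 2.000, "Cl": 2.995e-3, "Ar": 1.662e-3, "K": 0.862, "Ca": 1.550,
    "Fe": 7.874, "Cu": 8.960, "Pb": 11.35,
}

REGISTRY = tuple(COMPOSITIONS)  # canonical material names


class MaterialLookupError(KeyError):
    """Raised when a material name is not in the registry."""


@dataclass(frozen=True)
class Material:
    """A named material: mass density plus elemental mass composition."""

    name: str
    density: float  # g/cm^3
    composition: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError(f"density must be positive, got {self.density}")
        if not self.composition:
            raise ValueError("composition must list at least one element")
        total = sum(f for _, f in self.composition)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"mass fractions sum to {total}, expected 1")


@dataclass(frozen=True)
class AttenuationTable:
    """Tabulated mass attenuation coefficients on an ascending energy grid."""

    material: str
    energy_keV: np.ndarray
    mu_total: np.ndarray   # cm^2/g
    mu_en: np.ndarray      # cm^2/g
    mu_photo: np.ndarray
    mu_incoh: np.ndarray
    mu_coh: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.energy_keV) <= 0):
            raise ValueError("energy grid must be strictly ascending")
        for arr in (self.mu_total, self.mu_en, self.mu_photo,
                    self.mu_incoh, self.mu_coh):
            if np.any(arr <= 0):
                raise ValueError("all coefficients must be positive")
        partial_sum = self.mu_photo + self.mu_incoh + self.mu_coh
        if np.any(np.abs(partial_sum / self.mu_total - 1) > 0.02):
            raise ValueError("partial coefficients do not sum to total within 2%")


def _table_name(name: str) -> str:
    return name.lower()


@lru_cache(maxsize=None)
def get_table(name: str) -> AttenuationTable:
    """Load the packaged attenuation table for a material or element."""
    key = _resolve(name)
    ref = resources.files("scattershield.data") / f"{_table_name(key)}.csv"
    try:
        with ref.open("r") as fh:
            raw = np.genfromtxt(fh, delimiter=",", names=True)
    except FileNotFoundError as exc:  # pragma: no cover - packaging error
        raise MaterialLookupError(f"no packaged table for {key!r}") from exc
    return AttenuationTable(
        material=key,
        energy_keV=np.ascontiguousarray(raw["energy_keV"]),
        mu_total=np.ascontiguousarray(raw["mu_total"]),
        mu_en=np.ascontiguousarray(raw["mu_en"]),
        mu_photo=np.ascontiguousarray(raw["mu_photo"]),
        mu_incoh=np.ascontiguousarray(raw["mu_incoh"]),
        mu_coh=np.ascontiguousarray(raw["mu_coh"]),
    )


def _resolve(name: str) -> str:
    if name in COMPOSITIONS:
        return name
    if name in ELEMENT_DENSITIES:
        return name
    if name.lower() in COMPOSITIONS:
        return name.lower()
    raise MaterialLookupError(
        f"unknown material {name!r}; valid materials: {sorted(COMPOSITIONS)} "
        f"(element symbols {sorted(ELEMENT_DENSITIES)} also resolve)")


@lru_cache(maxsize=None)
def get_material(name: str) -> Material:
    """Return the registered :class:`Material` for ``name``.

    Repeated calls return the identical (cached, frozen) object.
    """
    key = _resolve(name)
    if key in COMPOSITIONS:
        density, comp = COMPOSITIONS[key]
        return Material(key, density, tuple(sorted(comp.items())))
    return Material(key, ELEMENT_DENSITIES[key], ((key, 1.0),))


def _check_range(energy_keV: np.ndarray) -> np.ndarray:
    e = np.asarray(energy_keV, dtype=float)
    if np.any(e < ENERGY_MIN_KEV) or np.any(e > ENERGY_MAX_KEV):
        raise ValueError(
            f"energy out of range [{ENERGY_MIN_KEV}, {ENERGY_MAX_KEV}] keV")
    return e


def _loglog_interp(e: np.ndarray, grid: np.ndarray, values: np.ndarray) -> np.ndarray:
    return np.exp(np.interp(np.log(e), np.log(grid), np.log(values)))


def lookup_mu(material: Material | str, energy_keV) -> np.ndarray | float:
    """Total mass attenuation coefficient mu/rho (cm^2/g) at ``energy_keV``."""
    return _lookup(material, energy_keV, "mu_total")


def lookup_mu_en(material: Material | str, energy_keV) -> np.ndarray | float:
    """Mass energy-absorption coefficient mu_en/rho (cm^2/g)."""
    return _lookup(material, energy_keV, "mu_en")


def _lookup(material, energy_keV, column: str):
    name = material.name if isinstance(material, Material) else material
    tab = get_table(name)
    e = _check_range(energy_keV)
    out = _loglog_interp(e, tab.energy_keV, getattr(tab, column))
    return float(out) if np.isscalar(energy_keV) else out


def mixture_mu(composition, energy_keV) -> np.ndarray | float:
    """Mass-fraction-weighted mu/rho for a list of (material, fraction) pairs."""
    comp = list(composition)
    total = sum(f for _, f in comp)
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"mass fractions sum to {total}, expected 1")
    out = sum(f * np.asarray(lookup_mu(m, energy_keV)) for m, f in comp)
    return float(out) if np.isscalar(energy_keV) else out


def interaction_probabilities(material: Material | str, energy_keV: float):
    """Branch probabilities (photoelectric, incoherent, coherent) at one energy.

    Proportional to the partial coefficients; normalised to sum to one.
    """
    name = material.name if isinstance(material, Material) else material
    tab = get_table(name)
    e = _check_range(energy_keV)
    parts = np.array([
        _loglog_interp(e, tab.energy_keV, tab.mu_photo),
        _loglog_interp(e, tab.energy_keV, tab.mu_incoh),
        _loglog_interp(e, tab.energy_keV, tab.mu_coh),
    ])
    probs = parts / parts.sum(axis=0)
    return tuple(float(p) for p in probs) if np.isscalar(energy_keV) else probs
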