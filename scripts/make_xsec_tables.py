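"""Regenerate the packaged photon cross-section tables.

Builds per-element and per-material attenuation tables for the diagnostic
energy range (5-150 keV) and writes them as CSV files under
``src/scattershield/data/``.  The physics sources are:

* photoelectric: Cromer-Liberman anomalous scattering factor f'' (via gemmi),
  converted through the optical theorem  sigma_pe = 2 r_e lambda f'' ;
* incoherent: Klein-Nishina differential cross section integrated with the
  incoherent-scattering-function approximation S(q,Z) = Z [1 - (F(q)/Z)^2] ;
* coherent: Thomson differential cross section weighted by the squared
  International Tables (IT92) atomic form factor;
* mass energy-absorption: photoelectric + incoherent x Klein-Nishina mean
  energy-transfer fraction (radiative losses and fluorescence escape are
  neglected, a stated approximation at these energies).

The total is the sum of the three partials, so the partials-sum-to-total
invariant holds exactly.  Run ``python scripts/make_xsec_tables.py --check``
to compare the generated tables against published NIST reference anchors.
"""

from __future__ import annotations

import argparse
import math
from pathlib import Path

import gemmi
import numpy as np

R_E_CM = 2.8179403262e-13  # classical electron radius, cm
HC_KEV_A = 12.398419843320026  # h*c in keV * Angstrom
MEC2_KEV = 510.99895  # electron rest energy, keV
N_AVOGADRO = 6.02214076e23

DATA_DIR = Path(__file__).resolve().parents[1] / "src" / "scattershield" / "data"

ELEMENTS = ["H", "C", "N", "O", "Na", "Mg", "Al", "Si", "P", "S",
            "Cl", "Ar", "K", "Ca", "Fe", "Cu", "Pb"]

# Absorption edges (keV) that fall inside [5, 150] for the elements above.
EDGES_KEV = {
    "Fe": [7.112],
    "Cu": [8.979],
    "Pb": [13.0352, 15.2000, 15.8608, 88.0045],
}

# Densities and elemental mass compositions come from the package registry so
# the tables and the runtime library cannot drift apart.
import sys

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
from scattershield.materials import COMPOSITIONS as MATERIALS  # noqa: E402

# Published NIST (XCOM / Hubbell-Seltzer) reference anchors, cm^2/g.
NIST_ANCHORS_TOTAL = {
    "water": {10: 5.329, 15: 1.673, 20: 0.8096, 30: 0.3756, 40: 0.2683,
              50: 0.2269, 60: 0.2059, 80: 0.1837, 100: 0.1707, 150: 0.1505},
    "air": {10: 5.120, 20: 0.7779, 30: 0.3538, 50: 0.2080, 60: 0.1875,
            80: 0.1662, 100: 0.1541, 150: 0.1356},
    "aluminum": {10: 26.23, 20: 3.441, 30: 1.128, 50: 0.3681, 60: 0.2778,
                 80: 0.2018, 100: 0.1704, 150: 0.1378},
    "copper": {10: 215.9, 20: 33.79, 30: 10.92, 50: 2.613, 60: 1.593,
               80: 0.7630, 100: 0.4584, 150: 0.2217},
    "lead": {10: 130.6, 20: 86.36, 30: 30.32, 40: 14.36, 50: 8.041,
             60: 5.021, 80: 2.419, 100: 5.549, 150: 2.014},
}
NIST_ANCHORS_MUEN = {
    "water": {10: 4.944, 20: 0.5503, 30: 0.1557, 50: 0.04223, 60: 0.03190,
              80: 0.02583, 100: 0.02546, 150: 0.02764},
    "air": {10: 4.742, 20: 0.5389, 30: 0.1537, 50: 0.04098, 60: 0.03041,
            80: 0.02407, 100: 0.02325, 150: 0.02496},
}


def energy_grid(symbol: str | None = None, n_log: int = 62) -> np.ndarray:
    grid = set(np.geomspace(5.0, 150.0, n_log).tolist())
    grid.update([5.0, 150.0])
    edges = EDGES_KEV.get(symbol, []) if symbol else sorted(
        e for lst in EDGES_KEV.values() for e in lst)
    for e in edges:
        grid.update([e * (1 - 2e-4), e * (1 + 2e-4)])
    return np.array(sorted(grid))


STOL_MAX = 2.0  # 1/Angstrom; IT92 fit validity limit


def it92_form_factor(symbol: str, q_inv_a: np.ndarray) -> np.ndarray:
    """Atomic form factor F(q) from the IT92 4-Gaussian fit; q in 1/Angstrom.

    Beyond the fit's validity range (sin theta / lambda > 2 1/A) the value is
    continued with a hydrogen-like 1s falloff so the high-q tail decays
    physically instead of following the fit's constant term.
    """
    el = gemmi.Element(symbol)
    coef = el.it92
    stol = q_inv_a / (4 * math.pi)
    stol_c = np.minimum(stol, STOL_MAX)
    f = np.full_like(q_inv_a, coef.c, dtype=float)
    for a, b in zip(coef.a, coef.b):
        f += a * np.exp(-b * stol_c ** 2)
    f = np.maximum(f, 0.0)
    # hydrogenic damping of the tail: F_1s(q) = (1 + (q a_z / 2)^2)^-2
    a_z = 0.529177 / max(el.atomic_number - 0.3, 1.0)  # Angstrom
    q_tail = 4 * math.pi * stol
    q_edge = 4 * math.pi * STOL_MAX
    damp = ((1 + (q_edge * a_z / 2) ** 2) / (1 + (q_tail * a_z / 2) ** 2)) ** 2
    return np.where(stol > STOL_MAX, f * damp, f)


def klein_nishina_dcs(e_kev: float, cos_t: np.ndarray) -> np.ndarray:
    """d(sigma)/d(Omega) per electron, cm^2/sr (free electron)."""
    k = e_kev / MEC2_KEV
    ratio = 1.0 / (1.0 + k * (1.0 - cos_t))  # E'/E
    return 0.5 * R_E_CM ** 2 * ratio ** 2 * (ratio + 1.0 / ratio - (1 - cos_t ** 2))


def element_cross_sections(symbol: str, energies: np.ndarray):
    """Return (photo, incoh, coh, f_transfer) mass coefficients in cm^2/g."""
    el = gemmi.Element(symbol)
    z, a_mass = el.atomic_number, el.weight
    atoms_per_g = N_AVOGADRO / a_mass

    n_theta = 2000
    theta = np.linspace(0.0, math.pi, n_theta)
    cos_t = np.cos(theta)
    sin_t = np.sin(theta)

    photo = np.empty_like(energies)
    incoh = np.empty_like(energies)
    coh = np.empty_like(energies)
    f_tr = np.empty_like(energies)
    for i, e in enumerate(energies):
        _, fpp = gemmi.cromer_liberman(z=z, energy=float(e) * 1e3)
        lam_cm = HC_KEV_A / e * 1e-8
        # floor keeps every packaged coefficient strictly positive (hydrogen's
        # photoelectric term underflows the Cromer-Liberman fit at high energy)
        photo[i] = max(2.0 * R_E_CM * lam_cm * fpp * atoms_per_g, 1e-12)

        # momentum transfer q = (4 pi / lambda) sin(theta/2), 1/Angstrom
        q = 4 * math.pi / (HC_KEV_A / e) * np.sin(theta / 2)
        form = it92_form_factor(symbol, q)

        kn = klein_nishina_dcs(e, cos_t)
        s_incoh = z * (1.0 - np.clip(form / z, 0.0, 1.0) ** 2)
        sigma_incoh = 2 * math.pi * np.trapezoid(kn * s_incoh * sin_t, theta)
        incoh[i] = sigma_incoh * atoms_per_g

        thomson = 0.5 * R_E_CM ** 2 * (1 + cos_t ** 2)
        sigma_coh = 2 * math.pi * np.trapezoid(thomson * form ** 2 * sin_t, theta)
        coh[i] = sigma_coh * atoms_per_g

        # mean Klein-Nishina energy-transfer fraction (free electron)
        kk = e / MEC2_KEV
        ratio = 1.0 / (1.0 + kk * (1.0 - cos_t))
        sigma_kn = 2 * math.pi * np.trapezoid(kn * sin_t, theta)
        sigma_tr = 2 * math.pi * np.trapezoid(kn * (1 - ratio) * sin_t, theta)
        f_tr[i] = sigma_tr / sigma_kn
    return photo, incoh, coh, f_tr


def build_tables() -> dict[str, np.ndarray]:
    tables = {}
    for sym in ELEMENTS:
        e = energy_grid(sym)
        photo, incoh, coh, f_tr = element_cross_sections(sym, e)
        mu_en = photo + incoh * f_tr
        total = photo + incoh + coh
        tables[sym] = np.column_stack([e, total, mu_en, photo, incoh, coh])
    # materials on the union grid of their elements via mass-fraction additivity
    for name, (_, comp) in MATERIALS.items():
        e = energy_grid(None)
        cols = np.zeros((len(e), 4))
        for sym, frac in comp.items():
            tab = tables[sym]
            for j, col in enumerate([2, 3, 4, 5]):
                y = np.exp(np.interp(np.log(e), np.log(tab[:, 0]),
                                     np.log(np.maximum(tab[:, col], 1e-12))))
                cols[:, j] += frac * y
        mu_en, photo, incoh, coh = cols.T
        total = photo + incoh + coh
        tables[name] = np.column_stack([e, total, mu_en, photo, incoh, coh])
    return tables


def write_tables(tables: dict[str, np.ndarray]) -> None:
    DATA_DIR.mkdir(parents=True, exist_ok=True)
    header = "energy_keV,mu_total,mu_en,mu_photo,mu_incoh,mu_coh"
    for name, tab in tables.items():
        path = DATA_DIR / f"{name.lower()}.csv"
        np.savetxt(path, tab, delimiter=",", header=header, comments="",
                   fmt="%.4e")
    print(f"wrote {len(tables)} tables to {DATA_DIR}")


def check_anchors(tables: dict[str, np.ndarray]) -> int:
    bad = 0
    for name, anchors in NIST_ANCHORS_TOTAL.items():
        tab = tables[name]
        for e_ref, mu_ref in anchors.items():
            mu = np.exp(np.interp(math.log(e_ref), np.log(tab[:, 0]),
                                  np.log(tab[:, 1])))
            err = mu / mu_ref - 1
            flag = "" if abs(err) < (0.05 if name == "lead" else 0.02) else "  <-- off"
            bad += bool(flag)
            print(f"{name:9s} total {e_ref:5.0f} keV: {mu:9.4f} vs {mu_ref:9.4f} ({err:+.2%}){flag}")
    for name, anchors in NIST_ANCHORS_MUEN.items():
        tab = tables[name]
        for e_ref, mu_ref in anchors.items():
            mu = np.exp(np.interp(math.log(e_ref), np.log(tab[:, 0]),
                                  np.log(tab[:, 2])))
            err = mu / mu_ref - 1
            flag = "" if abs(err) < 0.05 else "  <-- off"
            bad += bool(flag)
            print(f"{name:9s} mu_en {e_ref:5.0f} keV: {mu:9.4f} vs {mu_ref:9.4f} ({err:+.2%}){flag}")
    return bad


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--check", action="store_true", help="compare against NIST anchors")
    args = ap.parse_args()
    tables = build_tables()
    if args.check:
        n_bad = check_anchors(tables)
        print(f"{n_bad} anchor(s) outside tolerance")
    write_tables(tables)
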