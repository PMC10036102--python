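"""Photon-only Monte Carlo transport through a voxel scene.

Electron transport is suppressed: all transferred energy deposits in the
interaction voxel (kerma approximation) and no fluorescence is emitted,
matching the simulated tube's 80 kVp endpoint, which lies below the lead
K-edge.  Interactions are photoelectric absorption, free-electron
Klein-Nishina Compton scattering and Thomson-law coherent scattering; the
default low-energy cutoff is 5 keV.

The production path is the numba kernel in :mod:`scattershield._kernels`
driven by :func:`run_histories`.  The module-level operations on
:class:`PhotonState` (``woodcock_flight``, ``compton_scatter``, ...) are a
plain-Python reference implementation of the same physics used for oracle
tests and optional trajectory logging.

Reproducibility contract: results depend only on the run seed and the
configuration, never on scheduling; batch b draws from an independent
deterministic substream of the run seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .materials import (get_table, interaction_probabilities, lookup_mu,
                        lookup_mu_en)
from .scene import SourceGeometry, VoxelScene
from .spectrum import Spectrum, sample_energy

MEC2_KEV = 510.99895
E_FINE_MIN = 5.0
E_FINE_MAX = 150.0
E_FINE_STEP = 0.5
MAJORANT_EBIN_KEV = 5.0


@dataclass(frozen=True)
class RunConfig:
    """Histories, batching, seed and cutoff for one transport run."""

    n_histories: int
    n_batches: int = 10
    seed: int = 0
    cutoff_keV: float = 5.0
    path_logging: bool = False
    max_interactions: int = 10_000

    def __post_init__(self) -> None:
        if not self.n_histories >= self.n_batches >= 2:
            raise ValueError("need n_histories >= n_batches >= 2")


@dataclass
class PhotonState:
    """One photon history in flight."""

    position: np.ndarray
    direction: np.ndarray
    energy: float
    weight: float = 1.0
    alive: bool = True

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if abs(n - 1.0) > 1e-9:
            raise ValueError("direction must be a unit vector")
        self.direction = d / n
        if self.weight <= 0:
            raise ValueError("weight must be positive")


# --------------------------------------------------------------------------
# reference (pure-Python) physics operations


def sample_interaction(material, energy_keV: float, rng: np.random.Generator) -> str:
    """Draw an interaction branch per the partial attenuation coefficients."""
    p_photo, p_incoh, _ = interaction_probabilities(material, energy_keV)
    r = rng.random()
    if r < p_photo:
        return "photoelectric"
    if r < p_photo + p_incoh:
        return "incoherent"
    return "coherent"


def _rotate_direction(d: np.ndarray, cos_t: float, phi: float) -> np.ndarray:
    u, v, w = d
    sin_t = math.sqrt(max(0.0, 1 - cos_t ** 2))
    if abs(w) > 1 - 1e-12:
        nd = np.array([sin_t * math.cos(phi), sin_t * math.sin(phi),
                       cos_t if w > 0 else -cos_t])
    else:
        den = math.sqrt(1 - w ** 2)
        nd = np.array([
            u * cos_t + sin_t * (u * w * math.cos(phi) - v * math.sin(phi)) / den,
            v * cos_t + sin_t * (v * w * math.cos(phi) + u * math.sin(phi)) / den,
            w * cos_t - sin_t * den * math.cos(phi)])
    return nd / np.linalg.norm(nd)


def sample_klein_nishina(energy_keV: float, rng: np.random.Generator):
    """Kahn composition-rejection sampling of the Compton cosine.

    Returns (cos_theta, scattered energy in keV).
    """
    k = energy_keV / MEC2_KEV
    while True:
        r1, r2, r3 = rng.random(3)
        if r1 * (9 + 2 * k) <= 1 + 2 * k:
            x = 1 + 2 * k * r2
            if r3 <= 4 * (1 / x - 1 / x ** 2):
                break
        else:
            x = (1 + 2 * k) / (1 + 2 * k * r2)
            cos_t = 1 - (x - 1) / k
            if r3 <= 0.5 * (cos_t ** 2 + 1 / x):
                break
    return 1 - (x - 1) / k, energy_keV / x


def compton_scatter(photon: PhotonState, rng: np.random.Generator,
                    cutoff_keV: float = 5.0) -> float:
    """Klein-Nishina scatter; returns locally deposited energy (keV)."""
    if not photon.alive:
        raise ValueError("photon is dead")
    cos_t, e_prime = sample_klein_nishina(photon.energy, rng)
    phi = 2 * math.pi * rng.random()
    if e_prime < cutoff_keV:
        deposited = photon.energy
        photon.alive = False
        photon.energy = 0.0
        return deposited
    deposited = photon.energy - e_prime
    photon.energy = e_prime
    photon.direction = _rotate_direction(photon.direction, cos_t, phi)
    return deposited


def photoelectric_absorb(photon: PhotonState) -> float:
    """Full local absorption (no fluorescence); kills the photon."""
    if not photon.alive:
        raise ValueError("photon is dead")
    deposited = photon.energy
    photon.energy = 0.0
    photon.alive = False
    return deposited


def rayleigh_scatter(photon: PhotonState, rng: np.random.Generator) -> None:
    """Coherent scatter: Thomson angular law, no energy change or deposit."""
    if not photon.alive:
        raise ValueError("photon is dead")
    while True:
        mu = 2 * rng.random() - 1
        if rng.random() * 2 <= 1 + mu * mu:
            break
    photon.direction = _rotate_direction(photon.direction, mu, 2 * math.pi * rng.random())


@dataclass(frozen=True)
class FlightOutcome:
    """Result of one Woodcock flight: an interaction site or an escape."""

    escaped: bool
    position: np.ndarray | None = None
    voxel: tuple[int, int, int] | None = None


def woodcock_flight(photon: PhotonState, scene: VoxelScene,
                    rng: np.random.Generator) -> FlightOutcome:
    """Delta-tracking flight against the scene's global energy majorant.

    Reference implementation: free paths are sampled from the maximum linear
    attenuation over all scene materials at the photon energy; virtual
    collisions are rejected with probability 1 - mu_local/mu_majorant.  The
    scene is bounded by vacuum: leaving the grid is an escape.
    """
    if not photon.alive:
        raise ValueError("photon is dead")
    if not np.all(np.isfinite(photon.position)) or not np.isfinite(photon.energy):
        raise FloatingPointError("corrupted photon state")
    e = photon.energy
    mu_ids = np.array([0.0 if name == "vacuum" else lookup_mu(name, e) * rho * 100.0
                       for name, rho in scene.registry])  # 1/m
    mu_maj = mu_ids.max()
    pos = photon.position.copy()
    d = photon.direction
    lo = scene.origin
    hi = scene.origin + scene.spacing * np.array(scene.dims)
    for _ in range(10_000_000):
        pos = pos + d * (-math.log(rng.random()) / mu_maj)
        if np.any(pos < lo) or np.any(pos >= hi):
            photon.position = pos
            return FlightOutcome(escaped=True)
        idx = tuple(((pos - lo) / scene.spacing).astype(int))
        mu_loc = mu_ids[scene.materials[idx]]
        if rng.random() * mu_maj <= mu_loc:
            photon.position = pos
            return FlightOutcome(escaped=False, position=pos, voxel=idx)
    raise FloatingPointError("flight exceeded the step cap")


# --------------------------------------------------------------------------
# compiled scene physics + batch driver


@dataclass
class ScenePhysics:
    """Fine-grid attenuation tables and majorant mesh for one scene."""

    e_fine: np.ndarray
    mu_fine: np.ndarray        # (n_ids, nE) linear attenuation, 1/m
    cum_photo: np.ndarray      # (n_ids, nE) photoelectric branch CDF
    cum_pi: np.ndarray         # (n_ids, nE) photo + incoherent branch CDF
    muen_fine: np.ndarray      # (n_ids, nE) mass energy-absorption, cm^2/g
    muen_air_fine: np.ndarray  # (nE,) mass energy-absorption of air, cm^2/g
    maj: np.ndarray            # (mx,my,mz,neb) float32 majorant, 1/m
    maj_origin: np.ndarray
    maj_spacing: np.ndarray


def compile_physics(scene: VoxelScene, cell_m: float = 0.05) -> ScenePhysics:
    """Precompute per-material fine-energy tables and the cell majorant mesh.

    The majorant of a cell is the maximum linear attenuation over the
    materials present in the cell and its face/corner neighbours (so voxels
    straddling a cell boundary cannot beat the majorant), maximised over each
    coarse energy bin.
    """
    e_fine = np.arange(E_FINE_MIN, E_FINE_MAX + E_FINE_STEP / 2, E_FINE_STEP)
    n_ids = len(scene.registry)
    mu_fine = np.empty((n_ids, len(e_fine)))
    cum_photo = np.empty_like(mu_fine)
    cum_pi = np.empty_like(mu_fine)
    muen_fine = np.empty_like(mu_fine)
    for i, (name, rho) in enumerate(scene.registry):
        if name == "vacuum":
            mu_fine[i] = 1e-10
            cum_photo[i] = 1.0
            cum_pi[i] = 1.0
            muen_fine[i] = 0.0
            continue
        tab = get_table(name)
        loge = np.log(e_fine)

        def interp(col):
            return np.exp(np.interp(loge, np.log(tab.energy_keV), np.log(col)))

        photo, incoh, coh = interp(tab.mu_photo), interp(tab.mu_incoh), interp(tab.mu_coh)
        total = photo + incoh + coh
        mu_fine[i] = total * rho * 100.0
        cum_photo[i] = photo / total
        cum_pi[i] = (photo + incoh) / total
        muen_fine[i] = interp(tab.mu_en)
    muen_air_fine = np.asarray(lookup_mu_en("air", e_fine))

    # majorant mesh
    extent = scene.spacing * np.array(scene.dims)
    mdims = np.maximum(np.ceil(extent / cell_m - 1e-9).astype(int), 1)
    msp = extent / mdims
    ncells = int(np.prod(mdims))
    centers = [scene.voxel_centers(a) for a in range(3)]
    ci = [np.clip(((centers[a] - scene.origin[a]) / msp[a]).astype(int),
                  0, mdims[a] - 1) for a in range(3)]
    cell_idx = (ci[0][:, None, None] * mdims[1] + ci[1][None, :, None]) \
        * mdims[2] + ci[2][None, None, :]
    combined = scene.materials.astype(np.int64) * ncells + cell_idx
    present = np.bincount(combined.ravel(), minlength=n_ids * ncells) > 0
    present = present.reshape(n_ids, *mdims)
    # dilate presence so neighbouring-cell overlap stays conservative
    reach = int(np.ceil(scene.spacing.max() / msp.min()))
    for _ in range(max(reach, 1)):
        for axis in range(1, 4):
            p = present
            present = p | np.roll(p, 1, axis=axis) | np.roll(p, -1, axis=axis)
            # np.roll wraps; wrapped cells only ever add extra materials,
            # which keeps the majorant conservative
    eb_edges = np.arange(E_FINE_MIN, E_FINE_MAX + MAJORANT_EBIN_KEV, MAJORANT_EBIN_KEV)
    neb = len(eb_edges) - 1
    mu_bin_max = np.empty((n_ids, neb))
    for b in range(neb):
        sel = (e_fine >= eb_edges[b] - E_FINE_STEP) & (e_fine <= eb_edges[b + 1] + E_FINE_STEP)
        mu_bin_max[:, b] = mu_fine[:, sel].max(axis=1)
    maj = np.zeros((*mdims, neb), dtype=np.float32)
    flat_present = present.reshape(n_ids, ncells)
    for b in range(neb):
        vals = np.where(flat_present, mu_bin_max[:, b][:, None], 0.0)
        maj[..., b] = (vals.max(axis=0) * 1.0001).reshape(mdims)
    maj = np.maximum(maj, 1e-8)
    return ScenePhysics(e_fine=e_fine, mu_fine=mu_fine, cum_photo=cum_photo,
                        cum_pi=cum_pi, muen_fine=muen_fine,
                        muen_air_fine=muen_air_fine, maj=maj,
                        maj_origin=scene.origin.copy(), maj_spacing=msp)


@dataclass
class TransportResult:
    """Per-batch tallies and energy accounting for one run."""

    body_batches: np.ndarray      # (nb, nx, ny, nz) float32, keV deposits
    kerma_batches: np.ndarray     # (nb, nx, ny, nz) float32, collision kerma
    air_batches: np.ndarray       # (nb, mx, my, mz) float32, track-length kerma
    n_per_batch: np.ndarray
    emitted: np.ndarray
    deposited: np.ndarray
    escaped: np.ndarray
    corrupted_energy: np.ndarray
    n_corrupted: int
    n_virtual: int
    n_real: int
    n_escaped_uncollided: int = 0
    air_origin: np.ndarray = None
    air_spacing: np.ndarray = None
    paths: list | None = None

    @property
    def n_histories(self) -> int:
        return int(self.n_per_batch.sum())

    def energy_balance(self) -> np.ndarray:
        """(emitted - deposited - escaped - corrupted) / emitted, per batch."""
        return (self.emitted - self.deposited - self.escaped
                - self.corrupted_energy) / self.emitted


def batch_seeds(seed: int, n_batches: int):
    """Independent, reproducible per-batch substreams of the run seed."""
    root = np.random.SeedSequence(seed)
    children = root.spawn(n_batches)
    kernel_seeds = [int(c.generate_state(1)[0] % (2 ** 31)) for c in children]
    rngs = [np.random.default_rng(c) for c in children]
    return kernel_seeds, rngs


def run_histories(run: RunConfig, scene: VoxelScene, spectrum: Spectrum,
                  source: SourceGeometry, physics: ScenePhysics | None = None,
                  air_cell_m: float = 0.05) -> TransportResult:
    """Transport ``run.n_histories`` source photons; tally per batch.

    Photons start at the source focal point with directions uniform over the
    collimated field and energies drawn from the spectrum.  Analog energy
    deposits are scored on the scene grid; track-length collision kerma is
    scored on the coarse air-map mesh.
    """
    if run.n_histories < 1:
        raise ValueError("need at least one history")
    phys = physics if physics is not None else compile_physics(scene, air_cell_m)
    nb = run.n_batches
    counts = np.full(nb, run.n_histories // nb)
    counts[: run.n_histories % nb] += 1
    kernel_seeds, rngs = batch_seeds(run.seed, nb)

    body_batches = np.empty((nb, *scene.dims), dtype=np.float32)
    kerma_batches = np.empty((nb, *scene.dims), dtype=np.float32)
    mdims = phys.maj.shape[:3]
    air_batches = np.empty((nb, *mdims), dtype=np.float32)
    emitted = np.empty(nb)
    deposited = np.empty(nb)
    escaped = np.empty(nb)
    corrupted_e = np.empty(nb)
    n_corr = n_virt = n_real = n_unc = 0
    air_id = next((i for i, (nm, _) in enumerate(scene.registry) if nm == "air"), -1)

    for b in range(nb):
        n = int(counts[b])
        rng = rngs[b]
        energies = sample_energy(spectrum, rng, n)
        dirs = source.sample_directions(rng, n)
        edep = np.zeros(scene.dims, dtype=np.float64)
        kerma = np.zeros(scene.dims, dtype=np.float64)
        airmap = np.zeros(mdims, dtype=np.float64)
        out = _kernels.run_batch(
            kernel_seeds[b],
            float(source.position[0]), float(source.position[1]),
            float(source.position[2]),
            np.ascontiguousarray(dirs), np.ascontiguousarray(energies),
            scene.materials,
            float(scene.origin[0]), float(scene.origin[1]), float(scene.origin[2]),
            float(scene.spacing[0]), float(scene.spacing[1]), float(scene.spacing[2]),
            phys.mu_fine, phys.cum_photo, phys.cum_pi,
            E_FINE_MIN, E_FINE_STEP,
            phys.maj,
            float(phys.maj_origin[0]), float(phys.maj_origin[1]),
            float(phys.maj_origin[2]),
            float(phys.maj_spacing[0]), float(phys.maj_spacing[1]),
            float(phys.maj_spacing[2]),
            E_FINE_MIN, MAJORANT_EBIN_KEV,
            phys.muen_air_fine, airmap, edep, phys.muen_fine, kerma,
            run.cutoff_keV, run.max_interactions, air_id)
        emitted[b], deposited[b], escaped[b], corrupted_e[b], nc, nv, nr, nu = out
        n_corr += nc
        n_virt += nv
        n_real += nr
        n_unc += nu
        body_batches[b] = edep
        kerma_batches[b] = kerma
        air_batches[b] = airmap

    paths = None
    if run.path_logging:
        paths = log_paths(scene, spectrum, source,
                          np.random.default_rng(run.seed),
                          min(200, run.n_histories))
    return TransportResult(
        body_batches=body_batches, kerma_batches=kerma_batches,
        air_batches=air_batches,
        n_per_batch=counts, emitted=emitted, deposited=deposited,
        escaped=escaped, corrupted_energy=corrupted_e,
        n_corrupted=n_corr, n_virtual=n_virt, n_real=n_real,
        n_escaped_uncollided=n_unc,
        air_origin=phys.maj_origin, air_spacing=phys.maj_spacing,
        paths=paths)


def write_paths_jsonl(paths: list[dict], path) -> None:
    """Write trajectory polylines as JSON Lines (one history per line)."""
    import json

    with open(path, "w") as fh:
        for rec in paths:
            fh.write(json.dumps(rec) + "\n")


def log_paths(scene: VoxelScene, spectrum: Spectrum, source: SourceGeometry,
              rng: np.random.Generator, n: int) -> list[dict]:
    """Trace ``n`` histories with the reference tracker, recording polylines.

    Each record holds the history id, the vertex positions (m) and the photon
    energy (keV) entering each vertex, suitable for trajectory rendering.
    """
    records = []
    energies = sample_energy(spectrum, rng, n)
    dirs = source.sample_directions(rng, n)
    for i in range(n):
        p = PhotonState(source.position.copy(), dirs[i], float(energies[i]))
        verts = [p.position.copy()]
        evs = [p.energy]
        while p.alive:
            outcome = woodcock_flight(p, scene, rng)
            verts.append(p.position.copy())
            evs.append(p.energy)
            if outcome.escaped:
                break
            name, _ = scene.registry[scene.materials[outcome.voxel]]
            branch = sample_interaction(name, p.energy, rng)
            if branch == "photoelectric":
                photoelectric_absorb(p)
            elif branch == "incoherent":
                compton_scatter(p, rng)
            else:
                rayleigh_scatter(p, rng)
        records.append({"history": i,
                        "vertices": [list(map(float, v)) for v in verts],
                        "energies_keV": [float(e) for e in evs]})
    return records
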