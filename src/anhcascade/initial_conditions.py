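"""Nascent hot-ground-state occupation configurations.

Three generators are provided:

* projection of surface-hopping geometries onto the equilibrium normal
  modes, partitioning the released electronic energy into integer quanta;
* thermal configurations (independent per-mode Boltzmann/geometric draws),
  used both as stand-alone initial states and as the ambient-temperature
  augmentation added to hot configurations;
* rapid-exchange-limit statistical configurations drawn uniformly from all
  configurations inside a narrow total-energy band (IVR assumed complete
  before any energy leaves the molecule).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .constants import KB_CM1_PER_K, MW_ENERGY_CM1
from .muca_sampler import (
    EnergyWindow,
    proposal_scale,
    propose_config,
    validate_config,
)
from .vib_model import VibrationalSystem, total_energy

__all__ = [
    "ATOMIC_MASSES",
    "Geometry",
    "NormalModeSet",
    "HopRecord",
    "project_hop_occupations",
    "sample_thermal_config",
    "sample_statistical_configs",
]

#: standard atomic weights (amu) for the elements that occur in organic
#: chromophores; D is deuterium
ATOMIC_MASSES = {
    "H": 1.00794, "D": 2.014102, "He": 4.002602,
    "B": 10.811, "C": 12.0107, "N": 14.0067, "O": 15.9994, "F": 18.998403,
    "Na": 22.989769, "Mg": 24.305, "Si": 28.0855, "P": 30.973762,
    "S": 32.065, "Cl": 35.453, "K": 39.0983, "Ca": 40.078,
    "Br": 79.904, "I": 126.90447,
}


@dataclass
class Geometry:
    """Atom symbols, Cartesian coordinates (Angstrom) and masses (amu)."""

    symbols: list[str]
    coords: np.ndarray
    masses: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.symbols), 3):
            raise ValueError("coords must be (n_atoms, 3)")
        if self.masses is None:
            try:
                self.masses = np.array([ATOMIC_MASSES[s] for s in self.symbols])
            except KeyError as exc:
                raise ValueError(f"no mass for element {exc}") from exc
        else:
            self.masses = np.asarray(self.masses, dtype=float)
            if self.masses.shape != (len(self.symbols),):
                raise ValueError("masses length mismatch")

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)


@dataclass
class NormalModeSet:
    """Mass-weighted normal modes of a reference (equilibrium) geometry.

    ``vectors`` has shape (n_modes, 3*n_atoms); rows are orthonormal in the
    mass-weighted metric.
    """

    reference: Geometry
    frequencies: np.ndarray
    vectors: np.ndarray
    orthonormal_tol: float = 1e-6

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.vectors = np.asarray(self.vectors, dtype=float)
        nm = self.frequencies.size
        if self.vectors.shape != (nm, 3 * self.reference.n_atoms):
            raise ValueError("vectors must be (n_modes, 3*n_atoms)")
        if nm > 3 * self.reference.n_atoms - 6 and self.reference.n_atoms > 2:
            raise ValueError("more modes than 3N - 6")
        gram = self.vectors @ self.vectors.T
        if not np.allclose(gram, np.eye(nm), atol=self.orthonormal_tol):
            raise ValueError("mode vectors must be orthonormal")

    @property
    def n_modes(self) -> int:
        return self.frequencies.size


@dataclass
class HopRecord:
    """A surface-hopping snapshot and the electronic energy (cm^-1) released
    into the ground state there."""

    geometry: Geometry
    delta_e_elec: float

    def __post_init__(self) -> None:
        if self.delta_e_elec < 0:
            raise ValueError("delta_e_elec must be non-negative")


def _mass_weighted_displacement(ref: Geometry, hop: Geometry) -> np.ndarray:
    """Optimal rigid-body superposition (mass-weighted Kabsch), then the
    mass-weighted displacement vector sqrt(m) * dx, flattened to 3N."""
    if hop.symbols != ref.symbols:
        raise ValueError("hop geometry atoms must match the reference")
    m = ref.masses
    w = m / m.sum()
    ref_c = ref.coords - (w @ ref.coords)
    hop_c = hop.coords - (w @ hop.coords)
    rot, _ = Rotation.align_vectors(ref_c, hop_c, weights=m)
    dx = rot.apply(hop_c) - ref_c
    return (np.sqrt(m)[:, None] * dx).ravel()


def mode_displacements(
    modeset: NormalModeSet, hop: Geometry, superpose: bool = True
) -> np.ndarray:
    """Projections q_i (sqrt(amu)*Angstrom) of the hop displacement onto the
    normal vectors.

    With ``superpose`` (default) the hop geometry is first brought into
    optimal rigid-body coincidence with the reference, so overall rotation
    and translation cannot contaminate the projections; set it to False only
    for geometries already in the reference (Eckart) frame.
    """
    if superpose:
        delta = _mass_weighted_displacement(modeset.reference, hop)
    else:
        if hop.symbols != modeset.reference.symbols:
            raise ValueError("hop geometry atoms must match the reference")
        delta = (
            np.sqrt(modeset.reference.masses)[:, None]
            * (hop.coords - modeset.reference.coords)
        ).ravel()
    return modeset.vectors @ delta


def project_hop_occupations(
    modeset: NormalModeSet,
    hop: HopRecord,
    partition: str = "proportional",
) -> np.ndarray:
    """Integer occupations for one hop.

    Per-mode harmonic displacement energies e_i = MW_ENERGY_CM1 * nu_i^2
    q_i^2 define the partition weights.  ``proportional`` (default) splits
    delta_e_elec across modes proportionally to e_i and converts each share
    to quanta of nu_i with largest-remainder rounding, so that
    |sum n_i nu_i - delta_e_elec| <= max populated nu_i.  ``direct`` rounds
    e_i / nu_i per mode without renormalising to delta_e_elec.
    """
    q = mode_displacements(modeset, hop.geometry)
    nu = modeset.frequencies
    e_i = MW_ENERGY_CM1 * nu**2 * q**2
    if hop.delta_e_elec == 0:
        return np.zeros(modeset.n_modes, dtype=int)
    if partition == "direct":
        return np.floor(e_i / nu + 0.5).astype(int)
    if partition != "proportional":
        raise ValueError(f"unknown partition strategy {partition!r}")
    total = e_i.sum()
    if total <= 1e-9:  # displacement at machine-noise level
        raise ValueError(
            "hop geometry equals the reference: no direction to partition"
        )
    negligible = e_i < 1e-12 * total
    share = hop.delta_e_elec * e_i / total
    n = np.floor(share / nu).astype(int)
    frac = share / nu - n
    deficit = hop.delta_e_elec - float(n @ nu)
    for i in np.argsort(-frac):
        if negligible[i]:  # undisplaced modes never receive quanta
            continue
        if abs(deficit - nu[i]) < abs(deficit):
            n[i] += 1
            deficit -= nu[i]
    return n


def sample_thermal_config(
    system: VibrationalSystem, temperature: float, rng: np.random.Generator
) -> np.ndarray:
    """Independent per-mode Boltzmann draw, P(n_i) ~ exp(-n_i nu_i / kT).

    The harmonic (geometric-distribution) form; at ambient temperature and
    mid-IR frequencies the anharmonic correction to these weights is
    negligible, and the multicanonical path exists where exactness matters.
    """
    if temperature < 0:
        raise ValueError("temperature must be non-negative")
    if temperature == 0:
        return np.zeros(system.n_modes, dtype=int)
    p = 1.0 - np.exp(-system.nu / (KB_CM1_PER_K * temperature))
    return (rng.geometric(p) - 1).astype(int)


def sample_statistical_configs(
    system: VibrationalSystem,
    e_targets: np.ndarray,
    rng: np.random.Generator,
    tol: float = 16.0,
    n_burn: int = 2_000,
    stride: int = 50,
) -> list[np.ndarray]:
    """Rapid-exchange-limit configurations: one uniform draw from the
    configurations whose E_rel falls in the energy bin (width 2*tol) that
    contains each target.

    A band-confined walk would be reducible (single-quantum moves cannot
    connect most same-energy configurations without passing through other
    energies), so the draw reuses the multicanonical machinery over the
    window [0, band top): the flat-histogram stationary law is uniform
    within every energy bin, and the walk is recorded whenever it sits in
    the target's bin.
    """
    import math

    from .state_density import count_states

    if not tol > 0:
        raise ValueError("tol must be positive")
    out: list[np.ndarray] = []
    bw = 2.0 * tol
    for target in np.atleast_1d(np.asarray(e_targets, dtype=float)):
        if target <= 0:
            raise ValueError("target energies must be positive")
        band_bin = int(math.floor(target / bw))
        e_hi = (band_bin + 1) * bw
        window = EnergyWindow(0.0, e_hi, bw)
        dos = count_states(system, e_hi, bw, grain=min(1.0, bw))
        if dos.rho(target) == 0:
            raise ValueError(
                f"energy band around {target:.1f} cm^-1 holds no states"
            )
        n = np.zeros(system.n_modes, dtype=int)
        e = total_energy(system, n)
        scale = proposal_scale(system.n_modes, 1.0)
        draw: np.ndarray | None = None
        step = 0
        hits = 0
        max_steps = 200 * (n_burn + stride) + 10_000
        while step < max_steps:
            step += 1
            prop, log_fwd, log_rev = propose_config(n, 1.0, rng, scale)
            if validate_config(system, prop, window):
                e_prop = total_energy(system, prop)
                rho_cur, rho_prop = dos.rho(e), dos.rho(e_prop)
                if rho_prop > 0 and (
                    rho_cur == 0
                    or np.log(rho_cur) - np.log(rho_prop) + (log_rev - log_fwd)
                    >= np.log(max(rng.random(), 1e-300))
                ):
                    n, e = prop, e_prop
            if window.bin_of(e) == band_bin:
                hits += 1
                if hits >= n_burn and hits % stride == 0:
                    draw = n.copy()
                    break
        if draw is None:
            raise ValueError(
                f"energy band around {target:.1f} cm^-1 was not reached; "
                "is it dynamically accessible?"
            )
        out.append(draw)
    return out
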