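"""Kinetic Monte Carlo simulation of vibrational cooling to an isothermal
bath, producing time-dependent IR spectra.

Per time step dt each mode may lose or gain one quantum by exchange with the
solvent bath.  The per-mode proposal probabilities are

    p_down,i = q_i n_i nu_i dt
    p_up,i   = q_i (n_i + 1) nu_i dt exp(-nu_i / k_B T_bath)

with nu_i dt made dimensionless through the speed of light (nu[cm^-1] * c *
dt[fs]).  q is the single adjustable rate-scaling parameter of the cascade
model; it affects only the clock, not the transient spectral shapes, and can
be overridden per mode.  The Boltzmann factor on the upward rate encodes the
isothermal bath; in the harmonic limit these proposal rates alone satisfy
detailed balance with the Bose-Einstein occupation 1/(e^{nu/kT} - 1).

Three acceptance conventions are provided for the single-quantum moves:
``as_printed`` (min[1, e^{-(E - E_prop)/kT}]), ``metropolis``
(min[1, e^{-(E_prop - E)/kT}]) and ``none`` (always accept).  ``none`` is
the convention whose stationary state in the harmonic limit is exactly the
300 K thermal distribution, and is the one used by the cooling
demonstrations; see the methods note for the discussion.  Configurations are
deliberately *not* confined to the valid range of the Dunham expansion:
projected nascent hot configurations may start outside it and must be able
to relax.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .constants import C_CM_PER_FS, KB_CM1_PER_K
from .muca_sampler import SpectralMatrix
from .vib_model import (
    GroundTransitions,
    VibrationalSystem,
    ground_transitions,
    stick_arrays,
    total_energy,
)

__all__ = [
    "KmcParams",
    "Trajectory",
    "step_probabilities",
    "kmc_step",
    "run_trajectory",
    "ensemble_spectra",
    "ensemble_energy",
]

ACCEPTANCE_MODES = ("as_printed", "metropolis", "none")


@dataclass
class KmcParams:
    """Cooling-simulation controls.

    q : global dimensionless rate scaling (the model's one adjustable knob)
    q_i : optional per-mode overrides (length N)
    dt : time step in fs
    t_max : total simulated time in fs
    T_bath : bath temperature in K (isothermal bath approximation)
    acceptance_mode : one of 'as_printed', 'metropolis', 'none'
    n_trajectories : trajectories averaged per initial configuration
    spectral_window, spectral_bin : wavenumber grid for the time rows
    """

    q: float = 0.1
    q_i: np.ndarray | None = None
    dt: float = 5.0
    t_max: float = 10_000.0
    T_bath: float = 300.0
    acceptance_mode: str = "as_printed"
    n_trajectories: int = 576
    spectral_window: tuple[float, float] = (1350.0, 1850.0)
    spectral_bin: float = 2.0

    def __post_init__(self) -> None:
        if not self.q > 0:
            raise ValueError("q must be positive")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if self.t_max < 0:
            raise ValueError("t_max must be non-negative")
        if self.acceptance_mode not in ACCEPTANCE_MODES:
            raise ValueError(f"acceptance_mode must be one of {ACCEPTANCE_MODES}")
        if self.q_i is not None:
            self.q_i = np.asarray(self.q_i, dtype=float)

    def mode_rates(self, system: VibrationalSystem) -> np.ndarray:
        q = np.full(system.n_modes, self.q) if self.q_i is None else self.q_i
        if q.shape != (system.n_modes,):
            raise ValueError("q_i length mismatch")
        return q


@dataclass
class Trajectory:
    """Times (fs), per-step total energies (cm^-1) and the final
    configuration of one kMC run."""

    times: np.ndarray
    energies: np.ndarray
    final_config: np.ndarray


def step_probabilities(
    system: VibrationalSystem, config: np.ndarray, params: KmcParams
) -> tuple[np.ndarray, np.ndarray]:
    """Per-mode (p_down, p_up) proposal probabilities for one time step.

    Probabilities exceeding 1 are clipped with a warning (dt too large for
    that mode's rate).
    """
    n = np.asarray(config, dtype=float)
    q = params.mode_rates(system)
    nu = system.nu
    nudt = nu * C_CM_PER_FS * params.dt
    kt = KB_CM1_PER_K * params.T_bath
    p_down = q * n * nudt
    p_up = q * (n + 1.0) * nudt * np.exp(-nu / kt)
    if np.any(p_down + p_up > 1.0):
        warnings.warn(
            "per-mode proposal probability exceeds 1 (dt too large); clipping",
            RuntimeWarning,
            stacklevel=2,
        )
        excess = p_down + p_up
        scale = np.where(excess > 1.0, 1.0 / excess, 1.0)
        p_down, p_up = p_down * scale, p_up * scale
    return p_down, p_up


def _single_mode_delta(
    system: VibrationalSystem, config: np.ndarray, i: int, sign: int
) -> float:
    """E(n + sign*e_i) - E(n) from the fundamental closed form (O(N))."""
    n = np.asarray(config, dtype=float)
    x = system.x_matrix
    xii = x[i, i]
    cross = float(x[i] @ (n + 0.5)) - xii * (n[i] + 0.5)
    if sign == +1:
        return float(system.nu[i] + 2.0 * xii * (n[i] + 1.0) + cross)
    # downward: -(dE_fund evaluated at n - e_i)
    return -float(system.nu[i] + 2.0 * xii * n[i] + cross)


def _accept(delta_e: float, kt: float, mode: str, rng: np.random.Generator) -> bool:
    """delta_e = E_prop - E for the proposed single-quantum move."""
    if mode == "none":
        return True
    if mode == "metropolis":
        log_p = -delta_e / kt
    else:  # as_printed: p_acc = e^{-(E - E_prop)/kT}
        log_p = delta_e / kt
    return log_p >= 0 or rng.random() < np.exp(log_p)


def kmc_step(
    system: VibrationalSystem,
    config: np.ndarray,
    params: KmcParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Advance one time step; returns the new configuration.

    Proposal draws use the step-start occupations; proposed single-quantum
    moves are then visited in random order, each accepted against the energy
    change of the *current* (possibly already updated) configuration.
    """
    n = np.asarray(config, dtype=int).copy()
    p_down, p_up = step_probabilities(system, n, params)
    u = rng.random(n.size)
    want_down = u < p_down
    want_up = (u >= p_down) & (u < p_down + p_up)
    idx = np.flatnonzero(want_down | want_up)
    if idx.size == 0:
        return n
    rng.shuffle(idx)
    kt = KB_CM1_PER_K * params.T_bath
    for i in idx:
        sign = -1 if want_down[i] else +1
        if sign == -1 and n[i] == 0:
            continue
        delta_e = _single_mode_delta(system, n, int(i), sign)
        if _accept(delta_e, kt, params.acceptance_mode, rng):
            n[i] += sign
    return n


def run_trajectory(
    system: VibrationalSystem,
    config0: np.ndarray,
    params: KmcParams,
    rng: np.random.Generator,
    ref: GroundTransitions | None = None,
    spectral_out: np.ndarray | None = None,
    record_energy: bool = True,
) -> Trajectory:
    """One cooling trajectory of ceil(t_max/dt) steps plus the t = 0 row.

    If ``spectral_out`` (n_rows x n_cols) is given, the current
    configuration's stick spectrum is accumulated into the row of each time
    step regardless of what was accepted (negative transition energies carry
    zero intensity by construction).
    """
    n = np.asarray(config0, dtype=int).copy()
    if n.shape != (system.n_modes,):
        raise ValueError("config0 length mismatch")
    n_rows = int(round(params.t_max / params.dt)) + 1
    times = np.arange(n_rows) * params.dt
    energies = np.zeros(n_rows) if record_energy else np.zeros(0)
    if ref is None and spectral_out is not None:
        ref = ground_transitions(system)
    lo, hi = params.spectral_window
    for s in range(n_rows):
        if record_energy:
            energies[s] = total_energy(system, n)
        if spectral_out is not None:
            pos, inten, _, _, _ = stick_arrays(system, n, ref)
            sel = (inten > 0) & (pos >= lo) & (pos < hi)
            if np.any(sel):
                cols = ((pos[sel] - lo) / params.spectral_bin).astype(int)
                np.add.at(spectral_out[s], cols, inten[sel])
        if s < n_rows - 1:
            n = kmc_step(system, n, params, rng)
    return Trajectory(times, energies, n)


def _spectral_grid(params: KmcParams) -> np.ndarray:
    lo, hi = params.spectral_window
    ncol = int(round((hi - lo) / params.spectral_bin))
    return lo + (np.arange(ncol) + 0.5) * params.spectral_bin


def ensemble_spectra(
    system: VibrationalSystem,
    initial_configs: list[np.ndarray],
    params: KmcParams,
    rng: np.random.Generator,
    thermal_augment: float | None = None,
    equilibrium_row: np.ndarray | None = None,
) -> SpectralMatrix:
    """Trajectory-averaged time-dependent spectral matrix.

    ``n_trajectories`` runs per initial configuration are averaged (and
    averaged over the initial-configuration set).  If ``thermal_augment`` is
    a temperature, a fresh thermal configuration is sampled per trajectory
    and added element-wise to the hot configuration.  If
    ``equilibrium_row`` is given it is subtracted from every row (difference
    spectra: hot absorption minus equilibrium bleach).
    """
    if not initial_configs:
        raise ValueError("need at least one initial configuration")
    from .initial_conditions import sample_thermal_config

    col_axis = _spectral_grid(params)
    n_rows = int(round(params.t_max / params.dt)) + 1
    values = np.zeros((n_rows, col_axis.size))
    ref = ground_transitions(system)
    total = 0
    for c0 in initial_configs:
        c0 = np.asarray(c0, dtype=int)
        for _ in range(params.n_trajectories):
            start = c0
            if thermal_augment is not None:
                start = c0 + sample_thermal_config(system, thermal_augment, rng)
            run_trajectory(
                system, start, params, rng, ref=ref,
                spectral_out=values, record_energy=False,
            )
            total += 1
    values /= total
    if equilibrium_row is not None:
        values = values - np.asarray(equilibrium_row)[None, :]
    times = np.arange(n_rows) * params.dt
    return SpectralMatrix(times, col_axis, values, np.full(n_rows, total))


def ensemble_energy(
    system: VibrationalSystem,
    initial_configs: list[np.ndarray],
    params: KmcParams,
    rng: np.random.Generator,
    thermal_augment: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Ensemble-mean total energy trace (times, <E>(t)); cheap diagnostic of
    the cooling to the thermal plateau."""
    if not initial_configs:
        raise ValueError("need at least one initial configuration")
    from .initial_conditions import sample_thermal_config

    n_rows = int(round(params.t_max / params.dt)) + 1
    acc = np.zeros(n_rows)
    total = 0
    for c0 in initial_configs:
        c0 = np.asarray(c0, dtype=int)
        for _ in range(params.n_trajectories):
            start = c0
            if thermal_augment is not None:
                start = c0 + sample_thermal_config(system, thermal_augment, rng)
            traj = run_trajectory(
                system, start, params, rng, spectral_out=None, record_energy=True
            )
            acc += traj.energies
            total += 1
    return np.arange(n_rows) * params.dt, acc / total
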