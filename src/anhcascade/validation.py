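"""End-to-end validation computations for the cascade framework.

Each function runs one self-contained numerical experiment — state-counting
against brute force, flat-histogram correctness, kinetic-Monte-Carlo
equilibrium and cooling phenomenology, kinetic-fit recovery — and returns
plain numbers.  They are used by the acceptance test suite and by
``scripts/acceptance.py``; problem sizes default to desk-scale settings
(documented in the methods note).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import band_analysis as ba
from . import kmc_cooling as kmc
from . import muca_sampler as mu
from . import state_density as sd
from .constants import KB_CM1_PER_K
from .synthetic_fixtures import (
    FixtureSpec,
    generate_hot_configs,
    make_cyan_like_system,
    make_harmonic_system,
    make_toy_anharmonic,
    rng_from_seed,
)
from .vib_model import total_energy

__all__ = [
    "state_count_agreement",
    "harmonic_closed_form_agreement",
    "muca_flat_histogram_check",
    "muca_canonical_deviation",
    "kmc_equilibrium_occupation",
    "CoolingSummary",
    "cooling_phenomenology",
    "fit_recovery",
    "determinism_check",
]


def state_count_agreement(
    n_systems: int = 20, seed: int = 0, e_max: float = 3000.0, bin_width: float = 16.0
) -> tuple[int, int]:
    """Compare the grained Stein-Rabinovitch count with exhaustive
    enumeration (binned identically) on random separable systems with up to
    4 modes; returns (n_matching, n_systems)."""
    matches = 0
    for k in range(n_systems):
        spec = FixtureSpec(
            n_modes=2 + (seed + k) % 3 + (k % 2),
            freq_range=(150.0, 1200.0),
            offdiag_scale=0.0,
            seed=seed * 1000 + k,
        )
        system = make_toy_anharmonic(spec)
        dos = sd.count_states(system, e_max, bin_width)
        expect = np.zeros(dos.n_bins, dtype=int)
        for _, e in sd.brute_force_states(system, e_max):
            expect[int(math.floor(e / bin_width + 1e-9))] += 1
        if [int(c) for c in dos.counts] == list(expect):
            matches += 1
    return matches, n_systems


def harmonic_closed_form_agreement(max_modes: int = 5, max_quanta: int = 10) -> tuple[int, int]:
    """Cumulative state count of N equal-frequency harmonic modes at E = m*nu
    against the stars-and-bars closed form C(m + N, N); returns
    (n_matching, n_cases)."""
    nu = 250.0
    cases = matches = 0
    for n_modes in range(1, max_modes + 1):
        system = make_harmonic_system([nu] * n_modes)
        dos = sd.count_states(
            system, max_quanta * nu + 0.5 * nu, bin_width=nu
        )
        for m in range(max_quanta + 1):
            cases += 1
            cumulative = sum(int(c) for c in dos.counts[: m + 1])
            if cumulative == math.comb(m + n_modes, n_modes):
                matches += 1
    return matches, cases


def _toy_for_muca() -> tuple:
    """3-mode toy with <= 200 enumerable states below the sampled ceiling."""
    system = make_toy_anharmonic(
        FixtureSpec(n_modes=3, freq_range=(300.0, 900.0), seed=7)
    )
    e_max = 1600.0
    return system, e_max


def muca_flat_histogram_check(seed: int = 0) -> tuple[bool, float]:
    """Run flat-histogram walks on the 3-mode toy; returns (all walks flat,
    combined within-bin uniformity p-value).

    The uniformity statistic pools per-bin chi-squared terms over thinned
    (approximately independent) visits on a diagonal-X companion system,
    for which the separable density is exact.
    """
    from scipy import stats

    system, e_max = _toy_for_muca()
    dos = sd.count_states(system, e_max, 16.0)
    window = mu.EnergyWindow(0.0, e_max, 16.0)
    params = mu.MucaParams(
        max_steps=300_000, check_every=500,
        spectral_window=(0.0, 2000.0), spectral_bin=4.0,
    )
    rng = rng_from_seed(seed)
    flat = all(
        mu.run_walk(system, window, params, dos, rng).flat for _ in range(3)
    )

    dense = make_toy_anharmonic(
        FixtureSpec(n_modes=3, freq_range=(120.0, 350.0),
                    diag_range=(-6.0, -2.0), offdiag_scale=0.0, seed=9)
    )
    dwin = mu.EnergyWindow(0.0, 1200.0, 100.0)
    ddos = sd.count_states(dense, 1200.0, 100.0)
    dparams = mu.MucaParams(
        max_steps=250_000, check_every=1_000_000,
        spectral_window=(0.0, 2000.0), spectral_bin=4.0,
    )
    visits: dict[tuple, int] = {}
    import warnings

    for k in range(2):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = mu.run_walk(
                dense, dwin, dparams, ddos, rng_from_seed(seed * 100 + 11 + k),
                track_configs=True, track_every=200,
            )
        for cfg, c in res.visits.items():
            visits[cfg] = visits.get(cfg, 0) + c
    by_bin: dict[int, list[int]] = {}
    for cfg, c in visits.items():
        b = dwin.bin_of(total_energy(dense, np.array(cfg)))
        by_bin.setdefault(b, []).append(c)
    chi_total, dof = 0.0, 0
    for counts in by_bin.values():
        if len(counts) >= 3 and sum(counts) >= 5 * len(counts):
            chi, _ = stats.chisquare(counts)
            chi_total += chi
            dof += len(counts) - 1
    p = float(stats.chi2.sf(chi_total, dof)) if dof else float("nan")
    return flat, p


def muca_canonical_deviation(seed: int = 0, temperature: float = 300.0) -> float:
    """Integrated absolute deviation (fraction of total intensity) between
    the Boltzmann-reweighted MUCA spectrum and the exact enumerated
    canonical average.

    Uses a low-frequency 3-mode toy whose excited states carry substantial
    thermal weight, so the comparison genuinely exercises the sampled
    per-bin averages rather than only the single-configuration ground bin.
    """
    system = make_toy_anharmonic(
        FixtureSpec(n_modes=3, freq_range=(120.0, 350.0),
                    diag_range=(-6.0, -2.0), offdiag_scale=0.3, seed=9)
    )
    e_max = 1200.0
    bw = 16.0
    dos = sd.count_states(system, e_max, bw)
    windows = [mu.EnergyWindow(0.0, 608.0, bw), mu.EnergyWindow(608.0, e_max, bw)]
    params = mu.MucaParams(
        n_walks=3, max_steps=300_000, check_every=500,
        spectral_window=(0.0, 2000.0), spectral_bin=4.0,
    )
    rng = rng_from_seed(seed)
    results = mu.run_windows(system, windows, params, dos, rng)
    spec = mu.assemble_canonical_spectrum(results, dos, temperature)

    from .vib_model import ground_transitions, stick_arrays

    w_bins = sd.boltzmann_weights(dos, temperature)
    lo, hi = params.spectral_window
    ncol = int(round((hi - lo) / params.spectral_bin))
    ref = ground_transitions(system)
    full = mu.EnergyWindow(0.0, e_max, bw)
    rows: dict[int, np.ndarray] = {}
    counts: dict[int, int] = {}
    for cfg, e in sd.brute_force_states(system, e_max):
        if not mu.validate_config(system, cfg, full):
            continue
        b = int(math.floor(e / bw + 1e-9))
        pos, inten, _, _, _ = stick_arrays(system, cfg, ref)
        row = np.zeros(ncol)
        sel = (inten > 0) & (pos >= lo) & (pos < hi)
        np.add.at(row, ((pos[sel] - lo) / params.spectral_bin).astype(int), inten[sel])
        rows[b] = rows.get(b, np.zeros(ncol)) + row
        counts[b] = counts.get(b, 0) + 1
    exact = np.zeros(ncol)
    norm = sum(w_bins[b] for b in rows)
    for b, row in rows.items():
        exact += (w_bins[b] / norm) * row / counts[b]
    return float(np.abs(spec.values - exact).sum() / exact.sum())


def kmc_equilibrium_occupation(
    seed: int = 0, n_steps: int = 1_000_000, nu: float = 500.0
) -> tuple[float, float, float]:
    """Time-averaged occupation of a single harmonic mode coupled to the
    300 K bath with acceptance_mode='none'; returns (mean, Bose-Einstein
    target, batch-means standard error)."""
    system = make_harmonic_system([nu])
    params = kmc.KmcParams(q=1.0, dt=5.0, acceptance_mode="none", t_max=0.0)
    rng = rng_from_seed(seed)
    kt = KB_CM1_PER_K * params.T_bath
    target = 1.0 / (math.exp(nu / kt) - 1.0)
    n = np.array([0])
    burn = n_steps // 100
    n_batches = 50
    batch = (n_steps - burn) // n_batches
    batch_means = []
    acc = cnt = 0
    for s in range(n_steps):
        n = kmc.kmc_step(system, n, params, rng)
        if s >= burn:
            acc += int(n[0])
            cnt += 1
            if cnt == batch:
                batch_means.append(acc / cnt)
                acc = cnt = 0
    mean = float(np.mean(batch_means))
    sem = float(np.std(batch_means, ddof=1) / math.sqrt(len(batch_means)))
    return mean, target, sem


@dataclass
class CoolingSummary:
    """Outputs of the chromophore-like cooling experiment."""

    times_fs: np.ndarray
    energy_namd: np.ndarray
    energy_thermal_target: float
    nu_t_namd: np.ndarray
    nu_t_statistical: np.ndarray
    nu_equilibrium: float
    nu_cold_fundamental: float


def cooling_phenomenology(
    seed: int = 0,
    n_trajectories: int = 64,
    t_max: float = 10_000.0,
    e_hot: float = 8000.0,
    n_initial: int = 4,
) -> CoolingSummary:
    """Hot-ground-state cooling on the 87-mode chromophore-like fixture.

    Two initial-condition families are propagated with the one-parameter
    cooling model (acceptance_mode='none', whose harmonic-limit stationary
    state is the 300 K bath distribution): quanta on the 14 active modes
    (surface-hopping-projection style) and quanta spread over all modes
    (rapid-exchange statistical style).  Returns the ensemble-mean energy
    trace, the marker-band expectation-frequency traces <nu>(t), and the
    equilibrium references.
    """
    system, active, markers = make_cyan_like_system(seed=0)
    window = markers["cc_stretch"]
    rng = rng_from_seed(seed)
    params = kmc.KmcParams(
        q=0.1, dt=5.0, t_max=t_max, T_bath=300.0,
        acceptance_mode="none", n_trajectories=n_trajectories,
        spectral_window=(1350.0, 1850.0), spectral_bin=2.0,
    )
    namd_like = generate_hot_configs(system, active, e_hot, n_initial, rng)
    statistical = generate_hot_configs(
        system, list(range(system.n_modes)), e_hot, n_initial, rng
    )

    m_namd = kmc.ensemble_spectra(system, namd_like, params, rng,
                                  thermal_augment=300.0)
    m_stat = kmc.ensemble_spectra(system, statistical, params, rng,
                                  thermal_augment=300.0)

    e_params = kmc.KmcParams(
        q=0.1, dt=5.0, t_max=t_max, T_bath=300.0,
        acceptance_mode="none", n_trajectories=max(8, n_trajectories // 4),
    )
    times, e_namd = kmc.ensemble_energy(system, namd_like, e_params, rng,
                                        thermal_augment=300.0)

    kt = KB_CM1_PER_K * 300.0
    nbar = 1.0 / (np.exp(system.nu / kt) - 1.0)
    e_thermal = float(np.sum(system.nu * nbar))

    def nu_trace(matrix) -> np.ndarray:
        out = np.empty(matrix.row_axis.size)
        for i, row in enumerate(matrix.values):
            out[i] = ba.expectation_frequency(matrix.col_axis, row, window)
        return out

    nu_namd = nu_trace(m_namd)
    nu_stat = nu_trace(m_stat)

    # equilibrium <nu>: stationary ensemble started from thermal samples
    from .initial_conditions import sample_thermal_config

    eq_params = kmc.KmcParams(
        q=0.1, dt=5.0, t_max=1000.0, T_bath=300.0,
        acceptance_mode="none", n_trajectories=4,
        spectral_window=(1350.0, 1850.0), spectral_bin=2.0,
    )
    thermal_starts = [
        sample_thermal_config(system, 300.0, rng) for _ in range(24)
    ]
    m_eq = kmc.ensemble_spectra(system, thermal_starts, eq_params, rng)
    eq_row = m_eq.values.mean(axis=0)
    nu_eq = ba.expectation_frequency(m_eq.col_axis, eq_row, window)

    from .vib_model import fundamental_energies

    de0 = fundamental_energies(system, np.zeros(system.n_modes, dtype=int))
    idx = int(np.argmax(system.intensities_fund))
    return CoolingSummary(
        times_fs=m_namd.row_axis,
        energy_namd=e_namd,
        energy_thermal_target=e_thermal,
        nu_t_namd=nu_namd,
        nu_t_statistical=nu_stat,
        nu_equilibrium=float(nu_eq),
        nu_cold_fundamental=float(de0[idx]),
    )


def fit_recovery(seed: int = 0, n_replicates: int = 100) -> tuple[float, float]:
    """Sequential-model parameter recovery; returns (worst noiseless
    relative error over tau1/tau2, median noisy relative error of tau2 at
    5% Gaussian noise)."""
    tau1, tau2 = 0.5, 9.0
    t = np.linspace(0.02, 45.0, 60)
    clean = ba.sequential_model(t, tau1, tau2, amp_s1=0.3, amp_hot=1.0,
                                amp_ground=0.1, baseline=0.02)
    fit = ba.fit_sequential(ba.KineticTrace(t, clean), 0.8, 5.0)
    worst_clean = max(abs(fit.tau1 - tau1) / tau1, abs(fit.tau2 - tau2) / tau2)
    rng = rng_from_seed(seed)
    errors = []
    for _ in range(n_replicates):
        noisy = clean + 0.05 * np.abs(clean).max() * rng.normal(size=t.size)
        f = ba.fit_sequential(ba.KineticTrace(t, noisy), 0.8, 5.0)
        errors.append(abs(f.tau2 - tau2) / tau2)
    return float(worst_clean), float(np.median(errors))


def determinism_check(seed: int = 0) -> bool:
    """Rerun a seeded mini-pipeline twice and compare results exactly."""
    outs = []
    for _ in range(2):
        rng = rng_from_seed(seed)
        system = make_toy_anharmonic(FixtureSpec(n_modes=3, seed=seed))
        configs = generate_hot_configs(system, [0, 1, 2], 3000.0, 2, rng)
        params = kmc.KmcParams(
            q=0.5, dt=5.0, t_max=250.0, acceptance_mode="none",
            n_trajectories=4, spectral_window=(0.0, 2000.0), spectral_bin=4.0,
        )
        m = kmc.ensemble_spectra(system, configs, params, rng,
                                 thermal_augment=300.0)
        outs.append(m.values.tobytes() + m.row_axis.tobytes())
    return outs[0] == outs[1]
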