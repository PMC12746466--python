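"""Multicanonical (MUCA) flat-histogram sampling of occupation space.

The IR spectrum at a canonical temperature is assembled in two stages: a
random walk over occupation configurations whose stationary law is uniform
per energy bin (flat histogram), which fills a microcanonical spectral
matrix (one spectrum row per energy bin), followed by a Boltzmann-weighted
sum of the rows.

Per step each mode may independently step down one quantum with probability
1/N or up with probability r/N (r > 1 biases upward to accelerate coverage
of the sparsely connected high-energy bins; decrements at n_i = 0 are
suppressed).  A proposal is valid only if the total energy stays inside the
window and every fundamental transition energy remains positive; valid
proposals are accepted with the Metropolis-Hastings probability

    p_acc = min[1, rho(E)/rho(E_prop) * g_rev/g_fwd]

where rho is the separable state density and g are the forward/reverse
generation probabilities of the realised move (equal to r^dn for this
proposal family, dn = current minus proposed total quanta).  Regardless of
acceptance, the energy-bin histogram entry of the *current* configuration is
incremented and its stick spectrum is accumulated into the matching spectral
row; the walk terminates when every reachable bin satisfies the flatness
condition |H_b - <H>| / <H> < alpha.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .state_density import DensityOfStates, boltzmann_weights
from .vib_model import (
    GroundTransitions,
    Spectrum,
    VibrationalSystem,
    fundamental_energies,
    ground_transitions,
    stick_arrays,
    total_energy,
)

__all__ = [
    "EnergyWindow",
    "MucaParams",
    "SpectralMatrix",
    "WalkResult",
    "propose_config",
    "validate_config",
    "muca_acceptance",
    "flatness",
    "find_initial_config",
    "run_walk",
    "run_windows",
    "assemble_canonical_spectrum",
]


@dataclass(frozen=True)
class EnergyWindow:
    """Half-open energy window [e_lo, e_hi) split into bins of bin_width."""

    e_lo: float
    e_hi: float
    bin_width: float = 16.0

    def __post_init__(self) -> None:
        if not self.e_lo < self.e_hi:
            raise ValueError("require e_lo < e_hi")
        n = (self.e_hi - self.e_lo) / self.bin_width
        if abs(n - round(n)) > 1e-9:
            raise ValueError("window span must be a multiple of bin_width")

    @property
    def n_bins(self) -> int:
        return int(round((self.e_hi - self.e_lo) / self.bin_width))

    def bin_of(self, energy: float) -> int:
        return int(math.floor((energy - self.e_lo) / self.bin_width + 1e-9))

    def bin_centers(self) -> np.ndarray:
        return self.e_lo + (np.arange(self.n_bins) + 0.5) * self.bin_width


@dataclass
class MucaParams:
    """Sampler controls.

    r : up-proposal bias (r/N per mode; 1.08 accelerates convergence)
    alpha : histogram flatness threshold
    n_walks : independent walks per window
    max_steps : per-walk safety cap
    spectral_window, spectral_bin : wavenumber grid of the accumulated rows
    check_every : steps between flatness evaluations
    """

    r: float = 1.08
    alpha: float = 0.25
    n_walks: int = 6
    max_steps: int = 2_000_000
    spectral_window: tuple[float, float] = (1350.0, 1850.0)
    spectral_bin: float = 2.0
    check_every: int = 500

    def __post_init__(self) -> None:
        if not self.r > 0:
            raise ValueError("r must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class SpectralMatrix:
    """Rows of accumulated stick intensity: one row per energy bin (MUCA) or
    per time step (kMC); columns are wavenumber-bin centres."""

    row_axis: np.ndarray
    col_axis: np.ndarray
    values: np.ndarray
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.row_axis = np.asarray(self.row_axis, dtype=float)
        self.col_axis = np.asarray(self.col_axis, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.samples = np.asarray(self.samples)
        if self.values.shape != (self.row_axis.size, self.col_axis.size):
            raise ValueError("values shape mismatch")
        if self.samples.shape != (self.row_axis.size,):
            raise ValueError("samples shape mismatch")
        if np.any(self.samples < 0):
            raise ValueError("sample counts must be non-negative")

    def normalized_rows(self) -> np.ndarray:
        """Rows divided by their sample counts (empty rows left at zero)."""
        out = np.zeros_like(self.values)
        filled = self.samples > 0
        out[filled] = self.values[filled] / self.samples[filled, None]
        return out


def proposal_scale(n_modes: int, r: float) -> float:
    """Attempt-probability scale keeping per-mode probabilities proper.

    With few modes the nominal per-mode probabilities 1/N (down) and r/N
    (up) exceed 1; scaling both by s < 1 leaves the Hastings generation
    ratio r^dn unchanged while keeping the scheme well defined.  Returns 1
    whenever (1 + r)/N <= 1 (the many-mode regime).
    """
    return min(1.0, 0.95 * n_modes / (1.0 + r))


def propose_config(
    config: np.ndarray, r: float, rng: np.random.Generator, scale: float = 1.0
) -> tuple[np.ndarray, float, float]:
    """One MUCA proposal; returns (proposed, log g_fwd, log g_rev).

    Each mode independently steps -1 w.p. scale/N, +1 w.p. scale*r/N, else
    stays; a down-step drawn at n_i = 0 is suppressed (realised as stay).
    The log generation probabilities of the realised move and of its exact
    reverse are returned for the Hastings ratio.
    """
    n = np.asarray(config)
    nm = n.size
    if scale * (1.0 + r) / nm > 1.0 + 1e-12:
        raise ValueError("(1 + r)/N must not exceed 1; reduce r or add modes")
    u = rng.random(nm)
    p_dn = scale / nm
    p_up = scale * r / nm
    want_down = u < p_dn
    want_up = (u >= p_dn) & (u < p_dn + p_up)
    moves = want_up.astype(int) - (want_down & (n > 0)).astype(int)
    prop = n + moves

    log_stay_interior = math.log(max(1.0 - scale * (1.0 + r) / nm, 1e-300))
    log_stay_boundary = math.log(max(1.0 - scale * r / nm, 1e-300))
    log_dn = math.log(p_dn)
    log_up = math.log(p_up)

    log_fwd = 0.0
    log_rev = 0.0
    for i in range(nm):
        m = moves[i]
        if m == -1:
            log_fwd += log_dn
            log_rev += log_up
        elif m == 1:
            log_fwd += log_up
            log_rev += log_dn
        else:
            s = log_stay_boundary if n[i] == 0 else log_stay_interior
            log_fwd += s
            log_rev += s  # unmoved modes have n'_i = n_i
    return prop, log_fwd, log_rev


def validate_config(
    system: VibrationalSystem, config: np.ndarray, window: EnergyWindow
) -> bool:
    """True iff E_rel lies in the window and all fundamentals have dE > 0."""
    if np.any(np.asarray(config) < 0):
        return False
    e = total_energy(system, config)
    if not (window.e_lo <= e < window.e_hi):
        return False
    return bool(np.all(fundamental_energies(system, config) > 0))


def muca_acceptance(
    dos: DensityOfStates, e: float, e_prop: float, r: float, delta_n: int
) -> float:
    """min[1, rho(E)/rho(E_prop) * r^dn], dn = current - proposed quanta.

    A proposal landing in a bin with rho = 0 is rejected outright.
    """
    rho_prop = dos.rho(e_prop)
    if rho_prop == 0:
        return 0.0
    rho_cur = dos.rho(e)
    if rho_cur == 0:
        return 1.0
    log_ratio = math.log(rho_cur) - math.log(rho_prop) + delta_n * math.log(r)
    return 1.0 if log_ratio >= 0 else math.exp(log_ratio)


def flatness(histogram: np.ndarray, alpha: float, mask: np.ndarray | None = None) -> bool:
    """Flat-histogram test: every (reachable) bin within alpha of the mean."""
    h = np.asarray(histogram, dtype=float)
    if mask is not None:
        h = h[np.asarray(mask, dtype=bool)]
    if h.size == 0:
        return False
    mean = h.mean()
    if mean == 0:
        return False
    return bool(np.all(np.abs(h - mean) / mean < alpha))


def find_initial_config(
    system: VibrationalSystem,
    window: EnergyWindow,
    rng: np.random.Generator,
    max_tries: int = 20_000,
) -> np.ndarray:
    """Randomised search for a valid configuration inside the window.

    Quanta are added to random modes until the energy enters (or overshoots)
    the window; repeated until validate_config passes.
    """
    nm = system.n_modes
    for _ in range(max_tries):
        n = np.zeros(nm, dtype=int)
        e = 0.0
        while e < window.e_lo:
            n[rng.integers(nm)] += 1
            e = total_energy(system, n)
        if validate_config(system, n, window):
            return n
    raise RuntimeError("no valid configuration found in window; is it reachable?")


@dataclass
class WalkResult:
    """One walk's histogram, accumulated spectral rows, and termination
    status; `visits` optionally maps configuration tuples to visit counts."""

    window: EnergyWindow
    histogram: np.ndarray
    matrix: SpectralMatrix
    flat: bool
    steps: int
    visits: dict | None = None
    final_config: np.ndarray | None = None


def run_walk(
    system: VibrationalSystem,
    window: EnergyWindow,
    params: MucaParams,
    dos: DensityOfStates,
    rng: np.random.Generator,
    config0: np.ndarray | None = None,
    track_configs: bool = False,
    track_every: int = 1,
) -> WalkResult:
    """One flat-histogram walk over the window.

    On every step (accepted or not) the current energy bin is incremented
    and the current configuration's stick lines are accumulated (nearest
    wavenumber bin) into the corresponding spectral row.  Bins with rho = 0
    are unreachable and excluded from the flatness test.  If max_steps is hit
    before flatness a warning is issued and partial results are returned.
    Tracked configuration visits (``track_configs``) are recorded every
    ``track_every`` steps; thinning them decorrelates the samples for
    visitation statistics.
    """

    if abs(window.bin_width - dos.bin_width) > 1e-12:
        raise ValueError("window and density-of-states bin widths must match")
    nb = window.n_bins
    centers = window.bin_centers()
    reachable = np.array(
        [dos.rho(c) > 0 for c in centers], dtype=bool
    )
    lo, hi = params.spectral_window
    ncol = int(round((hi - lo) / params.spectral_bin))
    col_axis = lo + (np.arange(ncol) + 0.5) * params.spectral_bin

    hist = np.zeros(nb, dtype=np.int64)
    values = np.zeros((nb, ncol))
    ref = ground_transitions(system)
    visits: dict | None = {} if track_configs else None

    n = (
        np.asarray(config0, dtype=int).copy()
        if config0 is not None
        else find_initial_config(system, window, rng)
    )
    e = total_energy(system, n)
    scale = proposal_scale(system.n_modes, params.r)
    flat = False
    step = 0
    n_seen_prev = -1  # flatness requires the visited-bin set to be stable
    while step < params.max_steps:
        step += 1
        prop, log_fwd, log_rev = propose_config(n, params.r, rng, scale)
        if validate_config(system, prop, window):
            e_prop = total_energy(system, prop)
            rho_cur, rho_prop = dos.rho(e), dos.rho(e_prop)
            if rho_prop > 0:
                if rho_cur == 0:
                    # current bin unreachable under the separable density
                    # (full-X energy in a rho=0 bin): always move off it
                    n, e = prop, e_prop
                else:
                    log_ratio = (
                        math.log(rho_cur)
                        - math.log(rho_prop)
                        + (log_rev - log_fwd)
                    )
                    if log_ratio >= 0 or rng.random() < math.exp(log_ratio):
                        n, e = prop, e_prop
        b = window.bin_of(e)
        hist[b] += 1
        _accumulate_row(system, n, ref, values[b], lo, hi, params.spectral_bin)
        if visits is not None and step % track_every == 0:
            key = tuple(int(v) for v in n)
            visits[key] = visits.get(key, 0) + 1
        if step % params.check_every == 0:
            # Flatness is judged over the bins the walk can actually reach:
            # bins with separable rho > 0 that have been visited.  (With a
            # full X matrix a few rho > 0 bins near bin edges may hold no
            # valid configuration; they would stall the test forever.)  The
            # visited set must not have grown since the last check.
            mask = reachable & (hist > 0)
            n_seen = int(mask.sum())
            if (
                n_seen == n_seen_prev
                and n_seen > 0
                and flatness(hist, params.alpha, mask)
            ):
                flat = True
                break
            n_seen_prev = n_seen
    if not flat:
        warnings.warn(
            f"walk hit max_steps={params.max_steps} before flatness; "
            "returning partial results",
            RuntimeWarning,
            stacklevel=2,
        )
    matrix = SpectralMatrix(
        row_axis=centers, col_axis=col_axis, values=values, samples=hist.copy()
    )
    return WalkResult(window, hist, matrix, flat, step, visits, n.copy())


def _accumulate_row(
    system: VibrationalSystem,
    config: np.ndarray,
    ref: GroundTransitions,
    row: np.ndarray,
    lo: float,
    hi: float,
    dbin: float,
) -> None:
    pos, inten, _, _, _ = stick_arrays(system, config, ref)
    sel = (inten > 0) & (pos >= lo) & (pos < hi)
    if np.any(sel):
        idx = ((pos[sel] - lo) / dbin).astype(int)
        np.add.at(row, idx, inten[sel])


def run_windows(
    system: VibrationalSystem,
    windows: list[EnergyWindow],
    params: MucaParams,
    dos: DensityOfStates,
    rng: np.random.Generator,
) -> list[list[WalkResult]]:
    """n_walks independent walks (different random initial configurations)
    for each window; returns results grouped by window."""
    return [
        [run_walk(system, w, params, dos, rng) for _ in range(params.n_walks)]
        for w in windows
    ]


def assemble_canonical_spectrum(
    results_by_window: list[list[WalkResult]],
    dos: DensityOfStates,
    temperature: float,
    empty_weight_tol: float = 1e-6,
) -> Spectrum:
    """Boltzmann-weighted assembly of the windows' microcanonical rows.

    Walks within a window are pooled (sums of intensity and of samples, i.e.
    sample-weighted averaging), each row is divided by its sample count, rows
    from all windows are concatenated, and the canonical spectrum is the
    Boltzmann-weighted sum of the rows at ``temperature``.  Doubling all
    sample counts leaves the result invariant.
    """
    if not results_by_window or not results_by_window[0]:
        raise ValueError("no walk results supplied")
    col_axis = results_by_window[0][0].matrix.col_axis
    rows: list[np.ndarray] = []
    energies: list[float] = []
    filled: list[bool] = []
    for walks in results_by_window:
        values = sum(w.matrix.values for w in walks)
        samples = sum(w.matrix.samples for w in walks)
        pooled = SpectralMatrix(
            walks[0].matrix.row_axis, col_axis, values, samples
        )
        norm = pooled.normalized_rows()
        for i, center in enumerate(pooled.row_axis):
            energies.append(float(center))
            rows.append(norm[i])
            filled.append(bool(samples[i] > 0))
    order = np.argsort(energies)
    energies_arr = np.array(energies)[order]
    rows_arr = np.array(rows)[order]
    filled_arr = np.array(filled)[order]

    w_all = boltzmann_weights(dos, temperature)
    centers = dos.bin_centers()
    weights = np.zeros(energies_arr.size)
    for i, e in enumerate(energies_arr):
        b = dos.bin_index(e)
        if 0 <= b < dos.n_bins:
            weights[i] = w_all[b]
    dropped = float(weights[~filled_arr].sum())
    if dropped > empty_weight_tol:
        warnings.warn(
            f"empty spectral rows carry Boltzmann weight {dropped:.3g}",
            RuntimeWarning,
            stacklevel=2,
        )
    weights[~filled_arr] = 0.0
    total = weights.sum()
    if total <= 0:
        raise ValueError("no sampled rows carry Boltzmann weight")
    weights /= total
    return Spectrum(col_axis, weights @ rows_arr)
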