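"""Dunham-expansion vibrational energetics, transition energies and IR line
intensities.

The total vibrational energy of an occupation configuration
``n = (n_1, ..., n_N)`` is modelled by the Dunham (VPT2) expansion

    E(n) = sum_i nu_i (n_i + 1/2) + sum_{i<=j} X_ij (n_i + 1/2)(n_j + 1/2)

with mode frequencies ``nu_i`` and the symmetric anharmonicity matrix
``X_ij``, all in cm^-1.  Everything downstream works with the energy
relative to the zero-point configuration, ``E_rel(n) = E(n) - E(0)``.

Transition energies for fundamentals (n_i -> n_i + 1), first overtones
(n_i -> n_i + 2) and 1+1 combination bands (n_i, n_j -> n_i+1, n_j+1) are
obtained by direct differencing of the expansion, which is self-consistent
with the energy model for every band kind.  Closed forms used internally:

    dE_fund,i = nu_i + 2 X_ii (n_i + 1) + sum_{j!=i} X_ij (n_j + 1/2)
    dE_ot,i   = 2 dE_fund,i + 2 X_ii
    dE_cb,ij  = dE_fund,i + dE_fund,j + X_ij

IR intensities scale harmonic-oscillator matrix elements with occupancy and
with the ratio of the (occupation-dependent) transition energy to its value
from the all-zero configuration; transitions with non-positive energy carry
zero intensity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "VibrationalSystem",
    "SpectralLine",
    "Spectrum",
    "GroundTransitions",
    "total_energy",
    "fundamental_energies",
    "overtone_energies",
    "combination_energies",
    "transition_energy",
    "ground_transitions",
    "line_intensity",
    "stick_spectrum",
    "stick_arrays",
    "convolve_spectrum",
]

BAND_KINDS = ("fundamental", "overtone", "combination")

#: integer codes used in vectorised line tables
KIND_FUNDAMENTAL, KIND_OVERTONE, KIND_COMBINATION = 0, 1, 2


@dataclass(frozen=True)
class VibrationalSystem:
    """Anharmonic fingerprint of a molecule.

    Parameters
    ----------
    frequencies
        Harmonic/anharmonic mode frequencies nu_i in cm^-1 (strictly positive).
    x_matrix
        Symmetric N x N anharmonicity matrix X_ij in cm^-1.
    intensities_fund
        Base IR intensities of the fundamentals from the all-zero
        configuration (km/mol or arbitrary units, >= 0).
    intensities_overtone
        Optional base intensities of the first overtones.  ``None`` means no
        overtone lines are carried.
    intensities_comb
        Optional symmetric N x N base intensities of 1+1 combination bands
        (diagonal ignored).  ``None`` means no combination lines.
    freq_scale
        Multiplicative scaling applied to the frequencies only (not to X);
        empirical alignment with experiment typically uses values near 1
        (e.g. 0.992).
    """

    frequencies: np.ndarray
    x_matrix: np.ndarray
    intensities_fund: np.ndarray
    intensities_overtone: np.ndarray | None = None
    intensities_comb: np.ndarray | None = None
    freq_scale: float = 1.0

    def __post_init__(self) -> None:
        freq = np.atleast_1d(np.asarray(self.frequencies, dtype=float))
        x = np.asarray(self.x_matrix, dtype=float)
        if x.ndim == 0:
            x = x.reshape(1, 1)
        i0 = np.atleast_1d(np.asarray(self.intensities_fund, dtype=float))
        n = freq.size
        if x.shape != (n, n):
            raise ValueError(f"x_matrix shape {x.shape} != ({n}, {n})")
        if not np.allclose(x, x.T, atol=1e-8, rtol=1e-8):
            raise ValueError("x_matrix must be symmetric")
        x = 0.5 * (x + x.T)
        if np.any(freq <= 0):
            raise ValueError("frequencies must be strictly positive")
        if i0.shape != (n,):
            raise ValueError("intensities_fund length mismatch")
        if np.any(i0 < 0):
            raise ValueError("intensities must be non-negative")
        if not self.freq_scale > 0:
            raise ValueError("freq_scale must be positive")
        ot = self.intensities_overtone
        if ot is not None:
            ot = np.atleast_1d(np.asarray(ot, dtype=float))
            if ot.shape != (n,) or np.any(ot < 0):
                raise ValueError("intensities_overtone invalid")
        cb = self.intensities_comb
        if cb is not None:
            cb = np.asarray(cb, dtype=float)
            if cb.shape != (n, n) or np.any(cb < 0):
                raise ValueError("intensities_comb invalid")
            if not np.allclose(cb, cb.T, atol=1e-8, rtol=1e-8):
                raise ValueError("intensities_comb must be symmetric")
            cb = 0.5 * (cb + cb.T)
        for name, arr in (
            ("frequencies", freq),
            ("x_matrix", x),
            ("intensities_fund", i0),
            ("intensities_overtone", ot),
            ("intensities_comb", cb),
        ):
            if arr is not None:
                arr.setflags(write=False)
            object.__setattr__(self, name, arr)

    @property
    def n_modes(self) -> int:
        return self.frequencies.size

    @property
    def nu(self) -> np.ndarray:
        """Scaled frequencies actually used in the energy expressions."""
        return self.freq_scale * self.frequencies


def _as_config(system: VibrationalSystem, config: Sequence[int]) -> np.ndarray:
    n = np.asarray(config)
    if n.shape != (system.n_modes,):
        raise ValueError(
            f"occupation length {n.shape} does not match {system.n_modes} modes"
        )
    if np.any(n < 0):
        raise ValueError("occupation numbers must be non-negative")
    return n.astype(float)


def total_energy(system: VibrationalSystem, config: Sequence[int]) -> float:
    """Dunham-expansion energy of ``config`` relative to the zero-point level.

    ``E_rel(0) = 0`` exactly; additive over modes when all off-diagonal X
    vanish.
    """
    n = _as_config(system, config)
    x = system.x_matrix
    m = n + 0.5
    # sum_{i<=j} X_ij m_i m_j = (m^T X m + sum_i X_ii m_i^2) / 2
    diag = np.diag(x)
    e_n = system.nu @ n + 0.5 * (m @ x @ m + diag @ m**2)
    q = np.full(system.n_modes, 0.5)
    e_0 = 0.5 * (q @ x @ q + diag @ q**2)
    return float(e_n - e_0)


def fundamental_energies(
    system: VibrationalSystem, config: Sequence[int]
) -> np.ndarray:
    """Vector of fundamental transition energies dE_i(n -> n + e_i)."""
    n = _as_config(system, config)
    x = system.x_matrix
    diag = np.diag(x)
    cross = x @ (n + 0.5) - diag * (n + 0.5)  # sum_{j != i} X_ij (n_j + 1/2)
    return system.nu + 2.0 * diag * (n + 1.0) + cross


def overtone_energies(system: VibrationalSystem, config: Sequence[int]) -> np.ndarray:
    """Vector of first-overtone transition energies dE_i(n -> n + 2 e_i)."""
    return 2.0 * fundamental_energies(system, config) + 2.0 * np.diag(system.x_matrix)


def combination_energies(
    system: VibrationalSystem, config: Sequence[int]
) -> np.ndarray:
    """Matrix of 1+1 combination transition energies (i != j entries valid)."""
    de = fundamental_energies(system, config)
    return de[:, None] + de[None, :] + system.x_matrix


def transition_energy(
    system: VibrationalSystem,
    config: Sequence[int],
    kind: str,
    modes: int | tuple[int, int],
) -> float:
    """Transition energy of one band by direct differencing of the expansion.

    May be negative for strongly anharmonic, highly excited configurations.
    """
    _as_config(system, config)
    if kind == "fundamental":
        return float(fundamental_energies(system, config)[_one_mode(system, modes)])
    if kind == "overtone":
        return float(overtone_energies(system, config)[_one_mode(system, modes)])
    if kind == "combination":
        i, j = _two_modes(system, modes)
        return float(combination_energies(system, config)[i, j])
    raise ValueError(f"unknown band kind {kind!r}")


def _one_mode(system: VibrationalSystem, modes: int | tuple[int, int]) -> int:
    i = int(modes) if np.isscalar(modes) else int(modes[0])
    if not 0 <= i < system.n_modes:
        raise IndexError(f"mode index {i} out of range")
    return i


def _two_modes(system: VibrationalSystem, modes: tuple[int, int]) -> tuple[int, int]:
    i, j = int(modes[0]), int(modes[1])
    if i == j:
        raise ValueError("combination band requires two distinct modes")
    for k in (i, j):
        if not 0 <= k < system.n_modes:
            raise IndexError(f"mode index {k} out of range")
    return i, j


@dataclass(frozen=True)
class GroundTransitions:
    """Transition energies from the all-zero configuration (the dE^0 of the
    intensity ratio), precomputed once per system for the hot loops."""

    fund: np.ndarray
    overtone: np.ndarray
    comb: np.ndarray


def ground_transitions(system: VibrationalSystem) -> GroundTransitions:
    zero = np.zeros(system.n_modes, dtype=int)
    return GroundTransitions(
        fund=fundamental_energies(system, zero),
        overtone=overtone_energies(system, zero),
        comb=combination_energies(system, zero),
    )


def line_intensity(
    system: VibrationalSystem,
    config: Sequence[int],
    kind: str,
    modes: int | tuple[int, int],
    ref: GroundTransitions | None = None,
) -> float:
    """Occupancy- and anharmonicity-scaled IR intensity of one band.

    Fundamental: I = I0_i (n_i + 1) dE/dE0; overtone:
    I = I0ot_i (n_i+1)(n_i+2)/2 dE/dE0; combination:
    I = I0cb_ij (n_i+1)(n_j+1) dE/dE0 -- harmonic-oscillator occupancy
    scalings.  Returns 0 whenever dE <= 0 (or the band carries no base
    intensity).
    """
    n = _as_config(system, config)
    if ref is None:
        ref = ground_transitions(system)
    de = transition_energy(system, config, kind, modes)
    if de <= 0:
        return 0.0
    if kind == "fundamental":
        i = _one_mode(system, modes)
        de0 = ref.fund[i]
        base = system.intensities_fund[i] * (n[i] + 1.0)
    elif kind == "overtone":
        i = _one_mode(system, modes)
        if system.intensities_overtone is None:
            return 0.0
        de0 = ref.overtone[i]
        base = system.intensities_overtone[i] * (n[i] + 1.0) * (n[i] + 2.0) / 2.0
    else:
        i, j = _two_modes(system, modes)
        if system.intensities_comb is None:
            return 0.0
        de0 = ref.comb[i, j]
        base = system.intensities_comb[i, j] * (n[i] + 1.0) * (n[j] + 1.0)
    if de0 <= 0:
        return 0.0
    return float(base * de / de0)


@dataclass(frozen=True)
class SpectralLine:
    """One stick line: position (cm^-1), intensity, band kind and mode
    index/pair."""

    position: float
    intensity: float
    band_kind: str
    modes: tuple[int, ...]


@dataclass
class Spectrum:
    """A spectrum on a strictly increasing wavenumber grid."""

    grid: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.ndim != 1 or self.grid.size == 0:
            raise ValueError("grid must be a non-empty 1-D array")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if self.values.shape != self.grid.shape:
            raise ValueError("values must match grid")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")


def stick_arrays(
    system: VibrationalSystem,
    config: Sequence[int],
    ref: GroundTransitions | None = None,
):
    """All candidate lines of a configuration as flat arrays.

    Returns ``(positions, intensities, kinds, mode_i, mode_j)`` covering every
    fundamental, every first overtone and every 1+1 combination (i < j);
    band kinds whose base intensities are absent are skipped entirely.
    Lines with non-positive transition energy carry intensity 0.  This is the
    vectorised core shared by the samplers.
    """
    n = _as_config(system, config)
    if ref is None:
        ref = ground_transitions(system)
    nm = system.n_modes

    pos_parts, int_parts, kind_parts, mi_parts, mj_parts = [], [], [], [], []

    de_f = fundamental_energies(system, config)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where((de_f > 0) & (ref.fund > 0), de_f / ref.fund, 0.0)
    inten = system.intensities_fund * (n + 1.0) * ratio
    idx = np.arange(nm)
    pos_parts.append(de_f)
    int_parts.append(inten)
    kind_parts.append(np.full(nm, KIND_FUNDAMENTAL, dtype=np.int8))
    mi_parts.append(idx)
    mj_parts.append(idx)

    if system.intensities_overtone is not None:
        de_o = 2.0 * de_f + 2.0 * np.diag(system.x_matrix)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where((de_o > 0) & (ref.overtone > 0), de_o / ref.overtone, 0.0)
        inten = (
            system.intensities_overtone * (n + 1.0) * (n + 2.0) / 2.0 * ratio
        )
        pos_parts.append(de_o)
        int_parts.append(inten)
        kind_parts.append(np.full(nm, KIND_OVERTONE, dtype=np.int8))
        mi_parts.append(idx)
        mj_parts.append(idx)

    if system.intensities_comb is not None and nm > 1:
        de_c = de_f[:, None] + de_f[None, :] + system.x_matrix
        iu, ju = np.triu_indices(nm, k=1)
        de_c = de_c[iu, ju]
        de0 = ref.comb[iu, ju]
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where((de_c > 0) & (de0 > 0), de_c / de0, 0.0)
        inten = (
            system.intensities_comb[iu, ju]
            * (n[iu] + 1.0)
            * (n[ju] + 1.0)
            * ratio
        )
        pos_parts.append(de_c)
        int_parts.append(inten)
        kind_parts.append(np.full(iu.size, KIND_COMBINATION, dtype=np.int8))
        mi_parts.append(iu)
        mj_parts.append(ju)

    return (
        np.concatenate(pos_parts),
        np.concatenate(int_parts),
        np.concatenate(kind_parts),
        np.concatenate(mi_parts),
        np.concatenate(mj_parts),
    )


def stick_spectrum(
    system: VibrationalSystem,
    config: Sequence[int],
    window: tuple[float, float],
    keep_zero: bool = False,
) -> list[SpectralLine]:
    """All lines whose transition energy lies in ``window = (lo, hi)``.

    Zero-intensity lines are omitted unless ``keep_zero``.
    """
    lo, hi = window
    if not lo < hi:
        raise ValueError("window must satisfy lo < hi")
    pos, inten, kinds, mi, mj = stick_arrays(system, config)
    out: list[SpectralLine] = []
    for p, s, k, i, j in zip(pos, inten, kinds, mi, mj):
        if not (lo <= p <= hi):
            continue
        if s == 0.0 and not keep_zero:
            continue
        kind = BAND_KINDS[k]
        modes = (int(i),) if i == j else (int(i), int(j))
        out.append(SpectralLine(float(p), float(s), kind, modes))
    out.sort(key=lambda l: l.position)
    return out


def convolve_spectrum(
    lines: Sequence[SpectralLine] | tuple[np.ndarray, np.ndarray],
    grid: np.ndarray,
    fwhm: float,
) -> Spectrum:
    """Sum of area-preserving Gaussians of the given FWHM at the line
    positions, evaluated on ``grid``.

    ``lines`` may be a list of :class:`SpectralLine` or a ``(positions,
    intensities)`` pair of arrays.  Linear in the line list.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("grid must be non-empty")
    if not fwhm > 0:
        raise ValueError("fwhm must be positive")
    if isinstance(lines, tuple):
        pos, inten = (np.asarray(a, dtype=float) for a in lines)
    else:
        pos = np.array([l.position for l in lines], dtype=float)
        inten = np.array([l.intensity for l in lines], dtype=float)
    values = np.zeros_like(grid)
    if pos.size:
        sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        amp = inten / (sigma * np.sqrt(2.0 * np.pi))
        values = np.sum(
            amp[:, None] * np.exp(-0.5 * ((grid[None, :] - pos[:, None]) / sigma) ** 2),
            axis=0,
        )
    return Spectrum(grid, values)
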