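"""Deterministic generators of toy and chromophore-like vibrational systems.

All generators are pure functions of their seed (counter-based Philox
streams, so the same seed and call order reproduce bit-identical output on
any platform).  Frequencies and diagonal anharmonicities are drawn as
integer cm^-1 values: realistic at spectroscopic precision and commensurate
with the state-counting grain, so the exact-count oracles apply.

The 87-mode "chromophore-like" fixture mimics the *structure* of a mid-size
conjugated photoswitch — two dominant marker bands (a C=C stretch near
1570 cm^-1 and a C-C bridge stretch near 1465 cm^-1), a 14-mode active
subset carrying the nascent excitation, negative self-anharmonicities so
cooling blue-shifts the hot bands — without purporting to be any real
molecule's anharmonic data.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .band_analysis import BandWindow
from .vib_model import VibrationalSystem, fundamental_energies

__all__ = [
    "FixtureSpec",
    "rng_from_seed",
    "make_harmonic_system",
    "make_toy_anharmonic",
    "make_cyan_like_system",
    "generate_hot_configs",
]


def rng_from_seed(seed: int) -> np.random.Generator:
    """Counter-based (Philox) generator: same seed + call order -> same
    stream, on every platform."""
    return np.random.Generator(np.random.Philox(seed))


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a random toy system."""

    n_modes: int = 3
    freq_range: tuple[float, float] = (200.0, 1800.0)
    diag_range: tuple[float, float] = (-15.0, -2.0)
    offdiag_scale: float = 0.5
    n_active: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.freq_range[0] >= self.freq_range[1]:
            raise ValueError("freq_range must be increasing")
        if self.diag_range[0] >= self.diag_range[1] or self.diag_range[1] > 0:
            raise ValueError("diag_range must be increasing and non-positive")
        if self.n_active is not None and self.n_active > self.n_modes:
            raise ValueError("n_active must not exceed n_modes")


def make_harmonic_system(
    freqs: np.ndarray, intensities: np.ndarray | None = None
) -> VibrationalSystem:
    """Purely harmonic reference system (X = 0 exactly)."""
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    if intensities is None:
        intensities = np.ones_like(freqs)
    n = freqs.size
    return VibrationalSystem(
        frequencies=freqs,
        x_matrix=np.zeros((n, n)),
        intensities_fund=np.asarray(intensities, dtype=float),
    )


def make_toy_anharmonic(spec: FixtureSpec) -> VibrationalSystem:
    """Seeded random anharmonic toy; integer frequencies and diagonal X,
    small off-diagonal couplings, all ground fundamentals positive."""
    rng = rng_from_seed(spec.seed)
    nm = spec.n_modes
    for attempt in range(100):
        freqs = rng.integers(
            int(spec.freq_range[0]), int(spec.freq_range[1]) + 1, size=nm
        ).astype(float)
        diag = rng.integers(
            int(spec.diag_range[0]), int(spec.diag_range[1]) + 1, size=nm
        ).astype(float)
        off = spec.offdiag_scale * rng.normal(size=(nm, nm))
        x = np.triu(off, k=1)
        x = x + x.T + np.diag(diag)
        intens = rng.uniform(0.2, 1.0, size=nm)
        system = VibrationalSystem(
            frequencies=freqs, x_matrix=x, intensities_fund=intens
        )
        if np.all(fundamental_energies(system, np.zeros(nm, dtype=int)) > 0):
            if attempt > 0:
                warnings.warn(
                    f"regenerated toy system {attempt} time(s) to obtain "
                    "positive ground fundamentals",
                    RuntimeWarning,
                    stacklevel=2,
                )
            return system
    raise RuntimeError("could not generate a valid toy system")


def make_cyan_like_system(
    seed: int = 0, weak_multiquantum_intensities: bool = True
) -> tuple[VibrationalSystem, list[int], dict[str, BandWindow]]:
    """87-mode chromophore-like fixture.

    Returns ``(system, active_modes, marker_windows)``: 87 modes spanning
    ~50-3200 cm^-1; 14 active modes including two dominant markers placed at
    1570 and 1465 cm^-1; negative diagonal anharmonicities (roughly 0.5% of
    the frequency) so hot bands sit red of the cold ones and blue-shift on
    cooling.  When ``weak_multiquantum_intensities`` is set, first overtones
    and active-pair 1+1 combinations carry a few percent of the fundamental
    intensities so the multi-quantum structure is exercised.
    """
    rng = rng_from_seed(seed)
    blocks = [
        (25, 50.0, 600.0),     # skeletal torsions / bends
        (30, 600.0, 1350.0),   # fingerprint
        (22, 1350.0, 1700.0),  # CC/CN stretches (marker region)
        (10, 1700.0, 3200.0),  # C=O and CH/NH stretches
    ]
    freqs: list[float] = []
    for count, lo, hi in blocks:
        freqs.extend(
            sorted(rng.integers(int(lo), int(hi), size=count).astype(float))
        )
    freqs = np.array(sorted(freqs))
    # plant the two marker modes on exact positions
    marker_cc = int(np.argmin(np.abs(freqs - 1570.0)))
    freqs[marker_cc] = 1570.0
    dist = np.abs(freqs - 1465.0)
    dist[marker_cc] = np.inf
    marker_cb = int(np.argmin(dist))
    freqs[marker_cb] = 1465.0

    nm = freqs.size
    diag = -np.maximum(1.0, np.round(0.005 * freqs + rng.uniform(0.0, 2.0, nm)))
    # gentle marker self-anharmonicity keeps singly-excited hot lines inside
    # the marker analysis windows
    diag[marker_cc] = -4.0
    diag[marker_cb] = -3.5

    # 14-mode active subset: the markers plus bridge-like partners
    active = {marker_cc, marker_cb}
    low = [i for i in range(nm) if freqs[i] < 700.0]
    mid = [i for i in range(nm) if 700.0 <= freqs[i] < 1400.0]
    active.update(int(i) for i in rng.choice(low, size=7, replace=False))
    active.update(int(i) for i in rng.choice(mid, size=5, replace=False))
    while len(active) < 14:
        active.add(int(rng.integers(nm)))
    active_modes = sorted(active)

    # mode-mode couplings all negative, as in conjugated chromophores:
    # exciting any mode red-shifts the others, so cooling blue-shifts the
    # hot bands.  Couplings within the active (isomerisation-coupled) set
    # are an order of magnitude stronger than the spectator background.
    off = -np.abs(0.1 * rng.normal(size=(nm, nm))) - 0.01
    for a in active_modes:
        for b in active_modes:
            if a != b:
                off[a, b] = -abs(0.8 + 0.4 * rng.normal())
    x = np.triu(off, k=1)
    x = x + x.T + np.diag(diag)

    # re-centre the markers so their cold fundamentals sit exactly on the
    # nominal band positions after the coupling shifts
    for idx, nominal in ((marker_cc, 1570.0), (marker_cb, 1465.0)):
        de0 = freqs[idx] + 2.0 * x[idx, idx] + 0.5 * (
            x[idx].sum() - x[idx, idx]
        )
        freqs[idx] = np.round(freqs[idx] + nominal - de0)

    intens = rng.uniform(0.0, 15.0, size=nm)
    intens[marker_cc] = 100.0
    intens[marker_cb] = 60.0

    overtone = comb = None
    if weak_multiquantum_intensities:
        overtone = 0.03 * intens
        comb = np.zeros((nm, nm))
        for a in active_modes:
            for b in active_modes:
                if a < b:
                    comb[a, b] = comb[b, a] = 0.02 * np.sqrt(
                        intens[a] * intens[b]
                    )
    system = VibrationalSystem(
        frequencies=freqs,
        x_matrix=x,
        intensities_fund=intens,
        intensities_overtone=overtone,
        intensities_comb=comb,
    )
    markers = {
        "cc_stretch": BandWindow(1550.0, 1600.0),
        "bridge_stretch": BandWindow(1440.0, 1490.0),
    }
    return system, active_modes, markers


def generate_hot_configs(
    system: VibrationalSystem,
    active_modes: list[int],
    e_total: float,
    n_configs: int,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Random hot configurations with quanta only on the active modes.

    Each configuration's harmonic energy sum n_i nu_i lands within one
    quantum of the largest active frequency of ``e_total``.
    """
    if not e_total > 0:
        raise ValueError("e_total must be positive")
    if not active_modes:
        raise ValueError("need at least one active mode")
    nu = system.nu
    if e_total < 0.5 * min(nu[m] for m in active_modes):
        raise ValueError("e_total below half the smallest active quantum")
    out: list[np.ndarray] = []
    for _ in range(n_configs):
        n = np.zeros(system.n_modes, dtype=int)
        e = 0.0
        candidates = list(active_modes)
        while candidates:
            m = candidates[rng.integers(len(candidates))]
            if e + nu[m] <= e_total + 0.5 * nu[m]:
                n[m] += 1
                e += nu[m]
            else:
                candidates.remove(m)
        out.append(n)
    return out
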