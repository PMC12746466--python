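"""Quantitative analysis of time-resolved IR spectra.

Band-window integration, the band expectation frequency

    <nu> = int nu S(nu) dnu / int S(nu) dnu

whose rise in time quantifies hot-band reshaping toward the equilibrium
position, intensity breakdown by band kind, and sequential first-order
kinetic fits  S1 --tau1--> S0* --tau2--> S0  to integrated band signals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.special import erfc

from .vib_model import SpectralLine

__all__ = [
    "BandWindow",
    "KineticTrace",
    "SequentialFit",
    "integrate_band",
    "expectation_frequency",
    "intensity_breakdown",
    "sequential_populations",
    "sequential_model",
    "fit_sequential",
]


@dataclass(frozen=True)
class BandWindow:
    """Wavenumber window [nu_lo, nu_hi] in cm^-1."""

    nu_lo: float
    nu_hi: float

    def __post_init__(self) -> None:
        if not self.nu_lo < self.nu_hi:
            raise ValueError("require nu_lo < nu_hi")


@dataclass
class KineticTrace:
    """Time series of an integrated band signal or of <nu>."""

    times: np.ndarray
    values: np.ndarray
    uncertainty: np.ndarray | None = None
    time_unit: str = "ps"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.values.shape != self.times.shape:
            raise ValueError("values/times length mismatch")


def _window_slice(grid: np.ndarray, window: BandWindow) -> np.ndarray:
    sel = (grid >= window.nu_lo) & (grid <= window.nu_hi)
    if sel.sum() < 2:
        raise ValueError("band window does not overlap the spectral grid")
    return sel


def integrate_band(grid: np.ndarray, values: np.ndarray, window: BandWindow) -> float:
    """Trapezoidal integral of a spectrum row over the window."""
    grid = np.asarray(grid, dtype=float)
    values = np.asarray(values, dtype=float)
    sel = _window_slice(grid, window)
    return float(np.trapezoid(values[sel], grid[sel]))


def expectation_frequency(
    grid: np.ndarray, values: np.ndarray, window: BandWindow
) -> float:
    """Intensity-weighted mean wavenumber over the window.

    Defined on net-positive (growth) intensity only; a zero or net-negative
    window signals a bleach-dominated band and raises.
    """
    grid = np.asarray(grid, dtype=float)
    values = np.asarray(values, dtype=float)
    sel = _window_slice(grid, window)
    total = np.trapezoid(values[sel], grid[sel])
    if total <= 0:
        raise ValueError(
            "non-positive integrated intensity in window (bleach-dominated?)"
        )
    first = np.trapezoid(grid[sel] * values[sel], grid[sel])
    return float(first / total)


def intensity_breakdown(
    lines: Sequence[SpectralLine], window: BandWindow
) -> dict[str, float]:
    """Intensity-weighted fractions by band kind within the window.

    Returns {'fundamental': f, 'combination': c, 'overtone': o}; fractions
    sum to 1 when any intensity is present, and are all 0 otherwise.
    """
    sums = {"fundamental": 0.0, "combination": 0.0, "overtone": 0.0}
    for line in lines:
        if window.nu_lo <= line.position <= window.nu_hi:
            sums[line.band_kind] += line.intensity
    total = sum(sums.values())
    if total <= 0:
        return sums
    return {k: v / total for k, v in sums.items()}


def _decay(t: np.ndarray, k: float, sigma: float | None) -> np.ndarray:
    """exp(-k t) for t >= 0 (0 before), optionally convolved with a
    zero-centred Gaussian IRF of width sigma (analytic form)."""
    if sigma is None:
        return np.where(t >= 0, np.exp(-k * np.clip(t, 0, None)), 0.0)
    arg = k * (k * sigma**2 / 2.0 - t)
    return 0.5 * np.exp(np.clip(arg, None, 700.0)) * erfc(
        (k * sigma**2 - t) / (sigma * np.sqrt(2.0))
    )


def sequential_populations(
    t: np.ndarray, tau1: float, tau2: float, irf_fwhm: float | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(S1, S0*, S0) populations of the sequential first-order scheme.

    S1 = e^{-k1 t};  S0* = k1/(k2-k1) (e^{-k1 t} - e^{-k2 t}) with the
    k2 -> k1 limit k t e^{-k t};  S0 = 1 - S1 - S0*.  All components are 0
    for t < 0 (smoothly, when an instrument-response FWHM is supplied).
    """
    if tau1 <= 0 or tau2 <= 0:
        raise ValueError("lifetimes must be positive")
    t = np.asarray(t, dtype=float)
    k1, k2 = 1.0 / tau1, 1.0 / tau2
    sigma = None
    if irf_fwhm is not None:
        sigma = irf_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    d1 = _decay(t, k1, sigma)
    if abs(k2 - k1) < 3e-4 * k1:  # degenerate: k t e^{-k t} limit form
        if sigma is None:
            tc = np.clip(t, 0, None)
            s0star = np.where(t >= 0, k1 * tc * np.exp(-k1 * tc), 0.0)
        else:  # central difference of the generic form at the degeneracy
            dk = 1e-6 * k1
            s0star = (k1 / dk / 2.0) * (_decay(t, k1 - dk, sigma) - _decay(t, k1 + dk, sigma))
    else:
        # outside the degenerate band the direct difference loses at most
        # ~eps/(|k2-k1| t) ~ 1e-13 to cancellation
        s0star = k1 / (k2 - k1) * (d1 - _decay(t, k2, sigma))
    step = _decay(t, 1e-30, sigma)  # ~ Heaviside (IRF-smoothed)
    return d1, s0star, step - d1 - s0star


def sequential_model(
    t: np.ndarray,
    tau1: float,
    tau2: float,
    amp_s1: float = 0.0,
    amp_hot: float = 1.0,
    amp_ground: float = 0.0,
    baseline: float = 0.0,
    irf_fwhm: float | None = None,
) -> np.ndarray:
    """Observable of the sequential scheme: baseline + a1 S1 + a2 S0* +
    a3 S0 (S0 = ground-state recovery)."""
    s1, s0star, s0 = sequential_populations(t, tau1, tau2, irf_fwhm)
    return baseline + amp_s1 * s1 + amp_hot * s0star + amp_ground * s0


@dataclass
class SequentialFit:
    """Least-squares estimates for the sequential model.

    The fit works in the identifiable basis {1, S1, S0*}: because
    S1 + S0* + S0 = 1, a separate ground-recovery amplitude is perfectly
    collinear with the baseline and the other two amplitudes, so it is
    absorbed (a trace  b + a1 S1 + a2 S0* + a3 S0  maps to  baseline = b +
    a3, amp_s1 = a1 - a3, amp_hot = a2 - a3).
    """

    tau1: float
    tau2: float
    amp_s1: float
    amp_hot: float
    baseline: float
    covariance: np.ndarray | None
    tau_stderr: tuple[float, float] | None
    identifiable: bool
    residual_norm: float


def fit_sequential(
    trace: KineticTrace,
    tau1_guess: float,
    tau2_guess: float,
    irf_fwhm: float | None = None,
    fit_s1: bool = True,
) -> SequentialFit:
    """Nonlinear least squares of the sequential model to a kinetic trace.

    Lifetimes are constrained positive.  When the Jacobian at the optimum is
    rank-deficient or the kinetic amplitudes vanish (e.g. a constant trace)
    the tau standard errors are withheld and ``identifiable`` is False.
    """
    if trace.times.size < 5:
        raise ValueError("need at least 5 time points")

    def model(t, tau1, tau2, amp_hot, amp_s1, baseline):
        s1, s0star, _ = sequential_populations(t, tau1, tau2, irf_fwhm)
        return baseline + amp_s1 * s1 + amp_hot * s0star

    scale = float(np.max(np.abs(trace.values))) or 1.0
    p0 = [tau1_guess, tau2_guess, scale, scale if fit_s1 else 0.0, 0.0]
    lower = [1e-9, 1e-9, -np.inf, -np.inf if fit_s1 else -1e-12, -np.inf]
    upper = [np.inf, np.inf, np.inf, np.inf if fit_s1 else 1e-12, np.inf]
    sigma = trace.uncertainty
    try:
        popt, pcov = curve_fit(
            model, trace.times, trace.values, p0=p0,
            sigma=sigma, bounds=(lower, upper), maxfev=20_000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"sequential fit did not converge: {exc}") from exc
    resid = trace.values - model(trace.times, *popt)

    # identifiability: numerically full-rank Jacobian and non-negligible
    # kinetic amplitude at the optimum
    jac = _numerical_jacobian(model, trace.times, popt)
    sv = np.linalg.svd(jac, compute_uv=False)
    rank_ok = bool(sv[0] > 0 and sv[-1] / sv[0] > 1e-9)
    amp_scale = max(abs(popt[2]), abs(popt[3]))
    identifiable = bool(
        rank_ok and amp_scale > 1e-6 * scale and np.all(np.isfinite(pcov))
    )
    tau_stderr = None
    if identifiable:
        err = np.sqrt(np.diag(pcov)[:2])
        if np.all(np.isfinite(err)):
            tau_stderr = (float(err[0]), float(err[1]))
        else:
            identifiable = False
    return SequentialFit(
        tau1=float(popt[0]), tau2=float(popt[1]),
        amp_s1=float(popt[3]), amp_hot=float(popt[2]),
        baseline=float(popt[4]),
        covariance=pcov if identifiable else None,
        tau_stderr=tau_stderr, identifiable=identifiable,
        residual_norm=float(np.linalg.norm(resid)),
    )


def _numerical_jacobian(model, t, popt) -> np.ndarray:
    cols = []
    for j, p in enumerate(popt):
        h = 1e-6 * max(abs(p), 1e-6)
        hi = list(popt)
        lo = list(popt)
        hi[j] = p + h
        lo[j] = max(p - h, 1e-12) if j < 2 else p - h  # lifetimes stay positive
        cols.append((model(t, *hi) - model(t, *lo)) / (hi[j] - lo[j]))
    return np.array(cols).T
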