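"""Population-curve fitting, SOC-scaling lifetime extrapolation, and rates.

Accelerated-ISC post-processing: golden-rule transition rates scale as the
square of the coupling, k proportional to V^2, so multiplying the SOC by
alpha shortens the lifetime to tau_alpha = tau_1 alpha^-2, i.e. a straight
line log tau_alpha = log tau_1 - 2 log alpha.  Lifetimes fitted at several
alpha > 1 are extrapolated back to alpha = 1 by an *unweighted free-slope*
least-squares line in log10-log10 space; the fitted slope is reported for
comparison with the theoretical -2.  (The free slope is a deliberate
choice: it is what makes extrapolation robust when the fitted lifetimes
deviate from the exact alpha^-2 law.)

Rate/yield formulas:

    k = 1 / tau
    k_F = 2 pi e^2 E_F^2 f / (h^2 eps0 m c^3)      (Einstein spontaneous emission)
    Phi_T = k_ISC / (k_ISC + k_IC + k_F)           (triplet quantum yield)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit

from .constants import CODATA2018
from .spin_mixing import PopulationSeries

__all__ = [
    "DecayFit",
    "ExtrapolationResult",
    "RateSet",
    "fit_growth",
    "fit_decay",
    "fit_rate_loglinear",
    "extrapolate_to_unit_alpha",
    "rate_from_lifetime",
    "einstein_rate",
    "triplet_quantum_yield",
]


class FitError(RuntimeError):
    """Degenerate input or non-convergent least squares."""


@dataclass
class DecayFit:
    """A fitted scaled-and-shifted (complementary) exponential."""

    tau_fs: float
    amplitude: float
    shift_fs: float
    offset: float
    model_form: str              # "complementary_exponential_growth" | "exponential_decay"
    residual_rms: float

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        if self.model_form == "complementary_exponential_growth":
            return _growth(t, self.amplitude, self.tau_fs, self.shift_fs)
        return _decay(t, self.amplitude, self.tau_fs, self.shift_fs, self.offset)


@dataclass
class ExtrapolationResult:
    tau1_fs: float
    slope: float
    intercept_log10_fs: float
    alphas_used: np.ndarray
    taus_used_fs: np.ndarray

    def tau_at(self, alpha: float) -> float:
        """Evaluate the fitted line back at any alpha (fs)."""
        return 10.0 ** (self.intercept_log10_fs + self.slope * np.log10(alpha))


@dataclass
class RateSet:
    """First-order rate constants (s^-1) and the derived triplet yield."""

    k_isc: float
    k_ic: float
    k_f: float
    e_f_ev: float = np.nan
    f: float = np.nan

    @property
    def phi_t(self) -> float:
        return triplet_quantum_yield(self.k_isc, self.k_ic, self.k_f)


def _growth(t, a, tau, t0):
    return a * (1.0 - np.exp(-(t - t0) / tau))


def _decay(t, a, tau, t0, b):
    return b + a * np.exp(-(t - t0) / tau)


def _series_inputs(series, which) -> Tuple[np.ndarray, np.ndarray]:
    if isinstance(series, PopulationSeries):
        t = np.asarray(series.times_fs, dtype=float)
        y = np.asarray(series.select(which), dtype=float)
    else:
        t, y = (np.asarray(v, dtype=float) for v in series)
    if len(t) < 10:
        raise FitError("need at least 10 time points")
    if np.any((y < -1e-9) | (y > 1 + 1e-9)):
        raise FitError("populations must lie in [0, 1]")
    return t, y


def fit_growth(series, which="triplets") -> DecayFit:
    """Fit p(t) = A (1 - exp(-(t - t0)/tau)) with A in [0, 1].

    ``series`` is a PopulationSeries (with ``which`` selecting the summed
    state set, default the total triplet population) or a bare (t, p)
    pair.  Raises :class:`FitError` on flat/degenerate input instead of
    returning a silent number.
    """
    t, y = _series_inputs(series, which)
    if np.ptp(y) < 1e-12:
        raise FitError("constant series: growth time constant is unidentifiable")
    a0 = min(max(y[-1], 1e-3), 1.0)
    tau0 = _guess_tau(t, y, growth=True)
    try:
        popt, _ = curve_fit(
            _growth, t, y,
            p0=[a0, tau0, t[0]],
            bounds=([0.0, 1e-6, t[0] - (t[-1] - t[0])], [1.0, np.inf, t[-1]]),
            maxfev=20000, xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
    except RuntimeError as err:
        raise FitError(f"growth fit did not converge: {err}") from err
    resid = y - _growth(t, *popt)
    return DecayFit(
        tau_fs=float(popt[1]), amplitude=float(popt[0]), shift_fs=float(popt[2]),
        offset=0.0, model_form="complementary_exponential_growth",
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def fit_decay(series, which="S1") -> DecayFit:
    """Fit p(t) = B + A exp(-(t - t0)/tau) with B >= 0 (the "shifted" baseline)."""
    t, y = _series_inputs(series, which)
    if np.ptp(y) < 1e-12:
        raise FitError("constant series: decay time constant is unidentifiable")
    tau0 = _guess_tau(t, y, growth=False)
    # A and t0 are degenerate (A e^{t0/tau} is the identifiable combination);
    # pin t0 to the first time point and let A absorb the shift.
    def f(tt, a, tau, b):
        return _decay(tt, a, tau, t[0], b)
    try:
        popt, _ = curve_fit(
            f, t, y,
            p0=[max(y[0] - y[-1], 1e-3), tau0, max(y[-1], 0.0)],
            bounds=([0.0, 1e-6, 0.0], [np.inf, np.inf, 1.0]),
            maxfev=20000, xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
    except RuntimeError as err:
        raise FitError(f"decay fit did not converge: {err}") from err
    resid = y - f(t, *popt)
    return DecayFit(
        tau_fs=float(popt[1]), amplitude=float(popt[0]), shift_fs=float(t[0]),
        offset=float(popt[2]), model_form="exponential_decay",
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def fit_rate_loglinear(
    series,
    which="S1",
    t_max_fs: Optional[float] = None,
    skip_fraction: float = 0.1,
) -> DecayFit:
    """Effective decay lifetime from a log-linear fit of the population.

    Least-squares line through (t, ln p) over the window
    [skip_fraction * t_max, t_max]; tau = -1/slope.  For a pure
    exponential this equals the nonlinear fit; for the near-exponential
    ensemble decays of surface-hopping populations it is the robust
    choice on windows too short to pin a floor offset, because it has no
    amplitude/offset degeneracy.  When lifetimes at several SOC scaling
    factors are compared, using windows proportional to alpha^-2 (the
    same span in units of the expected lifetime) makes the window bias
    cancel in lifetime *ratios* — the quantity the acceleration law is
    about.  The initial ``skip_fraction`` of the window excludes the
    coherent admixture transient.
    """
    t, y = _series_inputs(series, which)
    if t_max_fs is None:
        t_max_fs = float(t[-1])
    m = (t >= skip_fraction * t_max_fs) & (t <= t_max_fs) & (y > 0)
    if m.sum() < 10:
        raise FitError("fewer than 10 usable points in the fit window")
    slope, intercept = np.polyfit(t[m], np.log(y[m]), 1)
    if slope >= 0:
        raise FitError("population does not decay over the fit window")
    resid = np.log(y[m]) - (slope * t[m] + intercept)
    return DecayFit(
        tau_fs=float(-1.0 / slope),
        amplitude=float(np.exp(intercept)),
        shift_fs=float(t[m][0]),
        offset=0.0,
        model_form="exponential_decay",
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def _guess_tau(t: np.ndarray, y: np.ndarray, growth: bool) -> float:
    """Initial tau from the 10%/90% crossing times of the normalized curve."""
    y0, y1 = y[0], y[-1]
    span = y1 - y0
    if abs(span) < 1e-12:
        return (t[-1] - t[0]) / 3.0
    z = (y - y0) / span
    lo = np.searchsorted(np.maximum.accumulate(z), 0.1)
    hi = np.searchsorted(np.maximum.accumulate(z), 0.632)
    lo = min(lo, len(t) - 1)
    hi = min(hi, len(t) - 1)
    tau = t[hi] - t[lo]
    return tau if tau > 0 else (t[-1] - t[0]) / 3.0


def extrapolate_to_unit_alpha(
    alphas: Sequence[float], taus_fs: Sequence[float]
) -> ExtrapolationResult:
    """Free-slope log10-log10 extrapolation of lifetimes to alpha = 1.

    Unweighted least-squares line through (log10 alpha, log10 tau);
    tau_1 = 10^intercept.  Requires >= 2 distinct alphas > 1 and positive
    lifetimes.  The result is invariant to the logarithm base.
    """
    a = np.asarray(alphas, dtype=float)
    t = np.asarray(taus_fs, dtype=float)
    if a.shape != t.shape or a.ndim != 1:
        raise ValueError("alphas and taus must be 1-D of equal length")
    if len(a) < 2:
        raise ValueError("need at least 2 (alpha, tau) points")
    if len(np.unique(a)) != len(a):
        raise ValueError("duplicate alphas")
    if np.any(a <= 1.0) or np.any(t <= 0.0):
        raise ValueError("need alphas > 1 and taus > 0")
    slope, intercept = np.polyfit(np.log10(a), np.log10(t), 1)
    return ExtrapolationResult(
        tau1_fs=float(10.0**intercept),
        slope=float(slope),
        intercept_log10_fs=float(intercept),
        alphas_used=a,
        taus_used_fs=t,
    )


def rate_from_lifetime(tau_fs: float) -> float:
    """k = 1/tau in s^-1 from a lifetime in fs."""
    if tau_fs <= 0:
        raise ValueError("tau must be > 0")
    return 1.0 / (tau_fs * 1e-15)


def einstein_rate(e_f_ev: float, f: float) -> float:
    """Einstein spontaneous-emission rate k_F = 2 pi e^2 E_F^2 f / (h^2 eps0 m c^3).

    ``e_f_ev`` is the emission energy in eV, ``f`` the (dimensionless)
    oscillator strength; returns s^-1.
    """
    if e_f_ev <= 0:
        raise ValueError("emission energy must be > 0")
    if f < 0:
        raise ValueError("oscillator strength must be >= 0")
    k = CODATA2018
    e_f_joule = e_f_ev * k.e
    return 2.0 * np.pi * k.e**2 * e_f_joule**2 * f / (k.h**2 * k.eps0 * k.m * k.c**3)


def triplet_quantum_yield(k_isc: float, k_ic: float, k_f: float) -> float:
    """Phi_T = k_ISC / (k_ISC + k_IC + k_F); scale-invariant, in [0, 1]."""
    if min(k_isc, k_ic, k_f) < 0:
        raise ValueError("rates must be >= 0")
    total = k_isc + k_ic + k_f
    if total == 0:
        raise ValueError("all rates are zero")
    return k_isc / total
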