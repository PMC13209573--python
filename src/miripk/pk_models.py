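"""Closed-form compartmental kinetics with first-order absorption.

All other modules build on the forward models here: the one- and
two-compartment disposition curves after extravascular (i.p.) dosing, the
closed-form peak of the one-compartment curve, and the effect-site
(biophase) concentration obtained by driving ``dCe/dt = ke0 (Cp - Ce)``
with a plasma curve.

Units are fixed throughout the package: time in minutes, concentration in
mg/L, volumes in L/kg, doses in mg/kg, rate constants in 1/min.  Because
dosing is intraperitoneal, bioavailability F is not separable; every volume
and clearance is apparent (V/F, CL/F).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ParameterDomainError",
    "OneCmtParams",
    "TwoCmtParams",
    "EffectLinkParams",
    "conc_1cmt",
    "conc_2cmt",
    "tmax_cmax_1cmt",
    "effect_site_conc",
]

#: relative threshold below which two rate constants are treated as equal
#: and the analytic limit form is used (avoids catastrophic cancellation in
#: differences of exponentials).
RATE_EQUAL_RTOL = 1e-8


class ParameterDomainError(ValueError):
    """A kinetic parameter is outside its physical domain."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ParameterDomainError(msg)


@dataclass(frozen=True)
class OneCmtParams:
    """One-compartment, first-order absorption parameters.

    ka, ke in 1/min; v is the apparent volume V/F in L/kg; tlag in min;
    dose in mg/kg.
    """

    ka: float
    ke: float
    v: float
    dose: float
    tlag: float = 0.0

    def __post_init__(self) -> None:
        _require(self.ka > 0, f"ka must be > 0, got {self.ka}")
        _require(self.ke > 0, f"ke must be > 0, got {self.ke}")
        _require(self.v > 0, f"v must be > 0, got {self.v}")
        _require(self.tlag >= 0, f"tlag must be >= 0, got {self.tlag}")
        _require(self.dose >= 0, f"dose must be >= 0, got {self.dose}")

    def with_dose(self, dose: float) -> "OneCmtParams":
        return replace(self, dose=dose)


@dataclass(frozen=True)
class TwoCmtParams:
    """Two-compartment, first-order absorption micro-constant parameters.

    k10 is central elimination; k12/k21 the distribution micro-constants;
    v1 the apparent central volume V1/F.
    """

    ka: float
    k10: float
    k12: float
    k21: float
    v1: float
    dose: float
    tlag: float = 0.0

    def __post_init__(self) -> None:
        for name in ("ka", "k10", "k12", "k21"):
            _require(getattr(self, name) > 0, f"{name} must be > 0")
        _require(self.v1 > 0, f"v1 must be > 0, got {self.v1}")
        _require(self.tlag >= 0, f"tlag must be >= 0, got {self.tlag}")
        _require(self.dose >= 0, f"dose must be >= 0, got {self.dose}")

    @property
    def hybrid_rates(self) -> tuple[float, float]:
        """Hybrid macro-constants (alpha, beta), alpha > beta > 0."""
        s = self.k10 + self.k12 + self.k21
        disc = s * s - 4.0 * self.k10 * self.k21
        if disc < 0:  # unreachable for positive micro-constants, kept as a guard
            raise ParameterDomainError(
                "complex hybrid rate constants (discriminant < 0)"
            )
        root = math.sqrt(disc)
        alpha = 0.5 * (s + root)
        beta = 0.5 * (s - root)
        _require(beta > 0, "beta must be > 0 (degenerate micro-constants)")
        return alpha, beta

    def with_dose(self, dose: float) -> "TwoCmtParams":
        return replace(self, dose=dose)


@dataclass(frozen=True)
class EffectLinkParams:
    """Effect-compartment link: ke0 is the biophase equilibration rate (1/min)."""

    ke0: float

    def __post_init__(self) -> None:
        _require(self.ke0 > 0, f"ke0 must be > 0, got {self.ke0}")


def _as_times(times) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if t.ndim != 1:
        raise ValueError("times must be one-dimensional")
    if t.size and t.min() < 0:
        raise ValueError("times must be >= 0")
    if t.size > 1 and np.any(np.diff(t) < 0):
        raise ValueError("times must be ascending")
    return t


def _expdiff(a: float, b: float, tau: np.ndarray) -> np.ndarray:
    """(exp(-a*tau) - exp(-b*tau)) / (b - a), with the a==b limit tau*exp(-a*tau)."""
    if abs(a - b) < RATE_EQUAL_RTOL * max(abs(a), abs(b)):
        return tau * np.exp(-a * tau)
    return (np.exp(-a * tau) - np.exp(-b * tau)) / (b - a)


def conc_1cmt(p: OneCmtParams, times) -> np.ndarray:
    """Plasma concentration of the one-compartment first-order absorption model.

    C(t) = D*ka / (V*(ka-ke)) * (exp(-ke*tau) - exp(-ka*tau)) for
    tau = t - tlag > 0 and 0 otherwise.  When |ka - ke| is below
    ``RATE_EQUAL_RTOL * max(ka, ke)`` the analytic limit
    C = (D*ka/V) * tau * exp(-ka*tau) is used.
    """
    t = _as_times(times)
    tau = t - p.tlag
    pos = tau > 0
    out = np.zeros_like(t)
    taup = tau[pos]
    out[pos] = (p.dose * p.ka / p.v) * _expdiff(p.ke, p.ka, taup)
    return np.maximum(out, 0.0)


def conc_2cmt(p: TwoCmtParams, times) -> np.ndarray:
    """Plasma concentration of the two-compartment first-order absorption model.

    Standard triexponential solution in exp(-ka*tau), exp(-alpha*tau),
    exp(-beta*tau).  If ka numerically coincides with alpha or beta (a
    measure-zero input), ka is nudged by one part in 1e9 so the generic
    three-exponential form applies.
    """
    t = _as_times(times)
    alpha, beta = p.hybrid_rates
    ka = p.ka
    for lam in (alpha, beta):
        if abs(ka - lam) < RATE_EQUAL_RTOL * max(ka, lam):
            ka = ka * (1.0 + 1e-9) + 1e-15
    tau = t - p.tlag
    pos = tau > 0
    out = np.zeros_like(t)
    taup = tau[pos]
    coef = p.dose * ka / p.v1
    with np.errstate(all="ignore"):  # extreme rates may overflow transiently
        terms = (
            (p.k21 - alpha) / ((ka - alpha) * (beta - alpha)) * np.exp(-alpha * taup)
            + (p.k21 - beta) / ((ka - beta) * (alpha - beta)) * np.exp(-beta * taup)
            + (p.k21 - ka) / ((alpha - ka) * (beta - ka)) * np.exp(-ka * taup)
        )
        vals = coef * terms
    out[pos] = np.where(np.isfinite(vals), vals, 0.0)
    return np.maximum(out, 0.0)


def tmax_cmax_1cmt(p: OneCmtParams) -> tuple[float, float]:
    """Closed-form peak (Tmax, Cmax) of the one-compartment curve.

    Tmax = tlag + ln(ka/ke)/(ka - ke); in the ka == ke limit
    Tmax = tlag + 1/ka.
    """
    if abs(p.ka - p.ke) < RATE_EQUAL_RTOL * max(p.ka, p.ke):
        tmax = p.tlag + 1.0 / p.ka
    else:
        tmax = p.tlag + math.log(p.ka / p.ke) / (p.ka - p.ke)
    cmax = float(conc_1cmt(p, np.array([tmax]))[0])
    return tmax, cmax


def _effect_site_analytic(p: OneCmtParams, ke0: float, t: np.ndarray) -> np.ndarray:
    # convolution of the biexponential plasma curve with ke0*exp(-ke0 s):
    # Ce = ke0 * A * [E(ke) - E(ka)], E(k) = (e^{-k tau}-e^{-ke0 tau})/(ke0-k),
    # A = D ka / (V (ka - ke)).  The measure-zero ka == ke case is resolved
    # by a one-part-in-1e9 nudge of ke.
    tau = t - p.tlag
    pos = tau > 0
    out = np.zeros_like(t)
    taup = tau[pos]
    ka, ke = p.ka, p.ke
    if abs(ka - ke) < RATE_EQUAL_RTOL * max(ka, ke):
        ke = ke * (1.0 - 1e-9) - 1e-15
    a = p.dose * ka / (p.v * (ka - ke))
    out[pos] = ke0 * a * (_expdiff(ke, ke0, taup) - _expdiff(ka, ke0, taup))
    return np.maximum(out, 0.0)


def _effect_site_tabulated(
    tab_times: np.ndarray, tab_conc: np.ndarray, ke0: float, t: np.ndarray
) -> np.ndarray:
    # exact update per linear segment: for Cp(s) = a + b*s on [0, h],
    # Ce(h) = Ce0 e^{-k h} + a (1 - e^{-k h}) + b (h - (1 - e^{-k h})/k)
    if tab_times.size < 2:
        raise ValueError("tabulated profile needs >= 2 points")
    grid = np.union1d(tab_times, t)
    grid = grid[(grid >= tab_times[0]) & (grid <= tab_times[-1])]
    cp = np.interp(grid, tab_times, tab_conc)
    ce = np.zeros_like(grid)
    for i in range(1, grid.size):
        h = grid[i] - grid[i - 1]
        if h <= 0:
            ce[i] = ce[i - 1]
            continue
        a0 = cp[i - 1]
        b = (cp[i] - cp[i - 1]) / h
        em = math.exp(-ke0 * h)
        ce[i] = ce[i - 1] * em + a0 * (1 - em) + b * (h - (1 - em) / ke0)
    out = np.interp(t, grid, ce, left=0.0)
    if t.size and t[-1] > tab_times[-1]:
        raise ValueError("requested times extend beyond the tabulated profile")
    return out


def effect_site_conc(plasma, link: EffectLinkParams, times) -> np.ndarray:
    """Effect-site concentration Ce driven by a plasma curve.

    ``plasma`` is either a :class:`OneCmtParams` (analytic convolution) or a
    ``(times, concentrations)`` pair of arrays, integrated exactly over each
    linear interpolation segment.  Ce starts at 0 at the start of the
    profile and lags the plasma curve; its peak occurs at or after the
    plasma Tmax.
    """
    t = _as_times(times)
    ke0 = link.ke0
    if isinstance(plasma, OneCmtParams):
        return _effect_site_analytic(plasma, ke0, t)
    tab_t, tab_c = plasma
    tab_t = _as_times(tab_t)
    tab_c = np.asarray(tab_c, dtype=float)
    if tab_t.shape != tab_c.shape:
        raise ValueError("tabulated times and concentrations differ in length")
    return _effect_site_tabulated(tab_t, tab_c, ke0, t)
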