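"""Exploratory exposure-response layer: delta-CK-MB, hysteresis, Ke0 scan.

The treatment-related pharmacodynamic signal is
``delta-CK-MB(t) = CK-MB_untreated(t) - CK-MB_treated(t)`` at matched
times.  Plotting it against plasma concentration traces a loop whenever
the response lags exposure; the signed, normalized loop area quantifies
the lag (positive = counterclockwise = effect higher on the descending
limb).  Driving the effect through a hypothetical biophase
(dCe/dt = ke0*(Cp - Ce)) and rescanning ke0 collapses the loop when ke0
matches the true equilibration rate; the scan reports per-ke0 convergence,
SSR, AIC, the observed-vs-fitted Pearson correlation and the residual loop
area in the (Ce, delta) plane.

"CORR" here is the Pearson correlation between observed and fitted
effect; the PD AIC uses the same n*ln(SSR) + 2p convention as the
compartmental fitting module.  Loop areas are normalized by the bounding
rectangle (max-min of each axis), so they are invariant to affine
rescaling of either axis and bounded by 1 in magnitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .pk_models import EffectLinkParams, OneCmtParams, effect_site_conc

__all__ = [
    "EffectCourse",
    "DeltaEffect",
    "HysteresisResult",
    "EffectFit",
    "Ke0ScanRow",
    "DEFAULT_KE0_GRID",
    "delta_ckmb",
    "hysteresis_loop",
    "fit_effect_model",
    "ke0_scan",
]

#: default ke0 grid (1/min), spanning fast to very slow biophase equilibration
DEFAULT_KE0_GRID = (0.01, 0.005, 0.002, 0.001, 0.0005, 0.0002, 0.0001, 0.00005)


@dataclass(frozen=True)
class EffectCourse:
    group: str
    times: tuple[float, ...]
    ckmb: tuple[float, ...]  # ng/mL

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.ckmb, dtype=float)
        if t.size != c.size:
            raise ValueError("times and ckmb differ in length")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly ascending")
        if np.any(c < 0):
            raise ValueError("ckmb must be >= 0")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EffectCourse":
        df = df.sort_values("time_min")
        return cls(group=str(df.group.iloc[0]),
                   times=tuple(df.time_min.astype(float)),
                   ckmb=tuple(df.ckmb_ng_per_mL.astype(float)))


@dataclass(frozen=True)
class DeltaEffect:
    times: tuple[float, ...]
    delta: tuple[float, ...]  # ng/mL; may be negative under noise


@dataclass(frozen=True)
class HysteresisResult:
    signed_area_normalized: float
    direction: str  # "counterclockwise" | "clockwise" | "degenerate"


@dataclass(frozen=True)
class EffectFit:
    params: dict[str, float]
    ssr: float
    aic: float
    corr: float  # NaN when undefined
    converged: bool
    reason: str
    fitted: tuple[float, ...]


@dataclass(frozen=True)
class Ke0ScanRow:
    ke0: float
    converged: bool
    reason: str
    ssr: float
    aic: float
    corr: float
    loop_area_normalized: float


def delta_ckmb(untreated: EffectCourse, treated: EffectCourse) -> DeltaEffect:
    """Untreated-minus-treated CK-MB at exactly matched times (no interpolation)."""
    tu = np.asarray(untreated.times)
    tt = np.asarray(treated.times)
    common, iu, it = np.intersect1d(tu, tt, return_indices=True)
    if common.size < 3:
        raise ValueError(
            f"only {common.size} matched time points; at least 3 required"
        )
    d = np.asarray(untreated.ckmb)[iu] - np.asarray(treated.ckmb)[it]
    return DeltaEffect(times=tuple(common), delta=tuple(d))


def hysteresis_loop(concs, delta) -> HysteresisResult:
    """Signed, normalized hysteresis loop area.

    The (concentration, effect) path is traversed in time order and closed
    last-to-first; the shoelace signed area is divided by the bounding
    rectangle (conc range * effect range).  Positive area means the loop
    runs counterclockwise with concentration on the x-axis, i.e. the
    effect is larger on the falling-concentration limb.
    """
    x = np.asarray(concs, dtype=float)
    y = np.asarray(delta.delta if isinstance(delta, DeltaEffect) else delta,
                   dtype=float)
    if x.size != y.size:
        raise ValueError("concentration and effect series differ in length")
    if x.size < 3:
        raise ValueError("at least 3 matched points are required")
    rx = float(np.ptp(x))
    ry = float(np.ptp(y))
    if rx == 0 or ry == 0:
        return HysteresisResult(0.0, "degenerate")
    area = 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
    norm = area / (rx * ry)
    if abs(norm) < 1e-12:
        return HysteresisResult(0.0, "degenerate")
    return HysteresisResult(norm,
                            "counterclockwise" if norm > 0 else "clockwise")


def _pearson(obs: np.ndarray, fit: np.ndarray) -> float:
    if np.std(obs) == 0 or np.std(fit) == 0:
        return float("nan")
    return float(np.corrcoef(obs, fit)[0, 1])


def fit_effect_model(ce, delta: DeltaEffect, pd_model: str = "linear") -> EffectFit:
    """Fit the effect as a function of effect-site concentration.

    linear: delta = E0 + S*Ce by ordinary least squares;
    emax:   delta = Emax*Ce/(EC50 + Ce) by bounded least squares
    (an EC50 at its bound counts as non-convergence).
    """
    x = np.asarray(ce, dtype=float)
    y = np.asarray(delta.delta, dtype=float)
    if x.size != y.size:
        raise ValueError("ce and delta must be aligned on the same times")
    n = x.size
    if pd_model == "linear":
        design = np.column_stack([np.ones(n), x])
        if np.ptp(x) == 0:
            return EffectFit({}, float("nan"), float("nan"), float("nan"),
                             False, "degenerate_ce_range", tuple(np.zeros(n)))
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        fitted = design @ coef
        params = {"e0": float(coef[0]), "slope": float(coef[1])}
        p = 2
        reason = "ok"
        converged = True
    elif pd_model == "emax":
        scale = max(np.max(np.abs(y)), 1e-9)
        lb = np.array([1e-9, 1e-9])
        ub = np.array([10.0 * scale, 100.0 * max(x.max(), 1e-9)])
        x0 = np.array([max(y.max(), 1e-3), max(np.median(x), 1e-6)])

        def resid(th):
            return th[0] * x / (th[1] + x) - y

        sol = least_squares(resid, np.clip(x0, lb * 1.01, ub * 0.99),
                            bounds=(lb, ub), xtol=1e-12, ftol=1e-12)
        fitted = sol.x[0] * x / (sol.x[1] + x)
        params = {"emax": float(sol.x[0]), "ec50": float(sol.x[1])}
        p = 2
        margin = 1e-6 * (ub - lb)
        at_bound = bool(np.any(sol.x <= lb + margin) or np.any(sol.x >= ub - margin))
        converged = bool(sol.success) and not at_bound
        reason = "ok" if converged else (
            "parameter_at_bound" if at_bound else "optimizer_failure")
    else:
        raise ValueError(f"unknown pd_model {pd_model!r}")
    ssr = float(np.sum((y - fitted) ** 2))
    aic = n * math.log(ssr) + 2 * p if ssr > 0 else float("-inf")
    corr = _pearson(y, fitted)
    return EffectFit(params, ssr, aic, corr, converged, reason, tuple(fitted))


def ke0_scan(
    plasma,
    untreated: EffectCourse,
    treated: EffectCourse,
    ke0_grid=DEFAULT_KE0_GRID,
    pd_model: str = "linear",
) -> tuple[pd.DataFrame, Ke0ScanRow | None]:
    """Effect-compartment ke0 sensitivity scan.

    ``plasma`` is a fitted :class:`OneCmtParams` or a ``(times, conc)``
    tabulated profile.  For each candidate ke0 the effect-site curve is
    computed at the matched effect times, the PD model is fitted, and the
    residual loop area in the (Ce, delta) plane is recorded.  Best row =
    lowest PD AIC among converged rows; ties break toward higher
    correlation, then larger ke0.
    """
    grid = [float(k) for k in ke0_grid]
    if len(grid) < 2 or any(k <= 0 for k in grid):
        raise ValueError("ke0 grid needs >= 2 positive values")
    d = delta_ckmb(untreated, treated)
    t = np.asarray(d.times, dtype=float)
    rows: list[Ke0ScanRow] = []
    for ke0 in grid:
        ce = effect_site_conc(plasma, EffectLinkParams(ke0), t)
        fit = fit_effect_model(ce, d, pd_model)
        try:
            loop = hysteresis_loop(ce, d)
            area = abs(loop.signed_area_normalized)
        except ValueError:
            area = float("nan")
        if fit.converged:
            rows.append(Ke0ScanRow(ke0, True, "ok", fit.ssr, fit.aic,
                                   fit.corr, area))
        else:
            rows.append(Ke0ScanRow(ke0, False, fit.reason, float("nan"),
                                   float("nan"), float("nan"), area))
    table = pd.DataFrame([r.__dict__ for r in rows])
    ok = [r for r in rows if r.converged]
    best = None
    if ok:
        def rank(r: Ke0ScanRow):
            corr = r.corr if np.isfinite(r.corr) else -np.inf
            return (r.aic, -corr, -r.ke0)

        best = min(ok, key=rank)
    return table, best
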