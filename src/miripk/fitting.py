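"""Weighted nonlinear least-squares compartmental fitting and diagnostics.

Covers the model re-evaluation layer: fitting a candidate model (one- or
two-compartment, first-order absorption, optional lag) to a concentration
profile by iteratively reweighted Levenberg-Marquardt under one of three
weighting schemes (unit, 1/Y-hat, 1/Y-hat^2), identifiability diagnostics
(parameter CV%, condition number of the weighted Jacobian), the AIC/SBC
information criteria in the n*ln(WSS) + penalty convention, the ordered
12-candidate ledger, a selection policy balancing fit, stability and
parsimony, and leave-one-rat-out robustness refitting.

The default fit target is the group mean concentration profile
(naive-mean fit): the study reports a single criterion set per group, and
the 13-point schedule makes n_obs = 13 for the mean profile.

Conventions recorded in every result:
  - AIC = n*ln(WSS) + 2p, SBC = n*ln(WSS) + p*ln(n); weighted criteria are
    comparable only within one weighting scheme.
  - condition number = ratio of extreme singular values of sqrt(W)*J.
  - convergence = relative parameter change < 1e-6 and relative WSS change
    < 1e-8 across reweighting iterations, all parameters strictly inside
    bounds, finite standard errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from . import nca
from .pk_models import RATE_EQUAL_RTOL, OneCmtParams, ParameterDomainError, \
    TwoCmtParams, conc_1cmt, conc_2cmt, tmax_cmax_1cmt

__all__ = [
    "ModelSpec",
    "FitResult",
    "SelectionPolicy",
    "SelectionResult",
    "LoroReport",
    "all_model_specs",
    "fit_model",
    "information_criteria",
    "condition_number",
    "candidate_ledger",
    "select_model",
    "loro",
]

STRUCTURES = ("one_compartment", "two_compartment")
WEIGHTINGS = ("unit", "inv_pred", "inv_pred_sq")

# bounds on the natural scale; rates 1/min, volumes L/kg
RATE_BOUNDS = (1e-6, 10.0)
VOLUME_BOUNDS = (1e-3, 1e3)

MAX_OUTER_ITER = 200
PARAM_RTOL = 1e-6
WSS_RTOL = 1e-8


@dataclass(frozen=True)
class ModelSpec:
    structure: str
    lag: bool
    weighting: str

    def __post_init__(self) -> None:
        if self.structure not in STRUCTURES:
            raise ValueError(f"unknown structure {self.structure!r}")
        if self.weighting not in WEIGHTINGS:
            raise ValueError(f"unknown weighting {self.weighting!r}")

    @property
    def param_names(self) -> tuple[str, ...]:
        if self.structure == "one_compartment":
            names = ("ka", "ke", "v")
        else:
            names = ("ka", "k10", "k12", "k21", "v1")
        return names + ("tlag",) if self.lag else names

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    @property
    def label(self) -> str:
        lag = "lag" if self.lag else "nolag"
        return f"{self.structure}/{lag}/{self.weighting}"


def all_model_specs() -> list[ModelSpec]:
    """The 12 candidate models in deterministic (structure, lag, weighting) order."""
    return [
        ModelSpec(s, lag, w)
        for s in STRUCTURES
        for lag in (False, True)
        for w in WEIGHTINGS
    ]


@dataclass
class FitResult:
    spec: ModelSpec
    estimates: dict[str, float]
    se: dict[str, float]
    cv_percent: dict[str, float]
    wss: float
    n_obs: int
    n_params: int
    aic: float
    sbc: float
    condition_number: float
    converged: bool
    reason: str
    residuals: np.ndarray
    predictions: np.ndarray
    predicted_cmax: float
    predicted_tmax: float
    predicted_auc: float

    @property
    def max_cv_percent(self) -> float:
        vals = [v for v in self.cv_percent.values() if np.isfinite(v)]
        return max(vals) if len(vals) == len(self.cv_percent) else float("inf")


def information_criteria(wss: float, n_obs: int, n_params: int) -> tuple[float, float]:
    """AIC and SBC in the n*ln(WSS) + penalty convention.

    A numerically perfect fit (wss <= 0) is reported as the -inf sentinel.
    """
    if n_obs <= n_params:
        raise ValueError("n_obs must exceed n_params")
    if wss < 0:
        raise ValueError("wss must be >= 0")
    if wss == 0:
        return float("-inf"), float("-inf")
    base = n_obs * math.log(wss)
    return base + 2.0 * n_params, base + n_params * math.log(n_obs)


def condition_number(jacobian: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Ratio of extreme singular values of the weight-scaled Jacobian.

    Rank-deficient Jacobians give the +inf sentinel.
    """
    j = np.asarray(jacobian, dtype=float)
    if weights is not None:
        j = np.sqrt(np.asarray(weights, dtype=float))[:, None] * j
    sv = np.linalg.svd(j, compute_uv=False)
    if sv.size == 0 or sv[-1] <= sv[0] * 1e-14 or sv[0] == 0:
        return float("inf")
    return float(sv[0] / sv[-1])


def _predict(spec: ModelSpec, theta: np.ndarray, times: np.ndarray,
             dose: float) -> np.ndarray:
    names = spec.param_names
    vals = dict(zip(names, theta))
    tlag = vals.get("tlag", 0.0)
    try:
        if spec.structure == "one_compartment":
            p = OneCmtParams(ka=vals["ka"], ke=vals["ke"], v=vals["v"],
                             dose=dose, tlag=tlag)
            return conc_1cmt(p, times)
        p = TwoCmtParams(ka=vals["ka"], k10=vals["k10"], k12=vals["k12"],
                         k21=vals["k21"], v1=vals["v1"], dose=dose, tlag=tlag)
        return conc_2cmt(p, times)
    except ParameterDomainError:
        # a degenerate excursion of the optimizer; zero predictions give a
        # large residual and steer the search back to the valid region
        return np.zeros_like(np.asarray(times, dtype=float))


def _make_predictor(spec: ModelSpec, times: np.ndarray, dose: float):
    """Allocation-light forward model theta -> predictions for the hot loop.

    Same mathematics as the public model functions, inlined to avoid
    per-evaluation dataclass and dict construction inside the optimizer.
    """
    one = spec.structure == "one_compartment"
    lag = spec.lag

    def predict(theta: np.ndarray) -> np.ndarray:
        tlag = theta[-1] if lag else 0.0
        tau = times - tlag
        pos = tau > 0
        out = np.zeros_like(times)
        taup = tau[pos]
        with np.errstate(all="ignore"):
            if one:
                ka, ke, v = theta[0], theta[1], theta[2]
                if abs(ka - ke) < RATE_EQUAL_RTOL * max(ka, ke):
                    vals = (dose * ka / v) * taup * np.exp(-ka * taup)
                else:
                    vals = (dose * ka / (v * (ka - ke))) * (
                        np.exp(-ke * taup) - np.exp(-ka * taup))
            else:
                ka, k10, k12, k21, v1 = theta[:5]
                s = k10 + k12 + k21
                disc = s * s - 4.0 * k10 * k21
                if disc < 0 or not np.isfinite(disc):
                    return out
                root = math.sqrt(disc)
                alpha = 0.5 * (s + root)
                beta = 0.5 * (s - root)
                if beta <= 0:
                    return out
                for lam in (alpha, beta):
                    if abs(ka - lam) < RATE_EQUAL_RTOL * max(ka, lam):
                        ka = ka * (1.0 + 1e-9) + 1e-15
                vals = (dose * ka / v1) * (
                    (k21 - alpha) / ((ka - alpha) * (beta - alpha))
                    * np.exp(-alpha * taup)
                    + (k21 - beta) / ((ka - beta) * (alpha - beta))
                    * np.exp(-beta * taup)
                    + (k21 - ka) / ((alpha - ka) * (beta - ka))
                    * np.exp(-ka * taup)
                )
        out[pos] = np.where(np.isfinite(vals), vals, 0.0)
        np.maximum(out, 0.0, out=out)
        return out

    return predict


def _bounds(spec: ModelSpec, tmax_lag: float):
    lo, hi = [], []
    for name in spec.param_names:
        if name == "tlag":
            lo.append(0.0)
            hi.append(tmax_lag)
        elif name in ("v", "v1"):
            lo.append(VOLUME_BOUNDS[0])
            hi.append(VOLUME_BOUNDS[1])
        else:
            lo.append(RATE_BOUNDS[0])
            hi.append(RATE_BOUNDS[1])
    return np.array(lo), np.array(hi)


def _to_internal(theta: np.ndarray, spec: ModelSpec) -> np.ndarray:
    # log scale for positive parameters, linear for tlag
    x = np.array(theta, dtype=float)
    for i, name in enumerate(spec.param_names):
        if name != "tlag":
            x[i] = math.log(x[i])
    return x


def _from_internal(x: np.ndarray, spec: ModelSpec) -> np.ndarray:
    theta = np.array(x, dtype=float)
    for i, name in enumerate(spec.param_names):
        if name != "tlag":
            theta[i] = math.exp(theta[i])
    return theta


def _strip_init(times: np.ndarray, concs: np.ndarray, dose: float) -> dict[str, float]:
    """Curve-stripping initial estimates: lambda_z -> ke, back-extrapolated
    V, residual-method ka (fallback ka = 5*ke)."""
    lz = nca.terminal_slope(times, concs)
    tlast = times[-1]
    if lz is not None:
        ke = lz.lambda_z
        b0 = math.exp(lz.intercept)
    else:
        ke = math.log(2) / max(tlast / 4.0, 1.0)
        b0 = max(concs.max(), 1e-6)
    auc_t, _ = nca.auc_aumc(times, concs)
    pos = np.flatnonzero(concs > 0)
    clast = concs[pos[-1]] if pos.size else 0.0
    auc_inf = auc_t + clast / ke
    v = dose / (auc_inf * ke) if auc_inf > 0 and dose > 0 else 1.0
    # residual (feathering) method on the absorption phase
    imax = int(np.argmax(concs))
    ka = 5.0 * ke
    early = np.flatnonzero((np.arange(times.size) <= imax) & (concs > 0))
    resid = b0 * np.exp(-ke * times[early]) - concs[early]
    ok = resid > 0
    if ok.sum() >= 2:
        slope = np.polyfit(times[early][ok], np.log(resid[ok]), 1)[0]
        if slope < 0:
            ka = -slope
    out = {"ka": ka, "ke": ke, "v": v}
    return out


def _initial_theta(spec: ModelSpec, init: dict[str, float],
                   first_time: float) -> np.ndarray:
    base = dict(init)
    if spec.structure == "two_compartment":
        ke = base.pop("ke", 0.01)
        v = base.pop("v", 1.0)
        base.setdefault("k10", ke)
        base.setdefault("k12", 0.5 * ke)
        base.setdefault("k21", 0.5 * ke)
        base.setdefault("v1", v)
    theta = []
    for name in spec.param_names:
        if name == "tlag":
            theta.append(base.get("tlag", 0.25 * first_time))
        else:
            lo, hi = VOLUME_BOUNDS if name in ("v", "v1") else RATE_BOUNDS
            theta.append(min(max(base.get(name, math.sqrt(lo * hi)),
                                 lo * 1.01), hi * 0.99))
    return np.array(theta)


def _start_set(spec: ModelSpec, base_theta: np.ndarray, max_starts: int = 9):
    """Base start plus one-at-a-time x0.3 / x3 perturbations, capped."""
    starts = [base_theta]
    for i, name in enumerate(spec.param_names):
        if name == "tlag":
            continue
        for factor in (0.3, 3.0):
            if len(starts) >= max_starts:
                return starts
            pert = base_theta.copy()
            lo, hi = VOLUME_BOUNDS if name in ("v", "v1") else RATE_BOUNDS
            pert[i] = min(max(pert[i] * factor, lo * 1.01), hi * 0.99)
            starts.append(pert)
    return starts


def _weights(spec: ModelSpec, pred: np.ndarray) -> np.ndarray:
    if spec.weighting == "unit":
        return np.ones_like(pred)
    floor = max(pred.max(), 1e-12) * 1e-8  # guard against zero predictions
    p = np.maximum(pred, floor)
    return 1.0 / p if spec.weighting == "inv_pred" else 1.0 / (p * p)


def _run_irls(spec: ModelSpec, x0: np.ndarray, times: np.ndarray,
              concs: np.ndarray, dose: float, lb: np.ndarray, hi: np.ndarray):
    """One IRLS solve from one start; returns (x, wss, weights, status).

    The inner solver is unconstrained Levenberg-Marquardt on the internal
    (log) scale; a wide safety clip keeps the exponentials finite and the
    caller classifies estimates at or beyond the declared bounds as
    non-converged.
    """
    span = hi - lb
    clip_lo, clip_hi = lb - 0.5 * span, hi + 0.5 * span
    # tlag is linear-scale and must stay physical during the search
    tlag_mask = np.array([n == "tlag" for n in spec.param_names])
    log_mask = ~tlag_mask
    clip_lo[tlag_mask] = lb[tlag_mask]
    clip_hi[tlag_mask] = hi[tlag_mask]
    forward = _make_predictor(spec, times, dose)

    def _theta(xi):
        th = np.clip(xi, clip_lo, clip_hi)
        th[log_mask] = np.exp(th[log_mask])
        return th

    x = np.clip(x0, lb, hi)
    pred = forward(_theta(x))
    w = _weights(spec, pred)
    wss_prev = None
    status = "max_iterations"
    n_outer = 1 if spec.weighting == "unit" else MAX_OUTER_ITER
    for _ in range(n_outer):
        sw = np.sqrt(w)

        def resid(xi):
            return sw * (concs - forward(_theta(xi)))

        def jac(xi):
            # forward differences on the internal (log) scale; cheaper than
            # generic numerical differentiation for this small dense problem
            r0 = resid(xi)
            out = np.empty((r0.size, xi.size))
            for i in range(xi.size):
                h = 1e-7 * max(abs(xi[i]), 1.0)
                xp = xi.copy()
                xp[i] += h
                out[:, i] = (resid(xp) - r0) / h
            return out

        sol = least_squares(resid, x, jac=jac, method="lm", xtol=1e-9,
                            ftol=1e-9, gtol=1e-9, max_nfev=200)
        if not sol.success and sol.status != 0:
            return sol.x, float("inf"), w, "optimizer_failure"
        dx = np.max(np.abs(sol.x - x) / np.maximum(np.abs(x), 1e-12))
        x = sol.x
        pred = forward(_theta(x))
        w = _weights(spec, pred)
        wss = float(np.sum(w * (concs - pred) ** 2))
        if spec.weighting == "unit":
            status = "ok" if sol.success else "max_iterations"
            break
        if not sol.success:
            status = "max_iterations"
            break
        if wss_prev is not None and (
            dx < PARAM_RTOL
            and abs(wss - wss_prev) <= WSS_RTOL * max(wss_prev, 1e-300)
        ):
            status = "ok"
            break
        wss_prev = wss
    x = np.clip(x, clip_lo, clip_hi)
    wss = float(np.sum(w * (concs - pred) ** 2))
    return x, wss, w, status


def _numeric_jacobian(spec: ModelSpec, theta: np.ndarray, times: np.ndarray,
                      dose: float) -> np.ndarray:
    """Central-difference Jacobian of predictions w.r.t. natural parameters."""
    base = _predict(spec, theta, times, dose)
    jac = np.empty((times.size, theta.size))
    for i in range(theta.size):
        h = 1e-6 * max(abs(theta[i]), 1e-8)
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h
        tm[i] = max(tm[i] - h, 0.0 if spec.param_names[i] == "tlag" else 1e-12)
        fp = _predict(spec, tp, times, dose)
        fm = _predict(spec, tm, times, dose)
        jac[:, i] = (fp - fm) / (tp[i] - tm[i])
    return jac


def fit_model(times, concs, dose: float, spec: ModelSpec,
              init: dict[str, float] | str = "auto",
              max_starts: int = 9) -> FitResult:
    """Fit one candidate model to a concentration profile.

    Minimizes the weighted residual sum of squares with weights refreshed
    from the current predictions each outer iteration; multi-start from the
    curve-stripping estimate and its one-at-a-time perturbations, best
    converged WSS wins.  Numerical failure never raises: the result carries
    ``converged = False`` with a reason.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concs, dtype=float)
    if t.size <= spec.n_params:
        raise ValueError(
            f"need more than {spec.n_params} observations for {spec.label}"
        )
    if spec.weighting != "unit" and np.all(c <= 0):
        raise ValueError("weighted schemes need positive concentrations")
    base_init = _strip_init(t, c, dose) if init == "auto" else dict(init)
    theta0 = _initial_theta(spec, base_init, t[t > 0].min() if np.any(t > 0) else 1.0)
    lo, hi = _bounds(spec, tmax_lag=float(t[t > 0].min()) if np.any(t > 0) else 1.0)
    lb_int = _to_internal(np.maximum(lo, 1e-300), spec)
    ub_int = _to_internal(hi, spec)
    for i, name in enumerate(spec.param_names):
        if name == "tlag":
            lb_int[i], ub_int[i] = lo[i], hi[i]

    best = None  # (wss, x, w, status)
    for x0 in _start_set(spec, theta0, max_starts):
        x, wss, w, status = _run_irls(spec, _to_internal(x0, spec), t, c, dose,
                                      lb_int, ub_int)
        key = (status != "ok", wss)
        if best is None or key < best[0]:
            best = (key, x, wss, w, status)
    _, x, wss, w, status = best
    theta = _from_internal(x, spec)
    # the first-order absorption curve is invariant under the flip-flop
    # exchange (ka, ke, v) -> (ke, ka, v*ke/ka); report the conventional
    # branch with ka >= ke
    if spec.structure == "one_compartment" and theta[1] > theta[0]:
        ka_old, ke_old = theta[0], theta[1]
        theta[0], theta[1] = ke_old, ka_old
        theta[2] *= ke_old / ka_old
        x = _to_internal(theta, spec)
    estimates = dict(zip(spec.param_names, theta))
    pred = _predict(spec, theta, t, dose)
    resid_w = np.sqrt(w) * (c - pred)

    # identifiability diagnostics at the optimum
    jac = _numeric_jacobian(spec, theta, t, dose)
    cn = condition_number(jac, w)
    n, p = t.size, spec.n_params
    se = {name: float("nan") for name in spec.param_names}
    cv = dict(se)
    finite_se = False
    jtj = (jac * w[:, None]).T @ jac
    try:
        cov = np.linalg.inv(jtj) * (wss / (n - p))
        diag = np.diag(cov)
        if np.all(np.isfinite(diag)) and np.all(diag >= 0):
            finite_se = True
            for i, name in enumerate(spec.param_names):
                se[name] = float(math.sqrt(diag[i]))
                denom = abs(estimates[name])
                cv[name] = 100.0 * se[name] / denom if denom > 0 else float("inf")
    except np.linalg.LinAlgError:
        status = "singular_normal_equations" if status == "ok" else status

    # strict-interior check on the internal (bounded) scale
    margin = 1e-6 * (ub_int - lb_int)
    at_bound = bool(np.any(x <= lb_int + margin) or np.any(x >= ub_int - margin))

    converged = status == "ok" and finite_se and not at_bound
    if converged:
        reason = "ok"
    elif status != "ok":
        reason = status
    elif at_bound:
        reason = "parameter_at_bound"
    else:
        reason = "nonfinite_se"

    aic, sbc = information_criteria(max(wss, 0.0), n, p) if wss > 0 else (
        float("-inf"), float("-inf"))

    # predicted exposure summaries of the fitted curve
    if spec.structure == "one_compartment":
        p1 = OneCmtParams(ka=estimates["ka"], ke=estimates["ke"], v=estimates["v"],
                          dose=dose, tlag=estimates.get("tlag", 0.0))
        ptmax, pcmax = tmax_cmax_1cmt(p1)
    else:
        grid = np.linspace(0.0, t[-1], 4097)
        curve = _predict(spec, theta, grid, dose)
        i = int(np.argmax(curve))
        ptmax, pcmax = float(grid[i]), float(curve[i])
    grid = np.linspace(0.0, t[-1], 4097)
    pauc = float(np.trapezoid(_predict(spec, theta, grid, dose), grid))

    return FitResult(
        spec=spec, estimates=estimates, se=se, cv_percent=cv, wss=wss,
        n_obs=n, n_params=p, aic=aic, sbc=sbc, condition_number=cn,
        converged=converged, reason=reason, residuals=resid_w,
        predictions=pred, predicted_cmax=pcmax, predicted_tmax=ptmax,
        predicted_auc=pauc,
    )


def candidate_ledger(times, concs, dose: float, **fit_kwargs) -> list[FitResult]:
    """All 12 candidate fits in deterministic order; per-row failures are
    recorded in the row, never abort the ledger."""
    results = []
    for spec in all_model_specs():
        try:
            results.append(fit_model(times, concs, dose, spec, **fit_kwargs))
        except ValueError as exc:
            results.append(FitResult(
                spec=spec, estimates={}, se={}, cv_percent={},
                wss=float("nan"), n_obs=len(np.asarray(times)),
                n_params=spec.n_params, aic=float("nan"), sbc=float("nan"),
                condition_number=float("nan"), converged=False,
                reason=f"input_error: {exc}", residuals=np.array([]),
                predictions=np.array([]), predicted_cmax=float("nan"),
                predicted_tmax=float("nan"), predicted_auc=float("nan"),
            ))
    return results


def ledger_frame(ledger: list[FitResult]) -> pd.DataFrame:
    """Tabular view of a candidate ledger.

    ``aic_comparable_group`` flags that AIC/SBC may only be ranked within
    one weighting scheme (weighted criteria use different residual scales).
    """
    rows = []
    for r in ledger:
        rows.append({
            "structure": r.spec.structure,
            "lag": r.spec.lag,
            "weighting": r.spec.weighting,
            "aic_comparable_group": r.spec.weighting,
            "n_params": r.n_params,
            "converged": r.converged,
            "reason": r.reason,
            "wss": r.wss,
            "aic": r.aic,
            "sbc": r.sbc,
            "condition_number": r.condition_number,
            "max_cv_percent": r.max_cv_percent,
            "predicted_cmax": r.predicted_cmax,
            "predicted_tmax": r.predicted_tmax,
            "predicted_auc": r.predicted_auc,
            **{f"est_{k}": v for k, v in r.estimates.items()},
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SelectionPolicy:
    cv_max: float = 50.0  # percent
    cn_max: float = 1e4
    delta_aic: float = 2.0
    weighting_order: tuple[str, ...] = WEIGHTINGS


@dataclass
class SelectionResult:
    chosen: FitResult | None
    audit: list[dict] = field(default_factory=list)


def select_model(ledger: list[FitResult],
                 policy: SelectionPolicy | None = None) -> SelectionResult:
    """Selection balancing fit, parameter stability and parsimony.

    Discard non-converged rows and rows failing the CV% / condition-number
    thresholds; within each weighting scheme keep the lowest-AIC row,
    preferring fewer parameters when AIC is within ``delta_aic``; across
    schemes (where AIC is not comparable) prefer the simplest weighting
    that has a survivor.  The audit trail records every discard.
    """
    policy = policy or SelectionPolicy()
    audit = []
    survivors = []
    for r in ledger:
        if not r.converged:
            audit.append({"model": r.spec.label, "action": "discard",
                          "why": f"not converged ({r.reason})"})
        elif not np.isfinite(r.condition_number) or r.condition_number > policy.cn_max:
            audit.append({"model": r.spec.label, "action": "discard",
                          "why": f"condition number {r.condition_number:.3g} "
                                 f"> {policy.cn_max:g}"})
        elif r.max_cv_percent > policy.cv_max:
            audit.append({"model": r.spec.label, "action": "discard",
                          "why": f"max CV% {r.max_cv_percent:.3g} "
                                 f"> {policy.cv_max:g}"})
        else:
            survivors.append(r)
    if not survivors:
        return SelectionResult(None, audit)
    by_weighting: dict[str, list[FitResult]] = {}
    for r in survivors:
        by_weighting.setdefault(r.spec.weighting, []).append(r)
    scheme_winners: dict[str, FitResult] = {}
    for w, rows in by_weighting.items():
        best_aic = min(r.aic for r in rows)
        near = [r for r in rows if r.aic - best_aic < policy.delta_aic]
        near.sort(key=lambda r: (r.n_params, r.aic))
        scheme_winners[w] = near[0]
        for r in rows:
            if r is not near[0]:
                audit.append({"model": r.spec.label, "action": "discard",
                              "why": "higher AIC or more parameters within scheme"})
    for w in policy.weighting_order:
        if w in scheme_winners:
            chosen = scheme_winners[w]
            audit.append({"model": chosen.spec.label, "action": "select",
                          "why": f"survivor in simplest weighting scheme '{w}'"})
            for other_w, r in scheme_winners.items():
                if other_w != w:
                    audit.append({"model": r.spec.label, "action": "discard",
                                  "why": "simpler weighting scheme preferred"})
            return SelectionResult(chosen, audit)
    return SelectionResult(None, audit)  # pragma: no cover


@dataclass
class LoroReport:
    full_fit: FitResult
    folds: pd.DataFrame  # left_out_subject, converged, cn, cmax, tmax, auc
    ranges: dict[str, tuple[float, float]]
    n_nonconverged: int


def mean_profile(table: pd.DataFrame, exclude_subject: str | None = None):
    """Group mean concentration at each post-dose sampling time."""
    df = table[table.time_min > 0]
    if exclude_subject is not None:
        df = df[df.subject_id != exclude_subject]
    prof = df.groupby("time_min", as_index=False)["conc_mg_per_L"].mean()
    return prof.time_min.to_numpy(), prof.conc_mg_per_L.to_numpy()


def loro(table: pd.DataFrame, spec: ModelSpec, **fit_kwargs) -> LoroReport:
    """Leave-one-rat-out robustness refitting on one group's table.

    Fits the mean profile of all subjects, then refits once per excluded
    subject on the mean profile of the remainder; reports per-fold
    diagnostics and min-max ranges of the predicted exposure summaries over
    converged folds.
    """
    subjects = sorted(table.subject_id.unique())
    if len(subjects) < 3:
        raise ValueError("leave-one-out needs at least 3 subjects")
    doses = table.dose_mg_per_kg.unique()
    if doses.size != 1:
        raise ValueError("leave-one-out expects a single-dose group")
    dose = float(doses[0])
    t, c = mean_profile(table)
    full = fit_model(t, c, dose, spec, **fit_kwargs)
    rows = []
    for s in subjects:
        tf, cf = mean_profile(table, exclude_subject=s)
        r = fit_model(tf, cf, dose, spec, **fit_kwargs)
        rows.append({
            "left_out_subject": s, "converged": r.converged, "reason": r.reason,
            "condition_number": r.condition_number,
            "predicted_cmax": r.predicted_cmax,
            "predicted_tmax": r.predicted_tmax,
            "predicted_auc": r.predicted_auc,
        })
    folds = pd.DataFrame(rows)
    ok = folds[folds.converged]
    ranges = {}
    for col in ("condition_number", "predicted_cmax", "predicted_tmax",
                "predicted_auc"):
        if len(ok):
            ranges[col] = (float(ok[col].min()), float(ok[col].max()))
        else:
            ranges[col] = (float("nan"), float("nan"))
    return LoroReport(full_fit=full, folds=folds, ranges=ranges,
                      n_nonconverged=int((~folds.converged).sum()))
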