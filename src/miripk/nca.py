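"""Non-compartmental analysis, group summaries and Welch comparisons.

Per-profile NCA (Cmax, Tmax, AUC, lambda_z, half-life, MRT, Vz, CL), the
dose-proportionality regression over group means, and Welch's
independent-samples t-test computed from summary statistics, mirroring the
summary-level comparison the study reports for the Nor-15 vs MI/RI-15
arms.

Terminal-slope selection emulates the usual automatic best-fit rule: among
all windows of at least three positive concentrations that end at the last
positive observation and exclude Tmax, choose the one maximizing the
adjusted R^2 of the log-linear regression, breaking ties toward more
points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NCAError",
    "LambdaZResult",
    "NCAResult",
    "WelchResult",
    "auc_aumc",
    "terminal_slope",
    "nca_profile",
    "welch_test",
    "dose_proportionality",
    "summarize_groups",
]


class NCAError(ValueError):
    """Invalid input for a non-compartmental computation."""


#: parameters summarized per group, in report order
NCA_PARAMETERS = (
    "cmax", "tmax", "auc_0_t", "auc_0_inf", "t_half",
    "mrt_0_t", "mrt_0_inf", "vz", "cl",
)

#: report rounding (decimal places) used when deciding whether a pairwise
#: test is meaningful at printed precision (the "N.C." convention)
REPORT_DECIMALS = {"vz": 2, "cl": 2}


@dataclass(frozen=True)
class LambdaZResult:
    lambda_z: float
    n_points: int
    adj_r2: float
    intercept: float  # log-scale intercept of the terminal regression


@dataclass(frozen=True)
class NCAResult:
    cmax: float
    tmax: float
    auc_0_t: float
    auc_0_inf: float
    lambda_z: float
    t_half: float
    aumc_0_t: float
    aumc_0_inf: float
    mrt_0_t: float
    mrt_0_inf: float
    vz: float
    cl: float
    lambda_z_npoints: int
    lambda_z_adj_r2: float
    auc_extrap_fraction: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float


def _check_profile(times, concs):
    t = np.asarray(times, dtype=float)
    c = np.asarray(concs, dtype=float)
    if t.size != c.size:
        raise NCAError("times and concentrations differ in length")
    if t.size < 2:
        raise NCAError("at least 2 points are required")
    if np.any(np.diff(t) <= 0):
        raise NCAError("times must be strictly ascending")
    if np.any(c < 0):
        raise NCAError("concentrations must be >= 0")
    return t, c


def auc_aumc(times, concs, method: str = "linear") -> tuple[float, float]:
    """AUC(0-t) and AUMC(0-t) by trapezoid accumulation.

    ``linear`` uses the linear trapezoid everywhere; ``lin_up_log_down``
    uses the log-trapezoid on strictly decreasing, strictly positive
    segments.
    """
    t, c = _check_profile(times, concs)
    if method not in ("linear", "lin_up_log_down"):
        raise NCAError(f"unknown AUC method {method!r}")
    auc = 0.0
    aumc = 0.0
    for i in range(1, t.size):
        dt = t[i] - t[i - 1]
        c1, c2 = c[i - 1], c[i]
        t1, t2 = t[i - 1], t[i]
        if method == "lin_up_log_down" and c2 < c1 and c2 > 0:
            k = math.log(c1 / c2) / dt
            auc += (c1 - c2) / k
            aumc += (t1 * c1 - t2 * c2) / k + (c1 - c2) / (k * k)
        else:
            auc += 0.5 * (c1 + c2) * dt
            aumc += 0.5 * (t1 * c1 + t2 * c2) * dt
    return float(auc), float(aumc)


def terminal_slope(
    times, concs, selection: str = "best_fit", window: tuple[int, int] | None = None
) -> LambdaZResult | None:
    """Terminal log-linear elimination rate lambda_z.

    Returns ``None`` (the lambda_z-failure marker) when no window with at
    least three positive post-Tmax concentrations yields a negative slope.
    ``selection='manual'`` regresses over ``window`` (inclusive index pair
    into the profile).
    """
    t, c = _check_profile(times, concs)

    def _fit(idx: np.ndarray) -> LambdaZResult | None:
        y = np.log(c[idx])
        res = stats.linregress(t[idx], y)
        if res.slope >= 0:
            return None
        n = idx.size
        r2 = res.rvalue ** 2
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2) if n > 2 else r2
        return LambdaZResult(float(-res.slope), int(n), float(adj),
                             float(res.intercept))

    if selection == "manual":
        if window is None:
            raise NCAError("manual selection requires a window")
        lo, hi = window
        idx = np.arange(lo, hi + 1)
        idx = idx[c[idx] > 0]
        if idx.size < 3:
            return None
        return _fit(idx)
    if selection != "best_fit":
        raise NCAError(f"unknown selection rule {selection!r}")

    imax = int(np.argmax(c))
    candidates = np.flatnonzero(c > 0)
    candidates = candidates[candidates > imax]
    if candidates.size < 3:
        return None
    best: LambdaZResult | None = None
    for start in range(candidates.size - 2):
        fit = _fit(candidates[start:])
        if fit is None:
            continue
        if best is None or fit.adj_r2 > best.adj_r2 + 1e-10 or (
            abs(fit.adj_r2 - best.adj_r2) <= 1e-10 and fit.n_points > best.n_points
        ):
            best = fit
    return best


def nca_profile(times, concs, dose: float, auc_method: str = "linear") -> NCAResult:
    """Full non-compartmental parameter vector for one profile.

    Extrapolation to infinity uses Clast/lambda_z for AUC and
    Clast*tlast/lambda_z + Clast/lambda_z^2 for AUMC; Vz and CL are
    apparent (per bioavailability).  When the terminal slope cannot be
    identified the infinity-dependent parameters are NaN.
    """
    t, c = _check_profile(times, concs)
    if dose < 0:
        raise NCAError("dose must be >= 0")
    imax = int(np.argmax(c))
    cmax = float(c[imax])
    tmax = float(t[imax])
    auc_t, aumc_t = auc_aumc(t, c, auc_method)
    if auc_t <= 0:
        raise NCAError("AUC(0-t) must be positive")
    lz = terminal_slope(t, c)
    pos = np.flatnonzero(c > 0)
    nan = float("nan")
    if lz is None:
        return NCAResult(cmax, tmax, auc_t, nan, nan, nan, aumc_t, nan,
                         aumc_t / auc_t, nan, nan, nan, 0, nan, nan)
    clast = float(c[pos[-1]])
    tlast = float(t[pos[-1]])
    k = lz.lambda_z
    auc_inf = auc_t + clast / k
    aumc_inf = aumc_t + clast * tlast / k + clast / (k * k)
    t_half = math.log(2) / k
    cl = dose / auc_inf
    vz = cl / k
    return NCAResult(
        cmax=cmax, tmax=tmax, auc_0_t=auc_t, auc_0_inf=auc_inf,
        lambda_z=k, t_half=t_half, aumc_0_t=aumc_t, aumc_0_inf=aumc_inf,
        mrt_0_t=aumc_t / auc_t, mrt_0_inf=aumc_inf / auc_inf,
        vz=vz, cl=cl, lambda_z_npoints=lz.n_points, lambda_z_adj_r2=lz.adj_r2,
        auc_extrap_fraction=(auc_inf - auc_t) / auc_inf,
    )


def welch_test(mean1, sd1, n1, mean2, sd2, n2) -> WelchResult:
    """Welch's independent-samples t-test from summary statistics.

    t = (m1 - m2)/sqrt(s1^2/n1 + s2^2/n2) with Welch-Satterthwaite degrees
    of freedom; two-sided p from Student's t.
    """
    if n1 < 2 or n2 < 2:
        raise NCAError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise NCAError("standard deviations must be >= 0")
    v1 = sd1 * sd1 / n1
    v2 = sd2 * sd2 / n2
    if v1 + v2 == 0:
        if mean1 == mean2:
            raise NCAError("degenerate input: both variances zero, equal means")
        return WelchResult(math.copysign(math.inf, mean1 - mean2),
                           float(min(n1, n2) - 1), 0.0)
    t = (mean1 - mean2) / math.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1 * v1 / (n1 - 1) + v2 * v2 / (n2 - 1))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return WelchResult(float(t), float(df), min(p, 1.0))


def dose_proportionality(doses, values) -> tuple[float, float, float]:
    """OLS of exposure against dose; returns (slope, intercept, r2)."""
    d = np.asarray(doses, dtype=float)
    y = np.asarray(values, dtype=float)
    if d.size < 3:
        raise NCAError("at least 3 (dose, value) pairs are required")
    if np.ptp(d) == 0:
        raise NCAError("degenerate design: all doses equal")
    res = stats.linregress(d, y)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)


def summarize_groups(
    results: dict[str, list[NCAResult]],
    doses: dict[str, float],
    compare: tuple[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Mean +/- SD per NCA parameter per group, plus Welch tests for one pair.

    A pairwise test is suppressed (recorded as ``N.C.`` with ``p`` NaN) when
    the two groups are indistinguishable at report rounding precision for
    that parameter, mirroring how apparent clearance is reported.
    """
    rows = []
    for group, res_list in results.items():
        for param in NCA_PARAMETERS:
            vals = np.array([getattr(r, param) for r in res_list], dtype=float)
            vals = vals[np.isfinite(vals)]
            n = vals.size
            mean = float(vals.mean()) if n else float("nan")
            sd = float(vals.std(ddof=1)) if n >= 2 else float("nan")
            rows.append((group, doses.get(group, float("nan")), param, mean, sd, n))
    summary = pd.DataFrame(
        rows, columns=["group", "dose_mg_per_kg", "parameter", "mean", "sd", "n"]
    )
    if compare is None:
        return summary, None
    g1, g2 = compare
    tests = []
    for param in NCA_PARAMETERS:
        s1 = summary[(summary.group == g1) & (summary.parameter == param)].iloc[0]
        s2 = summary[(summary.group == g2) & (summary.parameter == param)].iloc[0]
        if s1.n < 2 or s2.n < 2:
            tests.append((param, float("nan"), float("nan"), float("nan"),
                          "insufficient n"))
            continue
        dec = REPORT_DECIMALS.get(param)
        if dec is not None and (
            round(s1["mean"], dec) == round(s2["mean"], dec)
            and round(s1["sd"], dec) == round(s2["sd"], dec)
        ):
            tests.append((param, float("nan"), float("nan"), float("nan"), "N.C."))
            continue
        try:
            w = welch_test(s1["mean"], s1["sd"], int(s1["n"]),
                           s2["mean"], s2["sd"], int(s2["n"]))
        except NCAError:
            tests.append((param, float("nan"), float("nan"), float("nan"),
                          "degenerate: identical groups"))
            continue
        tests.append((param, w.t, w.df, w.p, ""))
    welch = pd.DataFrame(tests, columns=["parameter", "t", "df", "p", "note"])
    return summary, welch
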