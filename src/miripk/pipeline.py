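"""End-to-end pipeline orchestration.

One configuration object drives the whole analysis: obtain data (simulate
a study or read CSV tables), run per-rat NCA with group summaries, the
dose-exposure regression and the Nor-15 vs MIRI-15 Welch comparison, fit
the 12-candidate compartmental ledger on the MIRI mean profile and apply
the selection policy, run leave-one-rat-out robustness, and finish with
the delta-CK-MB hysteresis loop and ke0 sensitivity scan.  Every stage
writes a CSV table; a plain-text run log records the seed, library
versions and every numeric convention with a known alternative; a JSON
summary carries the headline numbers.

Stage failures are recorded and dependent stages are skipped with a
reason; the report never raises for a downstream numerical failure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io, nca
from .exposure_response import DEFAULT_KE0_GRID, EffectCourse, delta_ckmb, \
    hysteresis_loop, ke0_scan
from .fitting import ModelSpec, SelectionPolicy, candidate_ledger, ledger_frame, \
    loro, mean_profile, select_model
from .pk_models import OneCmtParams, conc_1cmt
from .synthetic_data import PDScenario, StudyDesign, default_design, \
    default_scenario, simulate_ckmb_course, simulate_pk_study

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline", "blq_to_zero"]

CONVENTIONS = {
    "aic_form": "n*ln(WSS) + 2p (SBC: n*ln(WSS) + p*ln(n))",
    "condition_number_form": "ratio of extreme singular values of sqrt(W)*J",
    "auc_method": "linear trapezoid (lin-up/log-down available by flag)",
    "lambda_z_rule": "best adjusted R^2, >= 3 post-Tmax positive points, "
                     "Tmax excluded, ties to more points",
    "loop_normalization": "shoelace signed area / bounding-rectangle area",
    "blq_rule": "BLQ observations set to 0 for AUC; zeros are never used "
                "in the terminal log-linear regression",
    "pd_corr": "Pearson correlation of observed vs fitted effect",
    "fit_target": "group mean concentration profile (naive-mean fit)",
}


@dataclass
class PipelineConfig:
    # either a design to simulate, or paths to read
    design: StudyDesign | None = None
    scenario: PDScenario | None = None
    conc_path: str | None = None
    effect_path: str | None = None
    untreated_group: str = "MIRI-model"
    treated_group: str = "MIRI-15"
    fit_group: str = "MIRI-15"
    compare_pair: tuple[str, str] = ("Nor-15", "MIRI-15")
    run_nca: bool = True
    run_ledger: bool = True
    run_loro: bool = True
    run_er: bool = True
    auc_method: str = "linear"
    selection_policy: SelectionPolicy = field(default_factory=SelectionPolicy)
    ke0_grid: tuple[float, ...] = DEFAULT_KE0_GRID
    pd_model: str = "linear"
    seed: int = 20260
    outdir: str = "results/pipeline"

    def __post_init__(self) -> None:
        if self.design is None and self.conc_path is None:
            raise ValueError("config needs either a design or an input path")


@dataclass
class PipelineReport:
    tables: dict[str, pd.DataFrame]
    summary: dict
    failures: dict[str, str]
    outdir: Path


def blq_to_zero(sub: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """One subject's (times, concs) with BLQ observations set to 0."""
    sub = sub.sort_values("time_min")
    t = sub.time_min.to_numpy(dtype=float)
    c = sub.conc_mg_per_L.to_numpy(dtype=float).copy()
    c[sub.blq.to_numpy(dtype=bool)] = 0.0
    return t, c


def _stage_nca(conc: pd.DataFrame, cfg: PipelineConfig, tables, summary):
    results: dict[str, list[nca.NCAResult]] = {}
    doses: dict[str, float] = {}
    rows = []
    for (group, subject), sub in conc.groupby(["group", "subject_id"]):
        dose = float(sub.dose_mg_per_kg.iloc[0])
        doses[group] = dose
        t, c = blq_to_zero(sub)
        res = nca.nca_profile(t, c, dose, cfg.auc_method)
        results.setdefault(group, []).append(res)
        rows.append({"group": group, "subject_id": subject,
                     "dose_mg_per_kg": dose, **res.as_dict()})
    tables["nca_results"] = pd.DataFrame(rows)
    pair = cfg.compare_pair if all(g in results for g in cfg.compare_pair) else None
    summ, welch = nca.summarize_groups(results, doses, pair)
    tables["group_summary"] = summ
    if welch is not None:
        tables["welch_tests"] = welch
    # dose-exposure regression over the normal arms' mean AUC0-t
    normal_groups = sorted(
        {g for g in results if conc[conc.group == g].state.iloc[0] == "normal"},
        key=lambda g: doses[g],
    )
    if len(normal_groups) >= 3:
        regs = []
        for param in ("auc_0_t", "cmax"):
            means = [
                float(summ[(summ.group == g) & (summ.parameter == param)]["mean"].iloc[0])
                for g in normal_groups
            ]
            slope, intercept, r2 = nca.dose_proportionality(
                [doses[g] for g in normal_groups], means)
            regs.append({"parameter": param, "slope": slope,
                         "intercept": intercept, "r2": r2})
        tables["dose_regression"] = pd.DataFrame(regs)
        summary["dose_auc_r2"] = regs[0]["r2"]
    return results


def _stage_ledger(conc: pd.DataFrame, cfg: PipelineConfig, tables, summary):
    sub = conc[conc.group == cfg.fit_group]
    if sub.empty:
        raise ValueError(f"fit group {cfg.fit_group!r} not in the data")
    dose = float(sub.dose_mg_per_kg.iloc[0])
    t, c = mean_profile(sub)
    ledger = candidate_ledger(t, c, dose)
    tables["ledger"] = ledger_frame(ledger)
    sel = select_model(ledger, cfg.selection_policy)
    tables["selection_audit"] = pd.DataFrame(sel.audit)
    if sel.chosen is not None:
        summary["selected_model"] = sel.chosen.spec.label
        summary["selected_estimates"] = sel.chosen.estimates
        summary["selected_aic"] = sel.chosen.aic
        summary["selected_sbc"] = sel.chosen.sbc
        summary["selected_condition_number"] = sel.chosen.condition_number
        # figure-ready observed vs predicted table
        tables["goodness_of_fit"] = pd.DataFrame({
            "time_min": t, "observed_mg_per_L": c,
            "predicted_mg_per_L": sel.chosen.predictions,
            "weighted_residual": sel.chosen.residuals,
        })
    else:
        summary["selected_model"] = None
    return sel


def _stage_loro(conc: pd.DataFrame, cfg: PipelineConfig, sel, tables, summary):
    sub = conc[conc.group == cfg.fit_group]
    spec = sel.chosen.spec if sel and sel.chosen else ModelSpec(
        "one_compartment", False, "unit")
    report = loro(sub, spec)
    tables["loro"] = report.folds
    summary["loro_all_converged"] = bool(report.folds.converged.all())
    summary["loro_ranges"] = {k: list(v) for k, v in report.ranges.items()}
    summary["loro_full_predicted_cmax"] = report.full_fit.predicted_cmax
    return report


def _stage_er(conc, untreated, treated, cfg: PipelineConfig, sel, tables, summary):
    d = delta_ckmb(untreated, treated)
    t = np.asarray(d.times)
    # plasma curve at matched times: the selected 1-cmt fit when available,
    # otherwise the tabulated mean profile of the treated group
    if sel and sel.chosen and sel.chosen.spec.structure == "one_compartment":
        est = sel.chosen.estimates
        dose = float(conc[conc.group == cfg.fit_group].dose_mg_per_kg.iloc[0])
        plasma = OneCmtParams(ka=est["ka"], ke=est["ke"], v=est["v"],
                              dose=dose, tlag=est.get("tlag", 0.0))
        cp = conc_1cmt(plasma, t)
    else:
        tp, cprof = mean_profile(conc[conc.group == cfg.fit_group])
        plasma = (np.concatenate(([0.0], tp)), np.concatenate(([0.0], cprof)))
        cp = np.interp(t, plasma[0], plasma[1])
    loop = hysteresis_loop(cp, d)
    summary["hysteresis_area_cp_plane"] = loop.signed_area_normalized
    summary["hysteresis_direction"] = loop.direction
    tables["hysteresis_path"] = pd.DataFrame({
        "time_min": t, "conc_mg_per_L": cp, "delta_ckmb_ng_per_mL": d.delta})
    scan, best = ke0_scan(plasma, untreated, treated, cfg.ke0_grid, cfg.pd_model)
    tables["ke0_scan"] = scan
    if best is not None:
        summary["best_ke0"] = best.ke0
        summary["best_ke0_ssr"] = best.ssr
        summary["best_ke0_aic"] = best.aic
        summary["best_ke0_corr"] = best.corr
        summary["best_ke0_loop_area"] = best.loop_area_normalized
    else:
        summary["best_ke0"] = None


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute all requested stages; see the module docstring."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables: dict[str, pd.DataFrame] = {}
    summary: dict = {"seed": config.seed}
    failures: dict[str, str] = {}

    # --- data stage
    untreated = treated = None
    try:
        if config.design is not None:
            design = config.design
            conc = simulate_pk_study(design)
            scenario = config.scenario or default_scenario(config.seed + 1)
            unt_df, trt_df = simulate_ckmb_course(design, scenario)
            untreated = EffectCourse.from_frame(unt_df)
            treated = EffectCourse.from_frame(trt_df)
            tables["effect_courses"] = pd.concat([unt_df, trt_df],
                                                 ignore_index=True)
        else:
            conc = io.read_concentration_table(config.conc_path)
            if config.effect_path is not None:
                eff = io.read_effect_table(config.effect_path)
                untreated = EffectCourse.from_frame(
                    eff[eff.group == config.untreated_group])
                treated = EffectCourse.from_frame(
                    eff[eff.group == config.treated_group])
                tables["effect_courses"] = eff
        tables["concentrations"] = conc
        # figure-ready mean profiles per group
        prof = (conc[conc.time_min > 0]
                .groupby(["group", "time_min"], as_index=False)
                .conc_mg_per_L.agg(["mean", "std"]))
        tables["mean_profiles"] = prof
    except Exception as exc:  # noqa: BLE001 - reported, not raised
        failures["data"] = str(exc)
        return _finalize(tables, summary, failures, outdir)

    if config.run_nca:
        try:
            _stage_nca(conc, config, tables, summary)
        except Exception as exc:  # noqa: BLE001
            failures["nca"] = str(exc)

    sel = None
    if config.run_ledger:
        try:
            sel = _stage_ledger(conc, config, tables, summary)
        except Exception as exc:  # noqa: BLE001
            failures["ledger"] = str(exc)

    if config.run_loro:
        if "ledger" in failures:
            failures["loro"] = "skipped: ledger stage failed"
        else:
            try:
                _stage_loro(conc, config, sel, tables, summary)
            except Exception as exc:  # noqa: BLE001
                failures["loro"] = str(exc)

    if config.run_er:
        if untreated is None or treated is None:
            failures["er"] = "skipped: no effect-course data"
        else:
            try:
                _stage_er(conc, untreated, treated, config, sel, tables, summary)
            except Exception as exc:  # noqa: BLE001
                failures["er"] = str(exc)

    return _finalize(tables, summary, failures, outdir)


def _finalize(tables, summary, failures, outdir: Path) -> PipelineReport:
    for name, df in tables.items():
        df.to_csv(outdir / f"{name}.csv", index=False)
    summary["failures"] = failures
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=_json_default)
    with open(outdir / "run_log.txt", "w") as fh:
        fh.write(f"miripk {__version__}\n")
        fh.write(f"numpy {np.__version__}, pandas {pd.__version__}\n")
        fh.write(f"seed: {summary.get('seed')}\n")
        fh.write("conventions:\n")
        for key, val in CONVENTIONS.items():
            fh.write(f"  {key}: {val}\n")
        if failures:
            fh.write("stage failures:\n")
            for stage, why in failures.items():
                fh.write(f"  {stage}: {why}\n")
    return PipelineReport(tables=tables, summary=summary, failures=failures,
                          outdir=outdir)


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)
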