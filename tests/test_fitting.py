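"""The weighted-fitting engine: recovery at truth, diagnostics identities,
ledger bookkeeping, selection policy and leave-one-rat-out."""

import math

import numpy as np
import pandas as pd
import pytest

from miripk.fitting import (
    FitResult,
    ModelSpec,
    SelectionPolicy,
    all_model_specs,
    candidate_ledger,
    condition_number,
    fit_model,
    information_criteria,
    ledger_frame,
    loro,
    mean_profile,
    select_model,
)
from miripk.pk_models import OneCmtParams, conc_1cmt
from miripk.synthetic_data import DEFAULT_SCHEDULE

SCHED = np.asarray(DEFAULT_SCHEDULE)
TRUTH = OneCmtParams(ka=0.025, ke=0.0029, v=7.21, dose=15.0)
CLEAN = conc_1cmt(TRUTH, SCHED)


class TestFitModel:
    def test_zero_noise_recovery_at_truth(self):
        r = fit_model(SCHED, CLEAN, 15.0, ModelSpec("one_compartment", False,
                                                    "unit"))
        assert r.converged
        assert r.wss < 1e-12
        for name, true in (("ka", TRUTH.ka), ("ke", TRUTH.ke), ("v", TRUTH.v)):
            assert abs(r.estimates[name] - true) / true < 1e-4
        assert np.all(np.abs(r.residuals) < 1e-6)

    def test_lag_spec_on_lag_free_data_is_nested_dominant(self):
        base = fit_model(SCHED, CLEAN, 15.0,
                         ModelSpec("one_compartment", False, "unit"))
        lagged = fit_model(SCHED, CLEAN, 15.0,
                           ModelSpec("one_compartment", True, "unit"))
        assert lagged.estimates["tlag"] == pytest.approx(0.0, abs=0.5)
        assert lagged.wss <= base.wss + 1e-12

    def test_weighted_schemes_also_recover_truth(self):
        for w in ("inv_pred", "inv_pred_sq"):
            r = fit_model(SCHED, CLEAN, 15.0,
                          ModelSpec("one_compartment", False, w))
            assert r.converged, r.reason
            assert abs(r.estimates["ke"] - TRUTH.ke) / TRUTH.ke < 1e-4

    def test_multistart_basin_stability(self):
        """Perturbed explicit initials land on the same optimum."""
        ref = None
        for f in (0.3, 1.0, 3.0):
            init = {"ka": TRUTH.ka * f, "ke": TRUTH.ke / f, "v": TRUTH.v * f}
            r = fit_model(SCHED, CLEAN, 15.0,
                          ModelSpec("one_compartment", False, "unit"),
                          init=init)
            est = np.array([r.estimates[k] for k in ("ka", "ke", "v")])
            if ref is None:
                ref = est
            assert np.allclose(est, ref, rtol=1e-6)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            fit_model(SCHED[:4], CLEAN[:4], 15.0,
                      ModelSpec("two_compartment", True, "unit"))

    def test_predicted_peak_matches_truth_on_clean_fit(self):
        r = fit_model(SCHED, CLEAN, 15.0,
                      ModelSpec("one_compartment", False, "unit"))
        from miripk.pk_models import tmax_cmax_1cmt

        tmax, cmax = tmax_cmax_1cmt(TRUTH)
        assert r.predicted_tmax == pytest.approx(tmax, rel=1e-3)
        assert r.predicted_cmax == pytest.approx(cmax, rel=1e-3)


class TestInformationCriteria:
    def test_unit_wss(self):
        aic, sbc = information_criteria(1.0, 13, 3)
        assert aic == pytest.approx(6.0)
        assert sbc == pytest.approx(3 * math.log(13))

    def test_gap_identity(self):
        for wss in (0.01, 1.0, 37.5):
            for n, p in ((13, 3), (20, 5), (8, 4)):
                aic, sbc = information_criteria(wss, n, p)
                assert sbc - aic == pytest.approx(p * (math.log(n) - 2),
                                                  abs=1e-12)

    def test_monotone_in_wss(self):
        a1, _ = information_criteria(0.5, 13, 3)
        a2, _ = information_criteria(0.6, 13, 3)
        assert a2 > a1

    def test_perfect_fit_sentinel(self):
        assert information_criteria(0.0, 13, 3) == (float("-inf"), float("-inf"))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            information_criteria(-1.0, 13, 3)
        with pytest.raises(ValueError):
            information_criteria(1.0, 3, 3)


class TestConditionNumber:
    def test_orthonormal_columns(self):
        q, _ = np.linalg.qr(np.random.default_rng(0).normal(size=(10, 3)))
        assert condition_number(q) == pytest.approx(1.0)

    def test_diagonal_scaling(self):
        q, _ = np.linalg.qr(np.random.default_rng(1).normal(size=(10, 2)))
        assert condition_number(q @ np.diag([1.0, 10.0])) == pytest.approx(10.0)

    def test_invariant_to_uniform_rescaling(self):
        j = np.random.default_rng(2).normal(size=(12, 4))
        assert condition_number(3.7 * j) == pytest.approx(condition_number(j))

    def test_rank_deficient_is_infinite(self):
        j = np.ones((10, 2))
        assert condition_number(j) == float("inf")


class TestLedger:
    def test_twelve_rows_in_deterministic_order(self):
        specs = all_model_specs()
        assert len(specs) == len(set(specs)) == 12
        ledger = candidate_ledger(SCHED, CLEAN, 15.0)
        assert [r.spec for r in ledger] == specs

    def test_gap_identity_holds_for_every_fit(self):
        ledger = candidate_ledger(SCHED, CLEAN, 15.0)
        for r in ledger:
            if np.isfinite(r.aic):
                assert r.sbc - r.aic == pytest.approx(
                    r.n_params * (math.log(r.n_obs) - 2), abs=1e-10)

    def test_frame_flags_aic_comparability_group(self):
        df = ledger_frame(candidate_ledger(SCHED, CLEAN, 15.0))
        assert (df.aic_comparable_group == df.weighting).all()
        assert len(df) == 12

    def test_input_failures_recorded_per_row(self):
        # 6 points: enough for every 1-compartment model, too few for
        # 6-parameter 2-compartment-with-lag
        t, c = SCHED[:6], CLEAN[:6]
        ledger = candidate_ledger(t, c, 15.0)
        assert len(ledger) == 12
        bad = [r for r in ledger if r.reason.startswith("input_error")]
        assert all(r.spec.n_params >= 6 for r in bad)
        assert len(bad) == 3


def _fake_fit(structure="one_compartment", lag=False, weighting="unit",
              aic=-10.0, cv=5.0, cn=100.0, converged=True):
    spec = ModelSpec(structure, lag, weighting)
    return FitResult(
        spec=spec, estimates={n: 1.0 for n in spec.param_names},
        se={n: 0.01 for n in spec.param_names},
        cv_percent={n: cv for n in spec.param_names},
        wss=1.0, n_obs=13, n_params=spec.n_params, aic=aic,
        sbc=aic + spec.n_params * (math.log(13) - 2), condition_number=cn,
        converged=converged, reason="ok" if converged else "max_iterations",
        residuals=np.zeros(13), predictions=np.zeros(13),
        predicted_cmax=1.0, predicted_tmax=50.0, predicted_auc=500.0)


class TestSelectionPolicy:
    def test_single_converged_row_selected(self):
        rows = [_fake_fit(converged=False), _fake_fit(lag=True, aic=-5.0)]
        sel = select_model(rows)
        assert sel.chosen is rows[1]

    def test_parsimony_tie_break_within_delta_aic(self):
        simple = _fake_fit(aic=-9.0)
        complex_ = _fake_fit(structure="two_compartment", aic=-10.0)
        sel = select_model([simple, complex_])
        assert sel.chosen is simple  # |dAIC| = 1 < 2: fewer parameters win

    def test_clear_aic_gap_beats_parsimony(self):
        simple = _fake_fit(aic=-5.0)
        complex_ = _fake_fit(structure="two_compartment", aic=-10.0)
        sel = select_model([simple, complex_])
        assert sel.chosen is complex_

    def test_simpler_weighting_preferred_across_schemes(self):
        unit = _fake_fit(weighting="unit", aic=-5.0)
        weighted = _fake_fit(weighting="inv_pred_sq", aic=-50.0)
        sel = select_model([unit, weighted])
        assert sel.chosen is unit  # AIC not comparable across schemes

    def test_diagnostic_thresholds_discard(self):
        good = _fake_fit(aic=-5.0)
        shaky_cv = _fake_fit(lag=True, aic=-20.0, cv=80.0)
        shaky_cn = _fake_fit(structure="two_compartment", aic=-20.0, cn=1e6)
        sel = select_model([good, shaky_cv, shaky_cn])
        assert sel.chosen is good
        assert sum(a["action"] == "discard" for a in sel.audit) == 2

    def test_no_survivor_returns_reasons(self):
        sel = select_model([_fake_fit(converged=False)])
        assert sel.chosen is None
        assert sel.audit and "not converged" in sel.audit[0]["why"]

    def test_thresholds_configurable(self):
        shaky = _fake_fit(cv=80.0)
        assert select_model([shaky]).chosen is None
        assert select_model([shaky],
                            SelectionPolicy(cv_max=90.0)).chosen is shaky


class TestLoro:
    @staticmethod
    def _table(n_subjects=4, jitter=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n_subjects):
            c = conc_1cmt(TRUTH, SCHED) * (1 + jitter * rng.normal(size=SCHED.size))
            for t, y in zip(SCHED, np.maximum(c, 0)):
                rows.append((f"r{i}", "MIRI-15", "miri", 15.0, t, y, 0))
        return pd.DataFrame(rows, columns=[
            "subject_id", "group", "state", "dose_mg_per_kg", "time_min",
            "conc_mg_per_L", "blq"])

    def test_identical_subjects_give_zero_width_ranges(self):
        rep = loro(self._table(), ModelSpec("one_compartment", False, "unit"))
        assert len(rep.folds) == 4
        for lo, hi in rep.ranges.values():
            assert hi - lo == pytest.approx(0.0, abs=1e-8)

    def test_fold_count_matches_subjects(self):
        rep = loro(self._table(n_subjects=5, jitter=0.05),
                   ModelSpec("one_compartment", False, "unit"))
        assert len(rep.folds) == 5
        assert set(rep.folds.left_out_subject) == {f"r{i}" for i in range(5)}

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            loro(self._table(n_subjects=2),
                 ModelSpec("one_compartment", False, "unit"))

    def test_mean_profile_excludes_predose_and_subject(self):
        tab = self._table(n_subjects=3)
        t, c = mean_profile(tab, exclude_subject="r0")
        assert t.size == SCHED.size
        assert np.all(t > 0)
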