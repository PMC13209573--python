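"""Non-compartmental analysis against hand-computed oracles, closed forms
and a reference Welch implementation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from miripk import reference
from miripk.nca import (
    NCAError,
    NCA_PARAMETERS,
    auc_aumc,
    dose_proportionality,
    nca_profile,
    summarize_groups,
    terminal_slope,
    welch_test,
)


class TestAucAumc:
    def test_constant_profile(self):
        auc, aumc = auc_aumc([0.0, 100.0], [2.0, 2.0])
        assert auc == pytest.approx(200.0)
        assert aumc == pytest.approx(2.0 * 100.0**2 / 2.0)

    def test_hand_trapezoid(self):
        auc, _ = auc_aumc([0.0, 60.0, 120.0], [0.0, 2.0, 1.0])
        assert auc == pytest.approx(60.0 + 90.0)

    def test_dense_exponential_reaches_closed_form(self):
        k, c0 = 0.01, 5.0
        t = np.linspace(0.0, 3000.0, 30_000)
        auc, _ = auc_aumc(t, c0 * np.exp(-k * t))
        assert auc == pytest.approx(c0 / k, rel=1e-3)

    def test_log_down_is_exact_on_exponential_segments(self):
        k, c0 = 0.01, 5.0
        t = np.array([0.0, 100.0, 300.0, 600.0])
        c = c0 * np.exp(-k * t)
        auc, _ = auc_aumc(t, c, method="lin_up_log_down")
        exact = (c0 / k) * (1 - math.exp(-k * 600.0))
        assert auc == pytest.approx(exact, rel=1e-12)

    def test_collinear_insertion_invariance(self):
        t = np.array([0.0, 60.0, 120.0, 240.0])
        c = np.array([0.0, 4.0, 2.0, 1.0])
        auc0, _ = auc_aumc(t, c)
        # insert midpoints on every straight segment
        t2, c2 = [t[0]], [c[0]]
        for i in range(1, t.size):
            tm = 0.5 * (t[i - 1] + t[i])
            t2 += [tm, t[i]]
            c2 += [float(np.interp(tm, t, c)), c[i]]
        auc1, _ = auc_aumc(t2, c2)
        assert auc1 == pytest.approx(auc0, abs=1e-12)

    def test_insufficient_points(self):
        with pytest.raises(NCAError):
            auc_aumc([0.0], [1.0])


class TestTerminalSlope:
    def test_exact_monoexponential_tail(self):
        k = 0.005
        t = np.array([10.0, 30.0, 60.0, 120.0, 240.0, 480.0, 720.0])
        c = 4.0 * np.exp(-k * t)
        # force a peak at the first point so the tail is the rest
        c[0] = 5.0
        res = terminal_slope(t, c)
        assert res.lambda_z == pytest.approx(k, abs=1e-10)
        assert res.adj_r2 == pytest.approx(1.0)

    def test_recovers_ke_from_model_profile(self):
        from miripk.pk_models import OneCmtParams, conc_1cmt

        p = OneCmtParams(ka=0.5, ke=0.002, v=5.0, dose=15.0)
        t = np.array([5, 10, 15, 30, 60, 120, 240, 480, 720, 1080, 1440.0])
        res = terminal_slope(t, conc_1cmt(p, t))
        assert res.lambda_z == pytest.approx(p.ke, rel=0.02)

    def test_flat_tail_yields_failure_marker(self):
        t = np.array([0.0, 10.0, 20.0, 30.0, 40.0, 50.0])
        c = np.array([5.0, 2.0, 2.0, 2.0, 2.0, 2.0])
        assert terminal_slope(t, c) is None

    def test_tmax_excluded_from_window(self):
        t = np.array([0.0, 10.0, 30.0, 60.0, 120.0, 240.0])
        c = np.array([0.0, 6.0, 4.0, 2.5, 1.4, 0.5])
        res = terminal_slope(t, c)
        assert res.n_points <= 4  # peak at t=10 can never be in the window


class TestProfileNCA:
    def test_internal_relations_hold_to_machine_precision(self, study_table):
        sub = study_table[study_table.subject_id == "MIRI-15-r1"]
        res = nca_profile(sub.time_min.to_numpy(),
                          sub.conc_mg_per_L.to_numpy(), 15.0)
        assert res.t_half == pytest.approx(math.log(2) / res.lambda_z, rel=1e-12)
        assert res.cl == pytest.approx(15.0 / res.auc_0_inf, rel=1e-12)
        assert res.vz == pytest.approx(res.cl / res.lambda_z, rel=1e-12)
        assert res.auc_0_inf >= res.auc_0_t > 0
        assert res.mrt_0_inf >= res.mrt_0_t

    def test_published_summary_consistency_vz(self):
        """Vz back-computed from the published Nor-15 summary values."""
        lam = math.log(2) / reference.mean("t_half", "Nor-15")
        vz = 15.0 / (lam * reference.mean("auc_0_inf", "Nor-15"))
        assert round(vz, 2) == reference.mean("vz", "Nor-15") == 5.83

    def test_published_summary_consistency_cl(self):
        cl = 15.0 / reference.mean("auc_0_inf", "MIRI-15")
        assert round(cl, 2) == reference.mean("cl", "MIRI-15") == 0.02

    def test_bolus_mrt_is_inverse_rate(self):
        k = 0.004
        t = np.linspace(0.0, 5000.0, 20_000)
        res = nca_profile(t, 5.0 * np.exp(-k * t), dose=10.0)
        assert res.mrt_0_inf == pytest.approx(1.0 / k, rel=0.01)


class TestWelch:
    def test_identical_summaries(self):
        res = welch_test(5.0, 1.0, 8, 5.0, 1.0, 8)
        assert res.t == 0.0
        assert res.p == 1.0

    def test_published_mrt_comparison_rounds_to_0004(self):
        m1, s1 = reference.SUMMARY["mrt_0_inf"]["Nor-15"]
        m2, s2 = reference.SUMMARY["mrt_0_inf"]["MIRI-15"]
        res = welch_test(m1, s1, 8, m2, s2, 8)
        assert round(res.p, 3) == 0.004

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            m1, m2 = rng.normal(0, 10, 2)
            s1, s2 = rng.uniform(0.5, 5.0, 2)
            n1, n2 = rng.integers(3, 30, 2)
            ours = welch_test(m1, s1, int(n1), m2, s2, int(n2))
            ref = stats.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2,
                                             equal_var=False)
            assert abs(ours.p - ref.pvalue) < 1e-10

    @given(m1=st.floats(-100, 100), m2=st.floats(-100, 100),
           s1=st.floats(0.1, 10), s2=st.floats(0.1, 10))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_symmetric_in_group_order(self, m1, m2, s1, s2):
        a = welch_test(m1, s1, 8, m2, s2, 8)
        b = welch_test(m2, s2, 8, m1, s1, 8)
        assert a.p == pytest.approx(b.p, rel=1e-12)
        assert a.t == pytest.approx(-b.t, rel=1e-12)

    def test_degenerate_input_rejected(self):
        with pytest.raises(NCAError):
            welch_test(5.0, 0.0, 8, 5.0, 0.0, 8)


class TestDoseProportionality:
    def test_perfect_line(self):
        _, _, r2 = dose_proportionality([1, 2, 4], [2, 4, 8])
        assert r2 == pytest.approx(1.0)

    def test_published_auc_regression(self):
        doses, means = reference.dose_exposure_points("auc_0_t")
        _, _, r2 = dose_proportionality(doses, means)
        assert round(r2, 4) == 0.9958

    def test_hand_computed_three_points(self):
        slope, _, r2 = dose_proportionality([1, 2, 3], [1, 3, 4])
        assert slope == pytest.approx(1.5)
        assert r2 == pytest.approx(27.0 / 28.0)

    def test_equal_doses_rejected(self):
        with pytest.raises(NCAError):
            dose_proportionality([5, 5, 5], [1, 2, 3])


class TestGroupSummaries:
    def _results(self, study_table):
        out = {}
        doses = {}
        for (g, _s), sub in study_table.groupby(["group", "subject_id"]):
            d = float(sub.dose_mg_per_kg.iloc[0])
            doses[g] = d
            res = nca_profile(sub.time_min.to_numpy(),
                              sub.conc_mg_per_L.to_numpy(), d)
            out.setdefault(g, []).append(res)
        return out, doses

    def test_replicated_value_has_zero_sd(self):
        res, doses = {"g": []}, {"g": 1.0}
        t = np.array([5, 10, 30, 60, 120, 240, 480.0])
        c = 2.0 * np.exp(-0.005 * t)
        c[0] = 2.5
        prof = nca_profile(t, c, 1.0)
        res["g"] = [prof, prof, prof]
        summ, _ = summarize_groups(res, doses)
        assert (summ.sd.abs() < 1e-12).all()
        assert np.allclose(summ[summ.parameter == "cmax"]["mean"], prof.cmax)

    def test_parameter_rows_match_reported_set(self, study_table):
        res, doses = self._results(study_table)
        summ, welch = summarize_groups(res, doses, ("Nor-15", "MIRI-15"))
        assert set(summ.parameter) == set(NCA_PARAMETERS) \
            == set(reference.SUMMARY)
        assert set(welch.parameter) == set(NCA_PARAMETERS)

    def test_clearance_comparison_suppressed_at_report_precision(self):
        """Two groups whose CL agrees at 2 printed decimals get 'N.C.'."""
        t = np.array([5, 10, 30, 60, 120, 240, 480.0])

        def prof(c0):
            c = c0 * np.exp(-0.005 * t)
            c[0] = c0 * 1.2
            return nca_profile(t, c, 1.0)

        res = {"a": [prof(2.0), prof(2.002), prof(1.998)],
               "b": [prof(2.001), prof(1.999), prof(2.0)]}
        _, welch = summarize_groups(res, {"a": 1.0, "b": 1.0}, ("a", "b"))
        note = welch[welch.parameter == "cl"].note.iloc[0]
        assert note == "N.C."

    def test_exposure_difference_is_detected(self, study_table):
        res, doses = self._results(study_table)
        _, welch = summarize_groups(res, doses, ("Nor-15", "MIRI-15"))
        p = welch[welch.parameter == "auc_0_inf"].p.iloc[0]
        assert p < 0.001
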