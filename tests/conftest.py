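import numpy as np
import pytest
from scipy.integrate import solve_ivp

from miripk.synthetic_data import (
    ErrorModel,
    PDScenario,
    StudyDesign,
    default_design,
    simulate_pk_study,
)


@pytest.fixture(scope="session")
def design():
    return default_design(seed=20260)


@pytest.fixture(scope="session")
def study_table(design):
    return simulate_pk_study(design)


@pytest.fixture()
def noise_free_design(design):
    """Default design stripped of every noise source."""
    return StudyDesign(
        groups=design.groups,
        schedule=design.schedule,
        error_model=ErrorModel(prop_cv=0.0, add_sd=0.0),
        true_params=design.true_params,
        iiv_cv=0.0,
        seed=design.seed,
    )


@pytest.fixture()
def zero_noise_scenario():
    return PDScenario(noise_sd=0.0)


def ode_conc_1cmt(ka, ke, v, dose, tlag, times):
    """Independent oracle: integrate the two-state absorption system."""
    times = np.asarray(times, dtype=float)

    def rhs(_t, y):
        return [-ka * y[0], ka * y[0] - ke * y[1]]

    out = np.zeros_like(times)
    pos = times > tlag
    if pos.any():
        tau = times[pos] - tlag
        sol = solve_ivp(rhs, (0.0, tau.max()), [dose, 0.0], t_eval=tau,
                        rtol=1e-10, atol=1e-14, method="LSODA")
        out[pos] = sol.y[1] / v
    return out


def ode_conc_2cmt(ka, k10, k12, k21, v1, dose, tlag, times):
    """Independent oracle: integrate the three-state system."""
    times = np.asarray(times, dtype=float)

    def rhs(_t, y):
        a, c, p = y
        return [-ka * a,
                ka * a - (k10 + k12) * c + k21 * p,
                k12 * c - k21 * p]

    out = np.zeros_like(times)
    pos = times > tlag
    if pos.any():
        tau = times[pos] - tlag
        sol = solve_ivp(rhs, (0.0, tau.max()), [dose, 0.0, 0.0], t_eval=tau,
                        rtol=1e-10, atol=1e-14, method="LSODA")
        out[pos] = sol.y[1] / v1
    return out


def ode_effect_site(cp_fn, ke0, times):
    """Independent oracle: integrate dCe/dt = ke0 (Cp - Ce) from Ce(0) = 0."""
    times = np.asarray(times, dtype=float)

    def rhs(t, y):
        return [ke0 * (cp_fn(t) - y[0])]

    sol = solve_ivp(rhs, (0.0, times.max()), [0.0], t_eval=times,
                    rtol=1e-10, atol=1e-14, method="LSODA", max_step=10.0)
    return sol.y[0]
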