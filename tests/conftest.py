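import numpy as np
import pytest

from raitg import (
    CohortDesign,
    IndividualParameters,
    PopulationParameters,
    Regimen,
    generate_cohort,
)
from raitg.model_core import LN2


@pytest.fixture(scope="session")
def study_pop() -> PopulationParameters:
    """Published population estimates used as generating truth."""
    return PopulationParameters.study_estimates()


@pytest.fixture(scope="session")
def median_params(study_pop) -> IndividualParameters:
    return IndividualParameters(
        rho=study_pop.pop_rho,
        a=study_pop.pop_a,
        lam=study_pop.pop_lam,
        ke=study_pop.pop_ke,
        Td=study_pop.pop_Td,
        N0=study_pop.pop_N0,
    )


@pytest.fixture
def single_dose() -> Regimen:
    return Regimen.single(3.7)


@pytest.fixture(scope="session")
def small_cohort(study_pop):
    """50 virtual patients with the study design (deterministic seed)."""
    return generate_cohort(study_pop, CohortDesign(n_patients=50), seed=2024)


def random_instance(rng):
    """One random parameter set + regimen, spanning realistic kinetic ranges."""
    n_doses = int(rng.integers(1, 9))
    activities = rng.uniform(3.7, 5.5, size=n_doses)
    intervals = rng.uniform(6.0, 8.0, size=n_doses - 1)
    times = np.concatenate([[0.0], np.cumsum(intervals)])
    from raitg import DoseEvent

    regimen = Regimen(tuple(DoseEvent(t, a) for t, a in zip(times, activities)))
    p = IndividualParameters(
        rho=float(np.exp(rng.uniform(np.log(5e-4), np.log(5e-2)))),
        a=float(np.exp(rng.uniform(np.log(5e-3), np.log(0.2)))),
        lam=float(np.exp(rng.uniform(np.log(1e-10), np.log(1e-7)))),
        ke=float(np.exp(rng.uniform(np.log(0.05), np.log(3.0)))),
        Td=float(np.exp(rng.uniform(np.log(3.0), np.log(150.0)))),
        N0=float(np.exp(rng.uniform(np.log(1e7), np.log(1e10)))),
    )
    return p, regimen


def ode_oracle(p, regimen, t_eval, tg0, rtol=1e-10):
    """Brute-force reference: integrate the three coupled ODEs piecewise
    between administrations, adding each dose to the activity compartment."""
    from scipy.integrate import solve_ivp

    def rhs(t, y):
        A, N, Tg = y
        return [
            -p.a * LN2 * A,
            (LN2 / p.Td) * N - p.rho * A * N,
            -p.ke * Tg + p.lam * N,
        ]

    t_eval = np.asarray(t_eval, dtype=float)
    dose_t = regimen.times
    dose_a = regimen.activities
    t_end = max(t_eval[-1], dose_t[-1]) + 1e-9
    segments = np.unique(np.concatenate([dose_t, [t_end]]))
    y = np.array([0.0, p.N0, tg0])
    out = np.empty((3, t_eval.size))
    if t_eval[0] == 0.0:
        out[:, 0] = [dose_a[0], p.N0, tg0]
    for k in range(segments.size - 1):
        t0, t1 = segments[k], segments[k + 1]
        hit = np.isclose(t0, dose_t)
        if hit.any():
            y[0] += dose_a[hit][0]
        sel = (t_eval > t0) & (t_eval <= t1)
        pts = t_eval[sel]
        # near-zero atol: the tumor compartment can fall many decades under a
        # strong kill term, so accuracy must be carried by rtol alone
        sol = solve_ivp(
            rhs,
            [t0, t1],
            y,
            t_eval=np.concatenate([pts, [t1]]),
            rtol=rtol,
            atol=[1e-14, 1e-12, 1e-14],
            method="LSODA",
        )
        if pts.size:
            out[:, sel] = sol.y[:, : pts.size]
        y = sol.y[:, -1]
    return {"activity": out[0], "tumor": out[1], "tg": out[2]}
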