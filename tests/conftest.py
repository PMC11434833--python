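import numpy as np
import pytest
from dataclasses import replace

import peritopk as pk

ZERO_VARIABILITY = dict(
    omegaV1=0.0, omegaCl1=0.0, omegaCl2=0.0, gammaCl1=0.0, bC1=0.0, bC2=0.0
)


@pytest.fixture(scope="session")
def pip_params():
    return pk.piperacillin_params()


@pytest.fixture(scope="session")
def taz_params():
    return pk.tazobactam_params()


@pytest.fixture(scope="session")
def pip_noiseless(pip_params):
    return replace(pip_params, **ZERO_VARIABILITY)


@pytest.fixture(scope="session")
def taz_noiseless(taz_params):
    return replace(taz_params, **ZERO_VARIABILITY)


@pytest.fixture(scope="session")
def small_cohort(pip_params, taz_params):
    """A 20-subject cohort at the study design, fixed seed."""
    design = pk.CohortDesign(n_patients=20)
    return pk.generate_cohort(design, pip_params, taz_params, seed=1234)


def rk4_profile(p, schedule, t_end, dt=1e-3):
    """Independent fixed-step RK4 integration of the two-compartment system.

    Deliberately naive: direct ODE right-hand side, no matrix exponential,
    so it cross-checks the analytic path.
    """
    k = pk.rate_constants(p)
    k10, k12, k21, k20 = k["k10"], k["k12"], k["k21"], k["k20"]

    def rhs(r, a1, a2):
        return (r - (k10 + k12) * a1 + k21 * a2, k12 * a1 - (k21 + k20) * a2)

    # integrate breakpoint-to-breakpoint: the input is piecewise constant,
    # so each segment uses its own constant rate and no RK4 substep ever
    # straddles a rate change
    times = [b for b in schedule.breakpoints() if b < t_end] + [t_end]
    times = sorted(set([0.0] + times))
    a1 = a2 = 0.0
    for lo, hi in zip(times[:-1], times[1:]):
        r = schedule.rate_at(lo)
        n = max(int(np.ceil((hi - lo) / dt)), 1)
        h = (hi - lo) / n
        for _ in range(n):
            d1 = rhs(r, a1, a2)
            d2 = rhs(r, a1 + h / 2 * d1[0], a2 + h / 2 * d1[1])
            d3 = rhs(r, a1 + h / 2 * d2[0], a2 + h / 2 * d2[1])
            d4 = rhs(r, a1 + h * d3[0], a2 + h * d3[1])
            a1 += h / 6 * (d1[0] + 2 * d2[0] + 2 * d3[0] + d4[0])
            a2 += h / 6 * (d1[1] + 2 * d2[1] + 2 * d3[1] + d4[1])
    return a1 / p.V1, a2 / p.V2
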