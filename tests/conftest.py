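import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from socdisc.discount_models import fit_mle
from socdisc.simulate import (AgentParams, DDMParams, simulate_participant,
                              simulate_ddm_trials)
from socdisc.task import TaskDesign

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def design() -> TaskDesign:
    return TaskDesign()


# -- shared heavy fixtures ---------------------------------------------------
# Parameter-recovery at cohort scale and the Euler first-passage oracle are
# used both by the module tests and the acceptance suite; computing them once
# per session keeps the full run fast.

MLE_TRUTH = AgentParams(k=0.2, V=250.0, sigma=0.05)


@pytest.fixture(scope="session")
def mle_recovery(design):
    """100 simulated softmax participants at a common truth, fitted by MLE."""
    rng = np.random.default_rng(20240522)
    fits = []
    for i in range(100):
        recs = simulate_participant(
            MLE_TRUTH, None, design, rng, participant_id=f"r{i:03d}")
        trials = pd.DataFrame(
            [{"participant_id": r.participant_id, "choice": r.choice,
              "distance": r.distance, "selfish_amount": r.selfish_amount,
              "rt": r.rt} for r in recs])
        fits.append(fit_mle(trials, design))
    return MLE_TRUTH, fits


EULER_PARAM_SETS = (
    DDMParams(alpha=1.5, beta=0.4, delta=0.8, tau=0.2),
    DDMParams(alpha=1.0, beta=0.5, delta=0.0, tau=0.3),
    DDMParams(alpha=2.0, beta=0.3, delta=-0.5, tau=0.15),
)


@pytest.fixture(scope="session")
def euler_samples():
    """First-passage Monte-Carlo samples (n = 80k) for three parameter
    sets, simulated with the bridge-corrected Euler scheme at dt = 1 ms."""
    out = {}
    for i, p in enumerate(EULER_PARAM_SETS):
        rng = np.random.default_rng(1000 + i)
        out[p] = simulate_ddm_trials(p, 80_000, rng, dt=0.001)
    return out
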