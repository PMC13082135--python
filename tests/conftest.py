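import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_startstop(n_subjects=120, seed=42, p_event=0.18, n_cov=2):
    """Deterministic random start-stop dataset with continuous covariates."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        t = 0.0
        x_fixed = rng.normal()
        for k in range(rng.integers(1, 5)):
            dur = rng.exponential(5) + 0.5
            ev = int(rng.random() < p_event)
            row = [i, t, t + dur, ev, rng.normal()]
            if n_cov > 1:
                row.append(x_fixed)
            rows.append(row)
            t += dur
            if ev:
                break
    cols = ["id", "start", "stop", "event_interval"] + [f"x{j+1}" for j in range(n_cov)]
    return pd.DataFrame(rows, columns=cols)


@pytest.fixture(scope="session")
def startstop_df():
    return make_startstop()


@pytest.fixture(scope="session")
def small_cohort():
    from initsurv import SimConfig, generate_cohort

    cfg = SimConfig(n_participants=250, seed=3, mc_truth_n=2000)
    return generate_cohort(cfg)
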