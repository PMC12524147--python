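import pandas as pd
import pytest

from fearfit import RWModelSpec, SubjectParams, simulate_cohort
from fearfit.simulate import CohortEffects


def random_trial_records(rng, n_acq=12, n_ext=12):
    """Random (phase, stimulus, us) tuples for oracle comparisons."""
    records = []
    for _ in range(n_acq):
        stim = rng.choice(["CSP", "CSM", "NA"])
        us = int(stim == "CSP" and rng.random() < 0.75)
        records.append(("acquisition", stim, us))
    for _ in range(n_ext):
        records.append(("extinction", str(rng.choice(["CSP", "CSM", "NA"])), 0))
    return records


def records_to_frame(records):
    rows = []
    idx = {"acquisition": 0, "extinction": 0}
    for phase, stim, us in records:
        idx[phase] += 1
        rows.append((phase, idx[phase], stim, us))
    return pd.DataFrame(
        rows, columns=["phase", "trial_index", "stimulus", "us"]
    )


def random_params(rng):
    return SubjectParams(
        lr_acq_plus=float(rng.uniform(0.02, 0.98)),
        lr_acq_minus=float(rng.uniform(0.02, 0.98)),
        lr_ext=float(rng.uniform(0.02, 0.98)),
        beta_intercept=float(rng.normal(100, 20)),
    )


@pytest.fixture(scope="session")
def m4():
    return RWModelSpec(2, True)


@pytest.fixture(scope="session")
def null_cohort():
    """20 subjects, no planted effects, no artifacts; default task design."""
    return simulate_cohort(20, effects=CohortEffects.null(0.0), seed=11)


@pytest.fixture(scope="session")
def default_cohort():
    """60 subjects under the default (paper-like) generator settings."""
    return simulate_cohort(60, seed=17)
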