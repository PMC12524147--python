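"""Unit and property tests for the RW expectation engine and observation model."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fearfit import (
    GroupParams,
    RWModelSpec,
    SubjectParams,
    forward_expectations,
    log_likelihood,
    predicted_startle,
    rw_update,
)

from _oracle import oracle_expectations, oracle_loglik
from conftest import random_params, random_trial_records, records_to_frame


@pytest.mark.parametrize(
    "e, lr, us, expected",
    [
        (0.5, 0.2, 1, 0.6),
        (0.73, 1e-12, 1, 0.73),      # vanishing learning rate: identity
        (0.9, 1.0, 0, 0.0),          # full-update limit
        (0.0, 0.3, 0, 0.0),
        (1.0, 0.3, 1, 1.0),
    ],
)
def test_rw_update_examples(e, lr, us, expected):
    assert rw_update(e, lr, us) == pytest.approx(expected, abs=1e-9)


def test_model_spec_ids_and_roundtrip():
    assert RWModelSpec(1, False).id == "M1"
    assert RWModelSpec(1, True).id == "M2"
    assert RWModelSpec(2, False).id == "M3"
    assert RWModelSpec(2, True).id == "M4"
    assert RWModelSpec.from_id("m3") == RWModelSpec(2, False)
    with pytest.raises(ValueError):
        RWModelSpec.from_id("M9")
    with pytest.raises(ValueError):
        RWModelSpec(3, True)


def test_subject_params_bounds():
    with pytest.raises(ValueError, match="lr_ext"):
        SubjectParams(0.2, 0.2, 1.0, 100.0)
    with pytest.raises(ValueError, match="lr_acq_plus"):
        SubjectParams(0.0, 0.2, 0.5, 100.0)


def test_two_hand_iterations_of_update(m4):
    # CS+(us=1), CS+(us=1) at lr 0.5 from E0=0.5: 0.75 then 0.875 before trial 3
    trials = records_to_frame(
        [("acquisition", "CSP", 1)] * 3
    )
    params = SubjectParams(0.5, 0.5, 0.5, 0.0)
    fw = forward_expectations(trials, params, m4)
    assert fw["e_disc"].tolist() == pytest.approx([0.5, 0.75, 0.875])


def test_forward_matches_bruteforce_oracle(m4):
    rng = np.random.default_rng(5)
    for _ in range(50):
        records = random_trial_records(rng)
        params = random_params(rng)
        fw = forward_expectations(records_to_frame(records), params, m4)
        expected = oracle_expectations(
            records, params.lr_acq_plus, params.lr_acq_minus, params.lr_ext
        )
        got = list(zip(fw["e_disc"], fw["e_gen"]))
        assert np.allclose(got, expected, atol=1e-14)


def test_one_lr_spec_collapses_us_minus_rate():
    rng = np.random.default_rng(8)
    records = random_trial_records(rng)
    trials = records_to_frame(records)
    p2 = SubjectParams(0.4, 0.9, 0.2, 0.0)
    p_equal = SubjectParams(0.4, 0.4, 0.2, 0.0)
    one_lr = forward_expectations(trials, p2, RWModelSpec(1, True))
    two_lr = forward_expectations(trials, p_equal, RWModelSpec(2, True))
    assert np.allclose(one_lr["e_disc"], two_lr["e_disc"])


def test_cs_minus_expectation_monotone_nonincreasing(m4):
    rng = np.random.default_rng(3)
    for _ in range(10):
        records = random_trial_records(rng, n_acq=20, n_ext=20)
        params = random_params(rng)
        fw = forward_expectations(records_to_frame(records), params, m4)
        csm = fw.loc[fw["stimulus"] == "CSM", "e_disc"].to_numpy()
        assert np.all(np.diff(csm) <= 1e-14)


@settings(max_examples=30, deadline=None)
@given(
    seed=st.integers(0, 10_000),
    lrp=st.floats(0.01, 0.99),
    lrm=st.floats(0.01, 0.99),
    lre=st.floats(0.01, 0.99),
)
def test_expectation_closure(seed, lrp, lrm, lre):
    """Expectations stay in [0, 1] for any sequence and valid rates."""
    rng = np.random.default_rng(seed)
    records = random_trial_records(rng, n_acq=16, n_ext=16)
    params = SubjectParams(lrp, lrm, lre, 0.0)
    fw = forward_expectations(records_to_frame(records), params,
                              RWModelSpec(2, True))
    assert ((fw["e_disc"] >= 0) & (fw["e_disc"] <= 1)).all()
    assert ((fw["e_gen"] >= 0) & (fw["e_gen"] <= 1)).all()


def test_permutation_sensitivity(m4):
    """Reversing trial order changes expectations (order matters)."""
    rng = np.random.default_rng(7)
    records = random_trial_records(rng)
    params = random_params(rng)
    fwd = forward_expectations(records_to_frame(records), params, m4)
    rev_records = records[:12][::-1] + records[12:][::-1]
    rev = forward_expectations(records_to_frame(rev_records), params, m4)
    # an order-insensitive implementation would produce the same values in
    # presentation order; the true forward pass must not
    a = fwd.loc[fwd.stimulus != "NA", "e_disc"].tolist()
    b = rev.loc[rev.stimulus != "NA", "e_disc"].tolist()
    assert a != b


def test_unordered_trials_rejected(m4):
    trials = records_to_frame([("acquisition", "CSP", 1)] * 3)
    shuffled = trials.iloc[[2, 0, 1]]
    with pytest.raises(ValueError, match="ordered"):
        forward_expectations(shuffled, SubjectParams(0.3, 0.3, 0.3, 0.0), m4)


def test_extinction_decay_closed_form(m4):
    """With no US, E_disc[CSP] decays geometrically at rate (1 - lr_ext)."""
    e0, lre = 0.5, 0.31
    k = 16
    records = [("extinction", "CSP", 0)] * k
    params = SubjectParams(0.2, 0.1, lre, 0.0)
    fw = forward_expectations(records_to_frame(records), params, m4, e0=e0)
    expected = e0 * (1.0 - lre) ** np.arange(k)
    assert np.allclose(fw["e_disc"], expected, rtol=0, atol=1e-15)


def test_predicted_startle_constant_when_betas_zero(m4):
    rng = np.random.default_rng(1)
    trials = records_to_frame(random_trial_records(rng))
    params = SubjectParams(0.3, 0.2, 0.4, 123.0)
    group = GroupParams(0.0, 0.0, 0.0, 1.0)
    mean = predicted_startle(trials, params, group, m4)
    assert np.allclose(mean, 123.0)


def test_na_predictions_habituate_monotonically(m4):
    rng = np.random.default_rng(2)
    trials = records_to_frame(random_trial_records(rng))
    params = random_params(rng)
    group = GroupParams(-0.5, 80.0, 40.0, 5.0)
    mean = predicted_startle(trials, params, group, m4)
    na = mean[(trials["stimulus"] == "NA").to_numpy()]
    assert np.all(np.diff(na) < 0)


def test_generalization_beta_rejected_for_disc_only_spec():
    group = GroupParams(-0.5, 80.0, 40.0, 5.0)
    with pytest.raises(ValueError, match="beta_generalization"):
        group.validate_for(RWModelSpec(2, False))


def test_loglik_gaussian_mode_and_scaling(m4):
    trials = records_to_frame([("acquisition", "NA", 0)])
    params = SubjectParams(0.3, 0.2, 0.4, 10.0)
    trials["startle"] = 10.0     # observation exactly at the mean, t=0
    total, per = log_likelihood(
        trials, params, GroupParams(0.0, 0.0, 0.0, 1.0), m4
    )
    assert per[0] == pytest.approx(-0.5 * np.log(2 * np.pi))
    total2, _ = log_likelihood(
        trials, params, GroupParams(0.0, 0.0, 0.0, 2.0), m4
    )
    assert total2 == pytest.approx(total - np.log(2.0))


def test_loglik_matches_independent_density(m4):
    rng = np.random.default_rng(9)
    records = random_trial_records(rng)
    trials = records_to_frame(records)
    params = random_params(rng)
    group = GroupParams(-0.4, 120.0, 60.0, 25.0)
    trials["startle"] = rng.normal(100, 40, size=len(trials))
    total, _ = log_likelihood(trials, params, group, m4)
    mean = predicted_startle(trials, params, group, m4)
    assert total == pytest.approx(
        oracle_loglik(trials["startle"].tolist(), mean.tolist(), 25.0)
    )


def test_model_nesting_likelihood_equivalence():
    """Constrained M4 reproduces M1/M2/M3 per-trial log-likelihoods."""
    rng = np.random.default_rng(12)
    records = random_trial_records(rng, n_acq=16, n_ext=16)
    trials = records_to_frame(records)
    trials["startle"] = rng.normal(100, 30, size=len(trials))
    m4 = RWModelSpec(2, True)
    p = SubjectParams(0.35, 0.35, 0.2, 95.0)

    # M1: equal acquisition rates, no generalization weight
    g1 = GroupParams(-0.5, 100.0, 0.0, 20.0)
    _, ll_m1 = log_likelihood(trials, p, g1, RWModelSpec(1, False))
    _, ll_m4c = log_likelihood(trials, p, g1, m4)
    assert np.array_equal(ll_m1, ll_m4c)

    # M2: equal acquisition rates, generalization active
    g2 = GroupParams(-0.5, 100.0, 55.0, 20.0)
    _, ll_m2 = log_likelihood(trials, p, g2, RWModelSpec(1, True))
    _, ll_m4c2 = log_likelihood(trials, p, g2, m4)
    assert np.array_equal(ll_m2, ll_m4c2)

    # M3: distinct acquisition rates, no generalization weight
    p3 = SubjectParams(0.5, 0.15, 0.2, 95.0)
    _, ll_m3 = log_likelihood(trials, p3, g1, RWModelSpec(2, False))
    _, ll_m4c3 = log_likelihood(trials, p3, g1, m4)
    assert np.array_equal(ll_m3, ll_m4c3)
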