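"""Synthetic-cohort generator: observation model, planted effects, panels."""

import numpy as np
import pandas as pd
import pytest

import fearfit as ff
from fearfit import GroupParams, RWModelSpec, SubjectParams
from fearfit.simulate import (
    CohortEffects,
    PopulationTruth,
    simulate_cohort,
    simulate_startle,
)
from fearfit.task import TaskDesign, simulate_trial_sequence


def test_noise_free_degenerate_case(m4):
    """All betas zero, vanishing noise: every modeled trial = intercept."""
    trials = simulate_trial_sequence(TaskDesign(), seed=0)
    params = SubjectParams(0.3, 0.2, 0.4, 100.0)
    group = GroupParams(0.0, 0.0, 0.0, 1e-9)
    out = simulate_startle(trials, params, group, m4, seed=1)
    assert np.allclose(out["startle"], 100.0, atol=1e-6)


def test_full_learning_rate_boundary(m4):
    """lr ~ 1: the CS+ trial after a reinforced one carries expectation 1."""
    trials = simulate_trial_sequence(TaskDesign(), seed=4)
    lr = 1.0 - 1e-12
    params = SubjectParams(lr, lr, lr, 50.0)
    group = GroupParams(0.0, 80.0, 40.0, 1e-9)
    out = simulate_startle(trials, params, group, m4, seed=1)
    mod = out[out["stimulus"] != "STAB"].reset_index(drop=True)
    csp = mod[mod["stimulus"] == "CSP"].index
    reinforced = mod.loc[csp, "us"].to_numpy() == 1
    # each CS+ trial following a reinforced CS+ has E_disc = 1; E_gen depends
    # on the interleaved CS- trials, so check the discrimination part only
    assert reinforced.sum() >= 1
    for prev, cur in zip(csp[:-1], csp[1:]):
        if mod.loc[prev, "us"] == 1:
            # discrimination term saturated at E = 1 (habituation slope is 0)
            assert mod.loc[cur, "startle"] >= 50.0 + 80.0 * 1.0 - 1e-6


def test_noise_free_runs_share_means(m4):
    """Two seeds differ only in the noise term (identical noise-free means)."""
    trials = simulate_trial_sequence(TaskDesign(), seed=4)
    params = SubjectParams(0.3, 0.15, 0.2, 100.0)
    group_nf = GroupParams(-0.5, 150.0, 100.0, 1e-12)
    a = simulate_startle(trials, params, group_nf, m4, seed=1)
    b = simulate_startle(trials, params, group_nf, m4, seed=2)
    assert np.allclose(a["startle"], b["startle"], atol=1e-6)


def test_affine_inversion_recovers_betas(m4):
    """Noise-free startle is exactly affine in the RW expectations."""
    trials = simulate_trial_sequence(TaskDesign(), seed=6)
    params = SubjectParams(0.28, 0.14, 0.22, 87.0)
    group = GroupParams(-0.6, 150.0, 100.0, 1e-12)
    out = simulate_startle(trials, params, group, m4, seed=0)
    fw = ff.forward_expectations(out, params, m4)
    X = np.column_stack(
        [np.ones(len(fw)), fw["t"], fw["e_disc"], fw["e_gen"]]
    )
    y = fw["startle"].to_numpy()
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    assert np.allclose(coef, [87.0, -0.6, 150.0, 100.0], atol=1e-6)


def test_mismatched_group_params_rejected():
    trials = simulate_trial_sequence(TaskDesign(), seed=0)
    params = SubjectParams(0.3, 0.2, 0.4, 100.0)
    with pytest.raises(ValueError, match="beta_generalization"):
        simulate_startle(
            trials, params, GroupParams(0.0, 80.0, 40.0, 10.0),
            RWModelSpec(2, False), seed=1,
        )


def test_cohort_reproducible_and_prevalence():
    a = simulate_cohort(100, effects=CohortEffects(prevalence=0.05), seed=21)
    b = simulate_cohort(100, effects=CohortEffects(prevalence=0.05), seed=21)
    pd.testing.assert_frame_equal(a.trials, b.trials)
    pd.testing.assert_frame_equal(a.subjects, b.subjects)
    n_ptsd = (a.subjects["true_group"] == "ptsd").sum()
    assert 1 <= n_ptsd <= 12   # ~Binomial(100, 0.05)


def test_low_prevalence_warns():
    with pytest.warns(UserWarning, match="prevalence"):
        simulate_cohort(10, effects=CohortEffects(prevalence=0.01), seed=1)


def test_null_effects_leave_no_group_difference(null_cohort):
    """With all effects off, discrimination differs only by sampling error."""
    coh = simulate_cohort(
        300, effects=CohortEffects.null(prevalence=0.3), seed=33
    )
    met = ff.subject_metrics(coh.trials)
    merged = met.merge(coh.subjects, on="subject_id")
    g = merged.groupby(merged["true_group"] == "ptsd")["discrimination_index"]
    means = g.mean()
    pooled_se = np.sqrt(sum(g.var() / g.count()))
    assert abs(means[True] - means[False]) < 4 * pooled_se


def test_planted_discrimination_deficit_shows_in_metrics():
    coh = simulate_cohort(
        400,
        effects=CohortEffects(prevalence=0.3, disc_attenuation=0.3,
                              artifact_rate=0.0, nonlearner_rate=0.0,
                              pre_positive_rate=0.0, comorbid_rate=0.0,
                              depanx_rate=0.0),
        seed=34,
    )
    met = ff.subject_metrics(coh.trials).merge(coh.subjects, on="subject_id")
    ptsd = met[met["true_group"] == "ptsd"]["discrimination_index"]
    healthy = met[met["true_group"] == "healthy"]["discrimination_index"]
    assert ptsd.mean() < 0.7 * healthy.mean()


def test_artifact_rate_zero_means_no_flags(null_cohort):
    assert not null_cohort.trials["artifact_flag"].any()


def test_planted_artifact_rate_matches_configuration(default_cohort):
    rate, _ = ff.artifact_rate(default_cohort.trials)
    n = (default_cohort.trials["stimulus"] != "STAB").sum()
    se = np.sqrt(0.021 * 0.979 / n)
    assert abs(rate - 0.021) < 4 * se


def test_severity_slope_recoverable_by_regression():
    """Regressing caps_post on true lr_ext recovers the planted slope."""
    coh = simulate_cohort(
        500,
        effects=CohortEffects(prevalence=0.0, severity_slope=-40.0),
        seed=35,
    )
    x = coh.subjects["true_lr_ext"]
    y = coh.subjects["caps_post"]
    slope = np.polyfit(x, y, 1)[0]
    se = coh.subjects["caps_post"].std() / (x.std() * np.sqrt(len(x)))
    assert abs(slope - (-40.0)) < 3 * se


def test_questionnaire_ranges_and_labels(default_cohort):
    s = default_cohort.subjects
    assert s["caps_pre"].between(0, 136).all()
    assert s["caps_post"].between(0, 136).all()
    assert s["ctq"].between(25, 170).all()
    assert (s["lec"] >= 0).all()
    # post-deployment cluster counts consistent with the planted group
    ptsd_like = s["true_group"].isin(["ptsd", "comorbid_ptsd"])
    meets = (
        (s["caps_b_post"] >= 1)
        & (s["caps_c_post"] >= 2)
        & (s["caps_d_post"] >= 2)
    )
    assert (meets == ptsd_like).all()
    # pure-PTSD subjects stay below the comorbidity cutoffs
    pure = s["true_group"] == "ptsd"
    assert (s.loc[pure, "bai_post"] <= 15).all()
    assert (s.loc[pure, "bdi2_post"] <= 19).all()


def test_expectancy_calibration_on_healthy_learners(null_cohort):
    """Late-acquisition keypress means: CS+ clearly positive, CS- negative."""
    met = ff.expectancy_summaries(null_cohort.trials)
    csp = met["exp_acq_csp_lasthalf"].mean()
    csm = met["exp_acq_csm_lasthalf"].mean()
    assert 0.3 < csp <= 1.0
    assert -1.0 <= csm < -0.5


def test_expectancy_only_on_cs_trials(default_cohort):
    t = default_cohort.trials
    assert t.loc[t["stimulus"].isin(["NA", "STAB"]), "expectancy"].isna().all()
    cs = t[t["stimulus"].isin(["CSP", "CSM"])]["expectancy"].dropna()
    assert set(cs.unique()) <= {-1.0, 0.0, 1.0}


def test_nonlearner_cue_gain_zero():
    coh = simulate_cohort(
        200,
        effects=CohortEffects(prevalence=0.0, nonlearner_rate=0.5,
                              artifact_rate=0.0),
        seed=36,
    )
    met = ff.subject_metrics(coh.trials).merge(coh.subjects, on="subject_id")
    nl = met[met["true_nonlearner"] == 1]
    ok = met[met["true_nonlearner"] == 0]
    # non-learners: no cue-driven response, so adjusted CS+ centers on zero
    assert abs(nl["acq_csp_lasthalf"].mean()) < 10
    assert ok["acq_csp_lasthalf"].mean() > 50
    # roughly half of the planted non-learners fail the potentiation gate
    frac = 1.0 - nl["potentiator"].mean()
    assert 0.3 < frac < 0.7
    assert ok["potentiator"].mean() > 0.95
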