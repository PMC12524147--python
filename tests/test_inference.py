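"""Hierarchical fitting, posterior draws, and LOO machinery."""

import numpy as np
import pandas as pd
import pytest

import fearfit as ff
from fearfit import RWModelSpec
from fearfit import _kernels
from fearfit.inference import PriorConfig, compare_models, extract_learning_rates
from fearfit.simulate import CohortEffects, PopulationTruth, simulate_cohort
from fearfit.task import TaskDesign

from conftest import random_params, random_trial_records, records_to_frame

SMALL = dict(n_draws=100, gibbs_burn=200, gibbs_thin=2, outer_iters=8)


@pytest.fixture(scope="module")
def small_fit(null_cohort):
    trials = null_cohort.trials[
        null_cohort.trials["subject_id"].isin(
            null_cohort.trials["subject_id"].unique()[:8]
        )
    ]
    return trials, ff.fit_model(trials, RWModelSpec(2, True), seed=5, **SMALL)


def test_fast_kernel_matches_reference_forward(m4):
    """The compiled forward pass equals the readable pandas implementation."""
    rng = np.random.default_rng(21)
    for _ in range(25):
        records = random_trial_records(rng)
        trials = records_to_frame(records)
        params = random_params(rng)
        ref = ff.forward_expectations(trials, params, m4)
        stim = trials["stimulus"].map({"CSP": 0, "CSM": 1, "NA": 2}).to_numpy()
        is_ext = (trials["phase"] == "extinction").to_numpy(dtype=np.int64)
        us = trials["us"].to_numpy(dtype=np.int64)
        ed, eg = _kernels.forward_kernel(
            stim.astype(np.int64), is_ext, us,
            params.lr_acq_plus, params.lr_acq_minus, params.lr_ext, 0.5,
        )
        assert np.allclose(ed, ref["e_disc"], atol=1e-14)
        assert np.allclose(eg, ref["e_gen"], atol=1e-14)


def test_fit_is_reproducible(small_fit):
    trials, fit = small_fit
    again = ff.fit_model(trials, RWModelSpec(2, True), seed=5, **SMALL)
    assert np.array_equal(fit.loglik, again.loglik)
    pd.testing.assert_frame_equal(fit.subject_summary, again.subject_summary)


def test_fit_summaries_well_formed(small_fit):
    trials, fit = small_fit
    assert fit.loglik.shape == (100, 8 * 72)
    assert len(fit.subject_summary) == 8
    rhat_cols = [c for c in fit.subject_summary.columns if c.endswith("_rhat")]
    assert rhat_cols and fit.subject_summary[rhat_cols].notna().all().all()
    assert fit.group_summary["rhat"].notna().all()
    assert set(fit.group_summary["parameter"]) == {
        "beta_trial", "beta_discrimination", "beta_generalization", "obs_sd"
    }


def test_extracted_rates_in_unit_interval(small_fit):
    _, fit = small_fit
    lrs = extract_learning_rates(fit)
    for col in ("lr_acq_plus", "lr_acq_minus", "lr_ext"):
        assert lrs[col].between(0, 1, inclusive="neither").all()


def test_single_subject_cohort_runs_with_warning(null_cohort, caplog):
    one = null_cohort.trials[
        null_cohort.trials["subject_id"] == "S0001"
    ]
    with caplog.at_level("WARNING"):
        fit = ff.fit_model(one, RWModelSpec(2, True), seed=1, **SMALL)
    assert "single-subject" in caplog.text
    assert np.isfinite(fit.loglik).all()


def test_partial_pooling_shrinks_homogeneous_cohort():
    """When all subjects share one parameter set, estimates barely spread."""
    pop_same = PopulationTruth(sd_logit_lr=1e-6, intercept_sd=1e-6)
    coh = simulate_cohort(
        12, effects=CohortEffects.null(0.0), population=pop_same, seed=3
    )
    fit = ff.fit_model(coh.trials, RWModelSpec(2, True), seed=2, **SMALL)
    est = fit.subject_summary["lr_ext_mean"]
    assert est.std() < 0.05


def test_one_lr_spec_reports_equal_acquisition_rates(small_fit):
    trials, _ = small_fit
    fit = ff.fit_model(trials, RWModelSpec(1, True), seed=4, **SMALL)
    lrs = extract_learning_rates(fit)
    assert np.allclose(lrs["lr_acq_plus"], lrs["lr_acq_minus"])


def test_compare_refuses_mismatched_data(small_fit, null_cohort):
    trials, fit = small_fit
    other_trials = null_cohort.trials[
        null_cohort.trials["subject_id"].isin(
            null_cohort.trials["subject_id"].unique()[8:16]
        )
    ]
    other = ff.fit_model(other_trials, RWModelSpec(1, False), seed=5, **SMALL)
    with pytest.raises(ValueError, match="identical observation"):
        compare_models([fit, other])
    with pytest.raises(ValueError, match="at least two"):
        compare_models([fit])


def test_identical_fits_have_zero_elpd_difference(small_fit):
    _, fit = small_fit
    res = compare_models([fit, fit], force=True)
    # self-comparison: any pairwise difference is exactly zero
    if len(res.pairwise):
        assert res.pairwise["elpd_diff"].abs().max() == 0.0


def test_posterior_contraction_with_cohort_size():
    """The group discrimination weight tightens as subjects are added."""
    sds = {}
    for n in (8, 32):
        coh = simulate_cohort(n, effects=CohortEffects.null(0.0), seed=51)
        fit = ff.fit_model(coh.trials, RWModelSpec(2, True), seed=6,
                           n_draws=150, gibbs_burn=400, gibbs_thin=3)
        g = fit.group_summary.set_index("parameter")
        sds[n] = float(g.loc["beta_discrimination", "sd"])
    assert sds[32] < sds[8]


def test_mcmc_reference_agrees_with_default_path():
    """Ensemble-sampler posterior agrees with the Gibbs path on a tiny cohort."""
    design = TaskDesign(n_acq_cs_plus=4, n_acq_cs_minus=4, n_acq_na=4,
                        n_ext_per_type=4)
    coh = simulate_cohort(4, design=design, effects=CohortEffects.null(0.0),
                          seed=9)
    gibbs = ff.fit_model(coh.trials, RWModelSpec(2, True), seed=3,
                         n_draws=300, gibbs_burn=600, gibbs_thin=3)
    mcmc = ff.fit_model(coh.trials, RWModelSpec(2, True), method="mcmc",
                        seed=3, n_draws=300, mcmc_steps=800, mcmc_burn=400)
    a = gibbs.group_summary.set_index("parameter")
    b = mcmc.group_summary.set_index("parameter")
    for param in ("beta_trial", "beta_discrimination", "beta_generalization"):
        tol = 2.5 * np.hypot(a.loc[param, "sd"], b.loc[param, "sd"])
        assert abs(a.loc[param, "mean"] - b.loc[param, "mean"]) < tol


def test_mismatched_trial_counts_rejected(null_cohort):
    trials = null_cohort.trials.copy()
    first = trials["subject_id"] == "S0001"
    broken = pd.concat([trials[~first], trials[first].iloc[:-3]])
    with pytest.raises(ValueError, match="equal trial counts"):
        ff.fit_model(broken, RWModelSpec(2, True), seed=1, **SMALL)


def test_priors_configurable():
    with pytest.raises(TypeError):
        PriorConfig(not_a_field=1.0)
    pc = PriorConfig(lr_mu_scale=2.0)
    assert pc.lr_mu_scale == 2.0
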