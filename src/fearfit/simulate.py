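"""Synthetic cohorts with the fear-conditioning task structure and known truth.

Every downstream stage of the package (scoring, derived metrics, exclusion
flow, model fitting, risk models) is exercised against cohorts produced
here, with ground-truth learning rates, observation-model coefficients and
group labels recorded per subject so recovery can be checked exactly.

The generator emulates a prospective deployment cohort: a small fraction of
subjects are destined to develop PTSD symptoms after deployment, and two
effects can be planted with known size:

* a *cue-discrimination deficit* in the PTSD group, implemented by shrinking
  the stimulus-specific expectation toward the shared generalization
  expectation by a multiplier ``disc_attenuation`` in the startle-generating
  model (overgeneralization: physiological responding discriminates less
  between threat and safety cues, while expectancy keypresses — generated
  from the un-attenuated expectations — still discriminate);
* a negative dependence of post-deployment symptom severity (CAPS) on the
  individual's extinction learning rate, with slope ``severity_slope``.

Startle magnitudes come from the package's own observation model: a linear
function of RW expectations on a habituating baseline plus Gaussian noise.
Questionnaire scores are truncated to instrument ranges; only the post-
deployment CAPS score carries a planted dependence on model parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .rw import (
    CSM,
    CSP,
    NA,
    STAB,
    GroupParams,
    RWModelSpec,
    SubjectParams,
    forward_expectations,
)
from .task import TaskDesign, simulate_trial_sequence

__all__ = [
    "PopulationTruth",
    "CohortEffects",
    "Cohort",
    "simulate_startle",
    "simulate_expectancy",
    "simulate_cohort",
    "read_trials",
    "read_subjects",
    "TRIAL_COLUMNS",
    "TRUTH_COLUMNS",
]

GROUP_HEALTHY = "healthy"
GROUP_PTSD = "ptsd"
GROUP_COMORBID = "comorbid_ptsd"
GROUP_DEPANX = "dep_anx_alone"


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class PopulationTruth:
    """Population-level ground truth for the generative model.

    Learning rates are drawn per subject as logit-normals centred on the
    stated means; the acquisition US+ rate is faster than the US- rate,
    matching the asymmetric-update pattern typical of fear acquisition.
    Startle units are arbitrary; the default intercept (100) and noise SD
    (30) put simulated magnitudes on the scale of typical adjusted startle
    tables, and the discrimination / generalization weights (150 / 100) put
    late-acquisition adjusted CS+ responses near 200 and CS- near 100.
    """

    mu_lr_acq_plus: float = 0.25
    mu_lr_acq_minus: float = 0.12
    mu_lr_ext: float = 0.15
    sd_logit_lr: float = 0.5
    intercept_mean: float = 100.0
    intercept_sd: float = 20.0
    beta_trial: float = -0.6
    beta_discrimination: float = 150.0
    beta_generalization: float = 100.0
    obs_sd: float = 30.0
    e0: float = 0.5

    def group_params(self, spec: RWModelSpec) -> GroupParams:
        """Observation-model coefficients appropriate for ``spec``."""
        bg = self.beta_generalization if spec.generalization else 0.0
        return GroupParams(
            beta_trial=self.beta_trial,
            beta_discrimination=self.beta_discrimination,
            beta_generalization=bg,
            obs_sd=self.obs_sd,
        )

    def draw_subject_params(
        self, rng: np.random.Generator
    ) -> SubjectParams:
        lrs = {}
        for name, mu in (
            ("lr_acq_plus", self.mu_lr_acq_plus),
            ("lr_acq_minus", self.mu_lr_acq_minus),
            ("lr_ext", self.mu_lr_ext),
        ):
            z = rng.normal(_logit(mu), self.sd_logit_lr)
            lrs[name] = float(np.clip(_expit(np.array(z)), 1e-4, 1 - 1e-4))
        return SubjectParams(
            beta_intercept=float(
                rng.normal(self.intercept_mean, self.intercept_sd)
            ),
            **lrs,
        )


@dataclass(frozen=True)
class CohortEffects:
    """Planted group structure and nuisance processes.

    ``disc_attenuation`` multiplies the PTSD group's deviation of the
    stimulus-specific expectation from the shared expectation (1.0 = no
    deficit, 0.0 = complete overgeneralization).  ``severity_slope`` is in
    CAPS units per unit extinction learning rate (negative: slower
    extinguishers end up more symptomatic).  ``nonlearner_rate`` plants
    subjects whose startle carries no cue-driven component at all; about
    half of them end up failing the potentiation gate (their NA-adjusted
    CS+ response is symmetric noise around zero).
    """

    prevalence: float = 0.05
    comorbid_rate: float = 0.02
    depanx_rate: float = 0.03
    pre_positive_rate: float = 0.13
    followup_loss_rate: float = 0.0
    nonlearner_rate: float = 0.10
    disc_attenuation: float = 0.4
    severity_slope: float = -40.0
    caps_pre_shift: float = 6.0
    drri_shift: float = 8.0
    artifact_rate: float = 0.021
    expectancy_missing_rate: float = 0.02
    caps_noise_sd: float = 8.0

    @classmethod
    def null(cls, prevalence: float = 0.05) -> "CohortEffects":
        """All planted effects and nuisance processes switched off."""
        return cls(
            prevalence=prevalence,
            comorbid_rate=0.0,
            depanx_rate=0.0,
            pre_positive_rate=0.0,
            followup_loss_rate=0.0,
            nonlearner_rate=0.0,
            disc_attenuation=1.0,
            severity_slope=0.0,
            caps_pre_shift=0.0,
            drri_shift=0.0,
            artifact_rate=0.0,
            expectancy_missing_rate=0.0,
        )


TRIAL_COLUMNS = [
    "subject_id",
    "phase",
    "trial_index",
    "stimulus",
    "us",
    "startle",
    "artifact_flag",
    "imputed_flag",
    "expectancy",
    "peak_latency_ms",
]

TRUTH_COLUMNS = [
    "true_group",
    "true_pre_positive",
    "true_nonlearner",
    "true_disc_blend",
    "true_lr_acq_plus",
    "true_lr_acq_minus",
    "true_lr_ext",
    "true_beta_intercept",
]

_QUESTIONNAIRE_COLUMNS = [
    "caps_pre",
    "caps_post",
    "caps_b_pre",
    "caps_c_pre",
    "caps_d_pre",
    "caps_b_post",
    "caps_c_post",
    "caps_d_post",
    "bai_pre",
    "bai_post",
    "bdi2_pre",
    "bdi2_post",
    "lec",
    "ctq",
    "drri_postbattle",
    "drri_combat",
    "drri_concerns",
    "drri_environment",
    "prior_deployment",
    "followup_lost",
]


@dataclass
class Cohort:
    """Simulated cohort: long trial table + one-row-per-subject table."""

    trials: pd.DataFrame
    subjects: pd.DataFrame
    design: TaskDesign
    population: PopulationTruth
    effects: CohortEffects
    model: RWModelSpec
    seed: int

    def to_csv(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "trials": out / "trials.csv",
            "subjects": out / "subjects.csv",
        }
        self.trials.to_csv(paths["trials"], index=False)
        self.subjects.to_csv(paths["subjects"], index=False)
        return paths


def simulate_startle(
    trials: pd.DataFrame,
    subject_params: SubjectParams,
    group_params: GroupParams,
    spec: RWModelSpec,
    seed: int,
    disc_blend: float = 1.0,
    cue_gain: float = 1.0,
    e0: float = 0.5,
) -> pd.DataFrame:
    """Attach simulated startle magnitudes to one subject's trial stubs.

    The noise-free mean is the package's observation model; ``disc_blend``
    shrinks the stimulus-specific expectation toward the shared one (toward
    ``e0`` under discrimination-only specs) to plant overgeneralization, and
    ``cue_gain`` scales the whole cue-driven component (0 for planted
    non-learners).  Stabilization pulses get baseline-only responses and do
    not advance the habituation clock.
    """
    group_params.validate_for(spec)
    rng = np.random.default_rng(seed)
    out = trials.copy()

    fw = forward_expectations(trials, subject_params, spec, e0=e0)
    is_cs = fw["stimulus"].isin([CSP, CSM]).to_numpy()
    e_disc = fw["e_disc"].to_numpy()
    e_gen = fw["e_gen"].to_numpy()
    ref = e_gen if spec.generalization else np.where(is_cs, e0, 0.0)
    e_disc_eff = np.where(is_cs, ref + disc_blend * (e_disc - ref), 0.0)

    cue = group_params.beta_discrimination * e_disc_eff
    if spec.generalization:
        cue = cue + group_params.beta_generalization * e_gen
    mean_modeled = (
        subject_params.beta_intercept
        + group_params.beta_trial * fw["t"].to_numpy(dtype=float)
        + cue_gain * cue
    )

    mean = np.full(len(out), subject_params.beta_intercept, dtype=float)
    mean[(out["stimulus"] != STAB).to_numpy()] = mean_modeled
    noise = rng.normal(0.0, group_params.obs_sd, size=len(out))
    out["startle"] = mean + noise
    return out


def simulate_expectancy(
    trials: pd.DataFrame,
    subject_params: SubjectParams,
    spec: RWModelSpec,
    seed: int,
    missing_rate: float = 0.0,
    e0: float = 0.5,
) -> pd.DataFrame:
    """Attach 3-level US-expectancy keypresses (-1 / 0 / +1) to CS trials.

    A latent judgment (the subject's un-attenuated stimulus-specific
    expectation plus N(0, 0.25) noise) is thresholded: above 0.75 the
    subject reports expecting the air puff (+1), below 0.40 not expecting
    it (-1), in between unsure (0).  The thresholds are calibrated so that a
    typical learner averages roughly +0.6 for CS+ and -0.75 for CS- over
    late acquisition.  NA and stabilization trials have no keypress.
    """
    rng = np.random.default_rng(seed)
    out = trials.copy()
    fw = forward_expectations(trials, subject_params, spec, e0=e0)
    is_cs = fw["stimulus"].isin([CSP, CSM]).to_numpy()
    latent = fw["e_disc"].to_numpy() + rng.normal(0.0, 0.25, size=len(fw))
    resp = np.where(latent > 0.75, 1.0, np.where(latent < 0.40, -1.0, 0.0))
    if missing_rate > 0:
        resp = np.where(
            rng.random(len(fw)) < missing_rate, np.nan, resp
        )
    expectancy = np.full(len(out), np.nan)
    expectancy[(out["stimulus"] != STAB).to_numpy()] = np.where(
        is_cs, resp, np.nan
    )
    out["expectancy"] = expectancy
    return out


def _draw_bcd_meeting(rng: np.random.Generator) -> tuple[int, int, int]:
    b = 1 + int(min(rng.poisson(0.8), 4))
    c = 2 + int(min(rng.poisson(1.2), 5))
    d = 2 + int(min(rng.poisson(1.0), 3))
    return b, c, d


def _draw_bcd_subthreshold(rng: np.random.Generator) -> tuple[int, int, int]:
    b = int(min(rng.poisson(0.4), 5))
    c = int(min(rng.poisson(0.8), 7))
    d = int(min(rng.poisson(0.8), 5))
    if b >= 1 and c >= 2 and d >= 2:
        c = 1  # keep below the symptom-cluster criteria
    return b, c, d


def _questionnaires(
    rng: np.random.Generator,
    group: str,
    pre_positive: bool,
    lr_ext: float,
    population: PopulationTruth,
    effects: CohortEffects,
) -> dict[str, float]:
    """One subject's questionnaire panel, consistent with the planted label."""
    q: dict[str, float] = {}

    # Pre-deployment symptom screen.
    if pre_positive:
        mode = rng.integers(3)
        b, c, d = (
            _draw_bcd_meeting(rng) if mode == 0 else _draw_bcd_subthreshold(rng)
        )
        q["bai_pre"] = 16 + int(rng.poisson(4)) if mode == 1 else int(
            min(rng.poisson(4), 15)
        )
        q["bdi2_pre"] = 20 + int(rng.poisson(4)) if mode == 2 else int(
            min(rng.poisson(5), 19)
        )
    else:
        b, c, d = _draw_bcd_subthreshold(rng)
        q["bai_pre"] = int(min(rng.poisson(4), 15))
        q["bdi2_pre"] = int(min(rng.poisson(5), 19))
    q["caps_b_pre"], q["caps_c_pre"], q["caps_d_pre"] = b, c, d

    # Post-deployment cluster counts and comorbidity flags.
    meets_post = group in (GROUP_PTSD, GROUP_COMORBID)
    b, c, d = (
        _draw_bcd_meeting(rng) if meets_post else _draw_bcd_subthreshold(rng)
    )
    q["caps_b_post"], q["caps_c_post"], q["caps_d_post"] = b, c, d
    q["bai_post"] = int(min(rng.poisson(4), 15))
    q["bdi2_post"] = int(min(rng.poisson(5), 19))
    if group == GROUP_COMORBID:
        if rng.random() < 0.5:
            q["bdi2_post"] = 20 + int(rng.poisson(5))
        else:
            q["bai_post"] = 16 + int(rng.poisson(5))
    elif group == GROUP_DEPANX:
        if rng.random() < 0.5:
            q["bdi2_post"] = 20 + int(rng.poisson(5))
        else:
            q["bai_post"] = 16 + int(rng.poisson(5))

    # CAPS severity; only caps_post depends on model parameters.
    pre_base = 10.0 + (
        effects.caps_pre_shift if group in (GROUP_PTSD, GROUP_COMORBID) else 0.0
    )
    q["caps_pre"] = float(
        np.clip(round(rng.normal(pre_base, 6.0)), 0, 136)
    )
    post_base = {
        GROUP_HEALTHY: 20.0,
        GROUP_PTSD: 45.0,
        GROUP_COMORBID: 50.0,
        GROUP_DEPANX: 25.0,
    }[group]
    caps_post = (
        post_base
        + effects.severity_slope * (lr_ext - population.mu_lr_ext)
        + rng.normal(0.0, effects.caps_noise_sd)
    )
    q["caps_post"] = float(np.clip(round(caps_post), 0, 136))

    # Trauma history and deployment stress.
    q["lec"] = int(min(rng.poisson(4), 17))
    q["ctq"] = float(np.clip(round(rng.normal(35.0, 8.0)), 25, 170))
    shift = effects.drri_shift if group in (GROUP_PTSD, GROUP_COMORBID) else 0.0
    for sub in ("drri_postbattle", "drri_combat", "drri_concerns",
                "drri_environment"):
        q[sub] = float(round(rng.normal(45.0 + shift, 10.0), 1))
    q["prior_deployment"] = int(rng.random() < 0.35)
    q["followup_lost"] = int(rng.random() < effects.followup_loss_rate)
    return q


def simulate_cohort(
    n_subjects: int,
    design: TaskDesign | None = None,
    effects: CohortEffects | None = None,
    population: PopulationTruth | None = None,
    model: RWModelSpec | None = None,
    seed: int = 0,
) -> Cohort:
    """Generate a full synthetic cohort.

    Group labels are drawn at the configured prevalence (with optional
    comorbid and depression/anxiety-alone strata), per-subject learning
    rates and intercepts from the population truth, trial sequences from the
    task design, and startle from the observation model under ``model``
    (two-rate discrimination + generalization by default).  Artifact flags
    are planted at ``effects.artifact_rate`` with the affected magnitudes
    corrupted by a large positive spike, so imputation is consequential.
    """
    if n_subjects < 2:
        raise ValueError(f"n_subjects must be >= 2, got {n_subjects}")
    design = design or TaskDesign()
    effects = effects or CohortEffects()
    population = population or PopulationTruth()
    model = model or RWModelSpec(2, True)
    group_params = population.group_params(model)

    p_rest = 1.0 - effects.prevalence - effects.comorbid_rate - effects.depanx_rate
    if p_rest < 0:
        raise ValueError("group rates sum to more than 1")
    if effects.prevalence > 0 and n_subjects * effects.prevalence < 1:
        import warnings

        warnings.warn(
            "configured prevalence yields < 1 expected case at this n",
            stacklevel=2,
        )

    root = np.random.SeedSequence(seed)
    subject_seeds = root.spawn(n_subjects)

    trial_frames = []
    subject_rows = []
    for j in range(n_subjects):
        rng = np.random.default_rng(subject_seeds[j])
        sid = f"S{j + 1:04d}"

        group = rng.choice(
            [GROUP_PTSD, GROUP_COMORBID, GROUP_DEPANX, GROUP_HEALTHY],
            p=[
                effects.prevalence,
                effects.comorbid_rate,
                effects.depanx_rate,
                p_rest,
            ],
        )
        pre_positive = bool(rng.random() < effects.pre_positive_rate)
        nonlearner = bool(rng.random() < effects.nonlearner_rate)
        params = population.draw_subject_params(rng)
        blend = (
            effects.disc_attenuation if group == GROUP_PTSD else 1.0
        )
        cue_gain = 0.0 if nonlearner else 1.0

        sub_seeds = rng.integers(0, 2**31 - 1, size=4)
        trials = simulate_trial_sequence(design, int(sub_seeds[0]))
        trials = simulate_startle(
            trials,
            params,
            group_params,
            model,
            int(sub_seeds[1]),
            disc_blend=blend,
            cue_gain=cue_gain,
            e0=population.e0,
        )
        trials = simulate_expectancy(
            trials,
            params,
            model,
            int(sub_seeds[2]),
            missing_rate=effects.expectancy_missing_rate,
            e0=population.e0,
        )

        # Plant artifacts on modeled trials; corrupt the magnitude so that
        # neighbor imputation visibly matters.
        art_rng = np.random.default_rng(int(sub_seeds[3]))
        modeled = (trials["stimulus"] != STAB).to_numpy()
        flags = np.zeros(len(trials), dtype=bool)
        if effects.artifact_rate > 0:
            flags[modeled] = art_rng.random(modeled.sum()) < effects.artifact_rate
        trials["artifact_flag"] = flags
        spikes = art_rng.uniform(150.0, 500.0, size=len(trials))
        trials.loc[flags, "startle"] = (
            trials.loc[flags, "startle"] + spikes[flags]
        )
        trials["imputed_flag"] = False
        trials["peak_latency_ms"] = np.round(
            np.clip(art_rng.normal(55.0, 15.0, size=len(trials)), 5.0, 95.0), 1
        )
        trials.insert(0, "subject_id", sid)
        trial_frames.append(trials[TRIAL_COLUMNS])

        row = {"subject_id": sid}
        row.update(
            _questionnaires(
                rng, str(group), pre_positive, params.lr_ext, population, effects
            )
        )
        row.update(
            {
                "true_group": str(group),
                "true_pre_positive": int(pre_positive),
                "true_nonlearner": int(nonlearner),
                "true_disc_blend": blend,
                "true_lr_acq_plus": params.lr_acq_plus,
                "true_lr_acq_minus": params.lr_acq_minus,
                "true_lr_ext": params.lr_ext,
                "true_beta_intercept": params.beta_intercept,
            }
        )
        subject_rows.append(row)

    trials_df = pd.concat(trial_frames, ignore_index=True)
    subjects_df = pd.DataFrame(subject_rows)
    return Cohort(
        trials=trials_df,
        subjects=subjects_df,
        design=design,
        population=population,
        effects=effects,
        model=model,
        seed=seed,
    )


def _check_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing required column(s): {missing}")


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read a long-format trial CSV, validating the schema."""
    df = pd.read_csv(path)
    _check_columns(
        df,
        ["subject_id", "phase", "trial_index", "stimulus", "us", "startle"],
        f"trial table {path}",
    )
    for col, default in (("artifact_flag", False), ("imputed_flag", False)):
        if col not in df.columns:
            df[col] = default
        else:
            df[col] = df[col].astype(bool)
    return df


def read_subjects(path: str | Path) -> pd.DataFrame:
    """Read a one-row-per-subject CSV, validating the schema."""
    df = pd.read_csv(path)
    _check_columns(df, ["subject_id"], f"subject table {path}")
    return df
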