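"""Rescorla-Wagner expectation engines and the startle observation model.

Four model variants are used throughout the package, crossing two factors:
one vs. two acquisition learning rates (separate rates for reinforced, US+,
and non-reinforced, US-, trials), and the presence of a generalization
learning process alongside the stimulus-specific discrimination process.

* M1 - one acquisition learning rate, discrimination only
* M2 - one acquisition learning rate, discrimination + generalization
* M3 - two acquisition learning rates, discrimination only
* M4 - two acquisition learning rates, discrimination + generalization

US expectations live on [0, 1] and are updated by the delta rule
``E <- (1 - lr) * E + lr * us``.  The discrimination process keeps one
expectation per conditioned stimulus and updates only the stimulus shown on
a trial; the generalization process keeps a single shared expectation
updated on every CS trial regardless of identity (updating both stimuli
identically from a common start collapses to one shared value).  Noise-alone
(NA) trials carry no cue, trigger no update, and contribute no expectation
term to the predicted startle.

Predicted startle is linear in the expectations on top of a habituating
baseline::

    mean(t) = beta_intercept + beta_trial * t
              + beta_discrimination * E_disc(shown CS)
              + beta_generalization * E_gen

with t a 0-based trial counter running continuously over the modeled session
(NA trials included, stabilization pulses excluded), and observed startle
Gaussian around the mean with homogeneous ``obs_sd``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "CSP",
    "CSM",
    "NA",
    "STAB",
    "PHASE_ACQ",
    "PHASE_EXT",
    "MODELED_STIMULI",
    "RWModelSpec",
    "SubjectParams",
    "GroupParams",
    "rw_update",
    "forward_expectations",
    "predicted_startle",
    "log_likelihood",
]

CSP = "CSP"
CSM = "CSM"
NA = "NA"
STAB = "STAB"

PHASE_ACQ = "acquisition"
PHASE_EXT = "extinction"

MODELED_STIMULI = (CSP, CSM, NA)

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class RWModelSpec:
    """Which of the four model variants to use.

    Parameters
    ----------
    n_acq_lrs:
        1 for a single acquisition learning rate, 2 for separate US+ / US-
        rates.
    generalization:
        Whether the shared generalization expectation enters the observation
        model (with its own group-level weight).
    """

    n_acq_lrs: int = 2
    generalization: bool = True

    def __post_init__(self) -> None:
        if self.n_acq_lrs not in (1, 2):
            raise ValueError(f"n_acq_lrs must be 1 or 2, got {self.n_acq_lrs}")

    @property
    def id(self) -> str:
        return {
            (1, False): "M1",
            (1, True): "M2",
            (2, False): "M3",
            (2, True): "M4",
        }[(self.n_acq_lrs, self.generalization)]

    @classmethod
    def from_id(cls, model_id: str) -> "RWModelSpec":
        table = {
            "M1": cls(1, False),
            "M2": cls(1, True),
            "M3": cls(2, False),
            "M4": cls(2, True),
        }
        try:
            return table[model_id.upper()]
        except KeyError:
            raise ValueError(
                f"unknown model id {model_id!r}; expected one of M1..M4"
            ) from None


@dataclass(frozen=True)
class SubjectParams:
    """Individual-level parameters: three learning rates and an intercept.

    ``lr_acq_minus`` is ignored (treated as equal to ``lr_acq_plus``) under a
    one-learning-rate model spec.  All learning rates must lie in the open
    interval (0, 1); the intercept is in startle units.
    """

    lr_acq_plus: float
    lr_acq_minus: float
    lr_ext: float
    beta_intercept: float

    def __post_init__(self) -> None:
        for name in ("lr_acq_plus", "lr_acq_minus", "lr_ext"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1), got {v}")

    def resolved(self, spec: RWModelSpec) -> "SubjectParams":
        """Collapse the US- rate onto the US+ rate under one-LR specs."""
        if spec.n_acq_lrs == 1 and self.lr_acq_minus != self.lr_acq_plus:
            return replace(self, lr_acq_minus=self.lr_acq_plus)
        return self


@dataclass(frozen=True)
class GroupParams:
    """Group-level observation-model parameters (startle units)."""

    beta_trial: float
    beta_discrimination: float
    beta_generalization: float
    obs_sd: float

    def __post_init__(self) -> None:
        if self.obs_sd <= 0:
            raise ValueError(f"obs_sd must be > 0, got {self.obs_sd}")

    def validate_for(self, spec: RWModelSpec) -> None:
        if not spec.generalization and self.beta_generalization != 0.0:
            raise ValueError(
                "beta_generalization must be 0 under a discrimination-only "
                f"model spec ({spec.id}); got {self.beta_generalization}"
            )


def rw_update(expectation: float, lr: float, us: int) -> float:
    """One delta-rule step: ``(1 - lr) * E + lr * us``."""
    return (1.0 - lr) * expectation + lr * us


def _check_modeled_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Select and order-check the modeled (non-stabilization) trials."""
    required = {"phase", "trial_index", "stimulus", "us"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    t = trials[trials["stimulus"] != STAB]
    phases = t["phase"].to_numpy()
    phase_rank = np.where(phases == PHASE_ACQ, 0, 1)
    if not np.all(np.diff(phase_rank) >= 0):
        raise ValueError("trials not ordered: extinction precedes acquisition")
    for ph in (PHASE_ACQ, PHASE_EXT):
        idx = t.loc[t["phase"] == ph, "trial_index"].to_numpy()
        if idx.size and not np.all(np.diff(idx) > 0):
            raise ValueError(f"trials not ordered within phase {ph!r}")
    return t


def forward_expectations(
    trials: pd.DataFrame,
    params: SubjectParams,
    spec: RWModelSpec,
    e0: float = 0.5,
) -> pd.DataFrame:
    """Propagate RW expectations over one subject's ordered trial sequence.

    Returns a copy of the modeled trials with columns ``e_disc`` (the
    pre-update discrimination expectation of the stimulus shown; 0.0 on NA
    trials, which carry no cue) and ``e_gen`` (the pre-update shared
    generalization expectation; 0.0 on NA trials), plus ``t``, the 0-based
    running trial counter used by the habituation term.

    Expectations start at ``e0`` and are carried across the acquisition /
    extinction boundary.  During acquisition the update uses ``lr_acq_plus``
    on reinforced and ``lr_acq_minus`` on non-reinforced CS trials (the two
    collapse under a one-LR spec); every extinction CS trial updates with
    ``lr_ext`` toward us = 0.  The generalization expectation is updated on
    every CS trial with the same outcome and learning rate as the
    discrimination update of the shown stimulus.
    """
    params = params.resolved(spec)
    t = _check_modeled_trials(trials).copy()

    e_disc_state = {CSP: float(e0), CSM: float(e0)}
    e_gen = float(e0)

    n = len(t)
    e_disc_out = np.zeros(n)
    e_gen_out = np.zeros(n)

    for i, (phase, stim, us) in enumerate(
        zip(t["phase"].to_numpy(), t["stimulus"].to_numpy(), t["us"].to_numpy())
    ):
        if stim == NA:
            continue
        if stim not in (CSP, CSM):
            raise ValueError(f"unknown stimulus code {stim!r}")
        e_disc_out[i] = e_disc_state[stim]
        e_gen_out[i] = e_gen
        if phase == PHASE_EXT:
            lr = params.lr_ext
        else:
            lr = params.lr_acq_plus if us == 1 else params.lr_acq_minus
        e_disc_state[stim] = rw_update(e_disc_state[stim], lr, int(us))
        e_gen = rw_update(e_gen, lr, int(us))

    t["e_disc"] = e_disc_out
    t["e_gen"] = e_gen_out
    t["t"] = np.arange(n)
    return t


def predicted_startle(
    trials: pd.DataFrame,
    subject_params: SubjectParams,
    group_params: GroupParams,
    spec: RWModelSpec,
    e0: float = 0.5,
) -> np.ndarray:
    """Per-trial predicted mean startle for one subject's modeled trials."""
    group_params.validate_for(spec)
    fw = forward_expectations(trials, subject_params, spec, e0=e0)
    mean = (
        subject_params.beta_intercept
        + group_params.beta_trial * fw["t"].to_numpy(dtype=float)
        + group_params.beta_discrimination * fw["e_disc"].to_numpy()
    )
    if spec.generalization:
        mean = mean + group_params.beta_generalization * fw["e_gen"].to_numpy()
    return np.asarray(mean, dtype=float)


def log_likelihood(
    trials: pd.DataFrame,
    subject_params: SubjectParams,
    group_params: GroupParams,
    spec: RWModelSpec,
    e0: float = 0.5,
) -> tuple[float, np.ndarray]:
    """Gaussian log-likelihood of observed startle under the model.

    Returns ``(total, per_trial)`` over the modeled trials; the per-trial
    vector is kept for pointwise leave-one-out comparison downstream.
    """
    if "startle" not in trials.columns:
        raise ValueError("trial table missing column: 'startle'")
    mean = predicted_startle(trials, subject_params, group_params, spec, e0=e0)
    y = trials.loc[trials["stimulus"] != STAB, "startle"].to_numpy(dtype=float)
    sd = group_params.obs_sd
    z = (y - mean) / sd
    per_trial = -0.5 * (_LOG_2PI + z * z) - np.log(sd)
    return float(per_trial.sum()), per_trial
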