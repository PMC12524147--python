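"""Trial-level QC of startle magnitudes.

Three steps, mirroring standard eyeblink-EMG scoring practice for this
task: (1) optional response-window validation — a response must peak within
100 ms of pulse onset to count, otherwise the trial is treated as artifact;
(2) neighbor-based imputation — an artifact trial's magnitude is replaced
by the mean of the nearest preceding and nearest subsequent clean trial of
the same stimulus type within the same phase (single-sided at sequence
edges); (3) artifact-rate reporting.

Imputation never deletes trials, only replaces magnitudes, so trial counts
are conserved; donors are always non-artifact trials, which makes the
operation idempotent.  A subject with a stimulus type that has no clean
trial left in a phase cannot be imputed and is flagged unusable, feeding
the cohort exclusion flow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rw import STAB

__all__ = [
    "RESPONSE_WINDOW_MS",
    "QCReport",
    "validate_response_window",
    "apply_response_window",
    "impute_artifacts",
    "artifact_rate",
]

logger = logging.getLogger(__name__)

# Closed acceptance window for the eyeblink peak, ms from pulse onset.
RESPONSE_WINDOW_MS = (0.0, 100.0)


@dataclass
class QCReport:
    """Summary of one QC pass over a cohort trial table."""

    n_trials: int = 0
    n_artifact: int = 0
    n_imputed: int = 0
    n_window_rejected: int = 0
    unusable_subjects: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_trials": self.n_trials,
            "n_artifact": self.n_artifact,
            "n_imputed": self.n_imputed,
            "n_window_rejected": self.n_window_rejected,
            "artifact_rate": (
                self.n_artifact / self.n_trials if self.n_trials else 0.0
            ),
            "unusable_subjects": list(self.unusable_subjects),
        }


def validate_response_window(
    peak_latency_ms: float, window: tuple[float, float] = RESPONSE_WINDOW_MS
) -> bool:
    """Accept a trial iff its peak latency falls in the closed window."""
    if peak_latency_ms is None or np.isnan(peak_latency_ms):
        raise ValueError("peak latency missing; cannot validate window")
    lo, hi = window
    return lo <= peak_latency_ms <= hi


def apply_response_window(
    trials: pd.DataFrame, window: tuple[float, float] = RESPONSE_WINDOW_MS
) -> pd.DataFrame:
    """Flag trials whose peak lies outside the response window as artifact.

    Trials with no recorded latency are skipped (with a log entry), not
    rejected.  Returns a copy with updated ``artifact_flag``.
    """
    out = trials.copy()
    if "peak_latency_ms" not in out.columns:
        logger.info("no peak_latency_ms column; window validation skipped")
        return out
    lat = pd.to_numeric(out["peak_latency_ms"], errors="coerce")
    missing = lat.isna()
    if missing.any():
        logger.info(
            "window validation skipped for %d trial(s) with missing latency",
            int(missing.sum()),
        )
    lo, hi = window
    rejected = (~missing) & ((lat < lo) | (lat > hi))
    out["artifact_flag"] = out["artifact_flag"].to_numpy(dtype=bool) | (
        rejected.to_numpy()
    )
    return out


def _impute_one_group(startle: np.ndarray, artifact: np.ndarray) -> np.ndarray:
    """Impute within one (subject, phase, stimulus) presentation-order run.

    Each flagged position takes the mean of the nearest preceding and
    nearest subsequent clean value; a single-sided neighbor is used at
    edges.  Runs of consecutive artifacts all resolve to clean donors,
    never to each other.
    """
    clean_idx = np.flatnonzero(~artifact)
    out = startle.astype(float).copy()
    for i in np.flatnonzero(artifact):
        before = clean_idx[clean_idx < i]
        after = clean_idx[clean_idx > i]
        donors = []
        if before.size:
            donors.append(startle[before[-1]])
        if after.size:
            donors.append(startle[after[0]])
        out[i] = float(np.mean(donors))
    return out


def impute_artifacts(trials: pd.DataFrame) -> tuple[pd.DataFrame, QCReport]:
    """Neighbor-impute artifact-flagged startle magnitudes, cohort-wide.

    Trials must be ordered by subject, phase, then trial index.  Returns a
    copy with artifact magnitudes replaced and ``imputed_flag`` set, plus a
    :class:`QCReport`.  Subjects with any (phase, stimulus) cell that has no
    clean trial are listed as unusable and left un-imputed there.
    Stabilization pulses are ignored.
    """
    out = trials.copy()
    report = QCReport()
    modeled = out["stimulus"] != STAB
    report.n_trials = int(modeled.sum())
    report.n_artifact = int(
        (out.loc[modeled, "artifact_flag"]).to_numpy(dtype=bool).sum()
    )

    unusable: set[str] = set()
    grouped = out[modeled].groupby(
        ["subject_id", "phase", "stimulus"], sort=False
    )
    for (sid, _phase, _stim), grp in grouped:
        art = grp["artifact_flag"].to_numpy(dtype=bool)
        if not art.any():
            continue
        if art.all():
            unusable.add(str(sid))
            continue
        imputed = _impute_one_group(grp["startle"].to_numpy(dtype=float), art)
        idx = grp.index[art]
        out.loc[idx, "startle"] = imputed[art]
        out.loc[idx, "imputed_flag"] = True
        report.n_imputed += int(art.sum())

    report.unusable_subjects = sorted(unusable)
    return out, report


def artifact_rate(trials: pd.DataFrame) -> tuple[float, pd.Series]:
    """Proportion of artifact-flagged CS and NA trials, overall and per subject."""
    modeled = trials[trials["stimulus"] != STAB]
    if modeled.empty:
        raise ValueError("no modeled trials in cohort")
    flags = modeled["artifact_flag"].to_numpy(dtype=bool)
    per_subject = modeled.assign(flag=flags).groupby("subject_id")["flag"].mean()
    return float(flags.mean()), per_subject
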