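"""Derived fear-learning measures from scored startle trials.

The measures follow the standard analysis of this differential-conditioning
startle task:

* trials are averaged per stimulus into *blocks of two* in presentation
  order, and within each block the noise-alone (NA) mean is subtracted from
  the CS+ and CS- means to adjust for drifting baseline startle;
* *cue discrimination index* = mean adjusted CS+ minus mean adjusted CS-
  over the last half of acquisition (blocks 3-4 of 4 under the default
  design) — low values mean poor threat/safety discrimination;
* *% conditioned fear* for each extinction block =
  ``100 * adjusted CS+ / (subject's maximum adjusted CS+ across acquisition
  blocks)``, then averaged into 4-trial blocks (Early / Mid1 / Mid2 / Late
  under the default 8-block extinction).  Values are not clipped: negative
  and >100 percentages propagate as the formula produces them;
* subjects whose last-half-acquisition adjusted CS+ mean is not strictly
  positive are *non-potentiators* (the air puff failed to induce measurable
  fear) and are routed to exclusion;
* expectancy keypresses (+1 expect / 0 unsure / -1 do not expect) are
  averaged over the last half of acquisition per stimulus and over 4-trial
  CS+ blocks in extinction, missing responses excluded from denominators.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .rw import CSM, CSP, NA, PHASE_ACQ, PHASE_EXT, STAB

__all__ = [
    "block_and_adjust",
    "percent_conditioned_fear",
    "nonpotentiator_filter",
    "expectancy_summaries",
    "subject_metrics",
    "NAMED_EXT_BLOCKS",
]

NAMED_EXT_BLOCKS = ("early", "mid1", "mid2", "late")


def block_and_adjust(trials: pd.DataFrame, phase: str) -> pd.DataFrame:
    """Two-trial block means per stimulus with NA subtraction, per subject.

    Returns a long DataFrame with columns ``subject_id``, ``phase``,
    ``stimulus``, ``block`` (1-based), ``block_mean`` and ``adjusted``
    (CS rows only; NA rows carry NaN).  Trials are paired in presentation
    order within each stimulus.  Odd trial counts or CS/NA block-count
    mismatches raise, naming the subject, phase and stimulus.
    """
    sel = trials[(trials["phase"] == phase) & (trials["stimulus"] != STAB)]
    if sel.empty:
        raise ValueError(f"no trials in phase {phase!r}")

    rows = []
    for sid, sub in sel.groupby("subject_id", sort=False):
        means: dict[str, np.ndarray] = {}
        for stim in (CSP, CSM, NA):
            vals = (
                sub[sub["stimulus"] == stim]
                .sort_values("trial_index")["startle"]
                .to_numpy(dtype=float)
            )
            if vals.size % 2 != 0:
                raise ValueError(
                    f"odd trial count for subject {sid}, phase {phase}, "
                    f"stimulus {stim}: {vals.size}"
                )
            means[stim] = vals.reshape(-1, 2).mean(axis=1)
        n_blocks = {s: m.size for s, m in means.items()}
        if len(set(n_blocks.values())) != 1:
            raise ValueError(
                f"block count mismatch for subject {sid}, phase {phase}: "
                f"{n_blocks}"
            )
        for stim in (CSP, CSM, NA):
            for b, m in enumerate(means[stim], start=1):
                adjusted = (
                    m - means[NA][b - 1] if stim in (CSP, CSM) else np.nan
                )
                rows.append((sid, phase, stim, b, m, adjusted))
    return pd.DataFrame(
        rows,
        columns=["subject_id", "phase", "stimulus", "block", "block_mean",
                 "adjusted"],
    )


def _last_half_mean(values: np.ndarray) -> float:
    return float(values[values.size // 2:].mean())


def percent_conditioned_fear(
    acq_csp_adjusted: np.ndarray, ext_csp_adjusted: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """% conditioned fear per extinction block, plus 4-trial block means.

    ``100 * adjusted extinction CS+ / max adjusted acquisition CS+``; the
    named 4-trial blocks are means of consecutive pairs of the 2-trial
    blocks.  A non-positive acquisition maximum leaves the measure
    undefined (all NaN) — such subjects are non-potentiators and belong in
    the exclusion flow.
    """
    acq_max = float(np.max(acq_csp_adjusted))
    if acq_max <= 0:
        n = ext_csp_adjusted.size
        return np.full(n, np.nan), np.full(n // 2, np.nan)
    pct = 100.0 * np.asarray(ext_csp_adjusted, dtype=float) / acq_max
    named = pct.reshape(-1, 2).mean(axis=1)
    return pct, named


def nonpotentiator_filter(
    acq_csp_adjusted: np.ndarray, tol: float = 0.0
) -> bool:
    """True (potentiator) iff the last-half adjusted CS+ mean exceeds ``tol``.

    The default strict ``> 0`` reads "CS+ response greater than baseline"
    literally on the NA-subtracted scale.
    """
    return _last_half_mean(np.asarray(acq_csp_adjusted, dtype=float)) > tol


def expectancy_summaries(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-subject expectancy means: acquisition last half and extinction blocks.

    Acquisition: mean keypress over the last half of CS+ and CS- trials
    (4 of 8 under the default design).  Extinction: CS+ means per 4-trial
    block.  Missing keypresses are dropped from denominators; the counts
    actually averaged are reported alongside.
    """
    sel = trials[trials["stimulus"].isin([CSP, CSM])]
    if "expectancy" not in sel.columns:
        sel = sel.assign(expectancy=np.nan)
    rows = []
    for sid, sub in sel.groupby("subject_id", sort=False):
        row: dict[str, float] = {"subject_id": sid}
        for stim, key in ((CSP, "csp"), (CSM, "csm")):
            vals = (
                sub[(sub["phase"] == PHASE_ACQ) & (sub["stimulus"] == stim)]
                .sort_values("trial_index")["expectancy"]
                .to_numpy(dtype=float)
            )
            last = vals[vals.size // 2:]
            ok = ~np.isnan(last)
            row[f"exp_acq_{key}_lasthalf"] = (
                float(last[ok].mean()) if ok.any() else np.nan
            )
            row[f"exp_acq_{key}_n"] = int(ok.sum())
        ext = (
            sub[(sub["phase"] == PHASE_EXT) & (sub["stimulus"] == CSP)]
            .sort_values("trial_index")["expectancy"]
            .to_numpy(dtype=float)
        )
        n_blocks = ext.size // 4
        for b in range(n_blocks):
            chunk = ext[4 * b: 4 * (b + 1)]
            ok = ~np.isnan(chunk)
            row[f"exp_ext_csp_b{b + 1}"] = (
                float(chunk[ok].mean()) if ok.any() else np.nan
            )
            row[f"exp_ext_csp_b{b + 1}_n"] = int(ok.sum())
        rows.append(row)
    return pd.DataFrame(rows)


def subject_metrics(
    trials: pd.DataFrame,
    extinction_metric: str = "percent",
    potentiator_tol: float = 0.0,
) -> pd.DataFrame:
    """All derived per-subject measures in one row per subject.

    ``extinction_metric="percent"`` (default) reports % conditioned fear;
    ``"difference"`` reports the raw NA-adjusted CS+ block values instead
    (robustness alternative).  Expects artifacts to be imputed already.
    """
    if extinction_metric not in ("percent", "difference"):
        raise ValueError(
            f"extinction_metric must be 'percent' or 'difference', got "
            f"{extinction_metric!r}"
        )
    acq = block_and_adjust(trials, PHASE_ACQ)
    ext = block_and_adjust(trials, PHASE_EXT)
    exp = expectancy_summaries(trials)

    rows = []
    for sid in trials["subject_id"].drop_duplicates():
        a_csp = (
            acq[(acq["subject_id"] == sid) & (acq["stimulus"] == CSP)]
            .sort_values("block")["adjusted"]
            .to_numpy()
        )
        a_csm = (
            acq[(acq["subject_id"] == sid) & (acq["stimulus"] == CSM)]
            .sort_values("block")["adjusted"]
            .to_numpy()
        )
        e_csp = (
            ext[(ext["subject_id"] == sid) & (ext["stimulus"] == CSP)]
            .sort_values("block")["adjusted"]
            .to_numpy()
        )
        row: dict[str, float] = {
            "subject_id": sid,
            "acq_csp_lasthalf": _last_half_mean(a_csp),
            "acq_csm_lasthalf": _last_half_mean(a_csm),
            "acq_max_csp": float(np.max(a_csp)),
            "potentiator": nonpotentiator_filter(a_csp, tol=potentiator_tol),
        }
        row["discrimination_index"] = (
            row["acq_csp_lasthalf"] - row["acq_csm_lasthalf"]
        )
        if extinction_metric == "percent":
            pct, named = percent_conditioned_fear(a_csp, e_csp)
            for b, v in enumerate(pct, start=1):
                row[f"pct_fear_b{b}"] = v
            if named.size == len(NAMED_EXT_BLOCKS):
                for name, v in zip(NAMED_EXT_BLOCKS, named):
                    row[f"pct_fear_{name}"] = v
            else:
                for b, v in enumerate(named, start=1):
                    row[f"pct_fear_named_b{b}"] = v
        else:
            named = e_csp.reshape(-1, 2).mean(axis=1)
            for b, v in enumerate(e_csp, start=1):
                row[f"ext_diff_b{b}"] = v
            if named.size == len(NAMED_EXT_BLOCKS):
                for name, v in zip(NAMED_EXT_BLOCKS, named):
                    row[f"ext_diff_{name}"] = v
        rows.append(row)
    out = pd.DataFrame(rows)
    return out.merge(exp, on="subject_id", how="left")
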