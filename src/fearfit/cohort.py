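"""Symptom classification, composite scores, and the cohort exclusion flow.

Classification rules:

* *partial PTSD*: at least 1 B-cluster, 2 C-cluster and 2 D-cluster
  symptoms (counts are assumed to be pre-filtered by the frequency >= 1 /
  intensity >= 2 item criteria, which require item-level interview data the
  pipeline does not model);
* *anxiety*: Beck Anxiety Inventory total strictly greater than 15
  (moderate-to-severe);
* *depression*: Beck Depression Inventory-2 total strictly greater than 19
  (moderate-to-severe);
* *DRRI composite*: each deployment-stress subscale is centered on its
  cohort mean and the centered scores averaged, giving an equally weighted
  composite with cohort mean ~0.  Centering means are computed once, on the
  post-deployment-assessed sample before any symptom-based exclusion, so
  the composite does not depend on downstream filtering.

The exclusion flow applies ordered gates to a cohort: (1) unusable records
(technical loss or missing questionnaires), (2) startle non-potentiators,
(3) lost to follow-up, (4) positive for any symptom group at the
pre-deployment screen, (5) post-deployment labelling, with PTSD cases that
also meet the depression or anxiety cutoff split off as comorbid.  The
primary analysis contrast is healthy vs. (pure) PTSD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LABEL_HEALTHY",
    "LABEL_PTSD",
    "LABEL_COMORBID",
    "LABEL_DEPANX",
    "classify_partial_ptsd",
    "classify_anx_dep",
    "drri_composite",
    "FlowResult",
    "apply_exclusion_flow",
]

LABEL_HEALTHY = "healthy"
LABEL_PTSD = "ptsd"
LABEL_COMORBID = "comorbid_ptsd"
LABEL_DEPANX = "dep_anx_alone"
LABEL_EXCL_UNUSABLE = "excluded_unusable"
LABEL_EXCL_NONPOT = "excluded_nonpotentiator"
LABEL_EXCL_FOLLOWUP = "excluded_lost_followup"
LABEL_EXCL_PRE = "excluded_pre"
LABEL_EXCL_MISSING = "excluded_missing"

DRRI_SUBSCALES = (
    "drri_postbattle",
    "drri_combat",
    "drri_concerns",
    "drri_environment",
)

BAI_CUTOFF = 15
BDI2_CUTOFF = 19


def classify_partial_ptsd(b_count: int, c_count: int, d_count: int) -> bool:
    """Partial-PTSD status from CAPS symptom-cluster counts (>=1 B, >=2 C, >=2 D)."""
    return b_count >= 1 and c_count >= 2 and d_count >= 2


def classify_anx_dep(bai_total: float, bdi2_total: float) -> tuple[bool, bool]:
    """(anxiety-positive, depression-positive) flags at the strict cutoffs."""
    return bai_total > BAI_CUTOFF, bdi2_total > BDI2_CUTOFF


def drri_composite(
    subjects: pd.DataFrame,
    subscales: tuple[str, ...] = DRRI_SUBSCALES,
    centering_means: dict[str, float] | None = None,
) -> pd.Series:
    """Equally weighted mean of mean-centered deployment-stress subscales.

    Means default to the column means of ``subjects`` over non-missing
    values; pass ``centering_means`` to center against a reference sample.
    Subjects missing every subscale get NaN; partial panels average the
    centered subscales that are present.
    """
    present = [s for s in subscales if s in subjects.columns]
    if not present:
        raise ValueError(
            f"no DRRI subscale columns found; expected some of {subscales}"
        )
    centered = pd.DataFrame(index=subjects.index)
    for s in present:
        mu = (
            centering_means[s]
            if centering_means is not None
            else float(subjects[s].mean())
        )
        centered[s] = subjects[s] - mu
    return centered.mean(axis=1, skipna=True).rename("drri_composite")


@dataclass
class FlowResult:
    """Exclusion-flow output: per-subject assignments plus gate counts."""

    assignments: pd.DataFrame
    flow: list[dict] = field(default_factory=list)

    @property
    def primary(self) -> pd.DataFrame:
        """The primary-analysis set: healthy and pure-PTSD subjects."""
        keep = self.assignments["label"].isin([LABEL_HEALTHY, LABEL_PTSD])
        return self.assignments[keep]

    def flow_table(self) -> str:
        lines = []
        for stage in self.flow:
            lines.append(
                f"{stage['stage']:<24s} in={stage['n_in']:<5d} "
                f"excluded={stage['n_excluded']:<5d} out={stage['n_out']}"
            )
        return "\n".join(lines)


def _required_questionnaires(df: pd.DataFrame) -> pd.Series:
    cols = [
        "caps_b_pre", "caps_c_pre", "caps_d_pre",
        "caps_b_post", "caps_c_post", "caps_d_post",
        "bai_pre", "bai_post", "bdi2_pre", "bdi2_post",
    ]
    missing_cols = [c for c in cols if c not in df.columns]
    if missing_cols:
        raise ValueError(f"subject table missing column(s): {missing_cols}")
    return df[cols].isna().any(axis=1)


def apply_exclusion_flow(
    subjects: pd.DataFrame,
    metrics: pd.DataFrame,
    unusable_subjects: list[str] | None = None,
) -> FlowResult:
    """Run the ordered exclusion gates and label the surviving subjects.

    ``metrics`` must carry ``subject_id`` and ``potentiator`` (from the
    derived-measures stage); ``unusable_subjects`` are IDs flagged by QC
    (e.g. no clean trials to impute from).  Subjects absent from
    ``metrics`` are treated as unusable.  At every gate the retained and
    excluded counts partition the incoming N.
    """
    df = subjects.copy()
    n0 = len(df)
    label = pd.Series(pd.NA, index=df.index, dtype="object")
    flow: list[dict] = []

    def gate(name: str, excluded_mask: pd.Series, excl_label: str) -> None:
        active = label.isna()
        n_in = int(active.sum())
        hit = active & excluded_mask
        label[hit] = excl_label
        flow.append(
            {
                "stage": name,
                "n_in": n_in,
                "n_excluded": int(hit.sum()),
                "n_out": n_in - int(hit.sum()),
            }
        )

    # 1. unusable / technical loss / missing questionnaires
    unusable = set(unusable_subjects or [])
    met = metrics.set_index("subject_id")
    known = df["subject_id"].isin(met.index)
    missing_q = _required_questionnaires(df)
    gate(
        "unusable",
        df["subject_id"].isin(unusable) | ~known,
        LABEL_EXCL_UNUSABLE,
    )
    gate("missing_questionnaires", missing_q, LABEL_EXCL_MISSING)

    # 2. startle non-potentiators
    pot = df["subject_id"].map(met["potentiator"]).eq(True)
    gate("nonpotentiator", ~pot, LABEL_EXCL_NONPOT)

    # 3. lost to follow-up
    lost = (
        df["followup_lost"].astype(bool)
        if "followup_lost" in df.columns
        else pd.Series(False, index=df.index)
    )
    gate("lost_to_followup", lost, LABEL_EXCL_FOLLOWUP)

    # 4. pre-deployment positive on any symptom group
    pre_ptsd = df.apply(
        lambda r: classify_partial_ptsd(
            r["caps_b_pre"], r["caps_c_pre"], r["caps_d_pre"]
        ),
        axis=1,
    )
    pre_anx = df["bai_pre"] > BAI_CUTOFF
    pre_dep = df["bdi2_pre"] > BDI2_CUTOFF
    gate("pre_deployment_positive", pre_ptsd | pre_anx | pre_dep, LABEL_EXCL_PRE)

    # 5. post-deployment labels
    post_ptsd = df.apply(
        lambda r: classify_partial_ptsd(
            r["caps_b_post"], r["caps_c_post"], r["caps_d_post"]
        ),
        axis=1,
    )
    post_anx = df["bai_post"] > BAI_CUTOFF
    post_dep = df["bdi2_post"] > BDI2_CUTOFF
    active = label.isna()
    label[active & post_ptsd & (post_anx | post_dep)] = LABEL_COMORBID
    label[active & post_ptsd & ~(post_anx | post_dep)] = LABEL_PTSD
    label[active & ~post_ptsd & (post_anx | post_dep)] = LABEL_DEPANX
    label[label.isna()] = LABEL_HEALTHY
    flow.append(
        {
            "stage": "post_deployment_labels",
            "n_in": int(active.sum()),
            "n_excluded": int(
                (label[active].isin([LABEL_COMORBID, LABEL_DEPANX])).sum()
            ),
            "n_out": int(label[active].isin([LABEL_HEALTHY, LABEL_PTSD]).sum()),
        }
    )

    assignments = pd.DataFrame(
        {"subject_id": df["subject_id"], "label": label.astype(str)}
    )
    total = sum(s["n_excluded"] for s in flow[:-1])
    assert total + flow[-1]["n_in"] == n0, "gate counts do not partition N"
    return FlowResult(assignments=assignments, flow=flow)
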