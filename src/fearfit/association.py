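"""Prospective-risk models: group membership and symptom severity.

Two downstream models link pre-trauma fear-learning measures to post-trauma
outcomes on the primary analysis set (healthy vs. pure PTSD):

* a logistic regression of PTSD status (healthy as reference) on the cue
  discrimination index (z-scored by default) together with pre-deployment
  symptom severity, deployment stress and trauma-history covariates, with
  the stepwise sequence used in this literature available (drop a
  non-contributing trauma-history count, test the discrimination x
  deployment-stress interaction, retain the final model);
* a multivariate linear model of post-deployment CAPS severity on the three
  extracted RW learning rates (optionally adjusted for pre-deployment
  covariates), reporting slopes, partial eta-squared effect sizes and a
  partial-residual table for plotting.

p-values are reported unadjusted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "RiskModelResult",
    "fit_status_model",
    "fit_severity_model",
    "predictor_independence",
]

STATUS_PREDICTORS = ("discrimination_index", "caps_pre", "drri_composite", "lec")
LR_PREDICTORS = ("lr_acq_plus", "lr_acq_minus", "lr_ext")


@dataclass
class RiskModelResult:
    """Coefficient table and metadata for one fitted risk model."""

    kind: str                      # "status" or "severity"
    params: pd.DataFrame           # term, coef, se, stat, p, (or / partial_eta2)
    reference: str | None
    converged: bool
    n: int
    notes: list[str] = field(default_factory=list)
    partial_residuals: pd.DataFrame | None = None

    def coef(self, term: str) -> float:
        row = self.params.loc[self.params["term"] == term]
        if row.empty:
            raise KeyError(f"term {term!r} not in model")
        return float(row["coef"].iloc[0])


def _check_variation(X: pd.DataFrame) -> None:
    for col in X.columns:
        if X[col].nunique(dropna=True) <= 1:
            raise ValueError(f"predictor {col!r} is constant across subjects")


def _zscore(s: pd.Series) -> tuple[pd.Series, float, float]:
    mu, sd = float(s.mean()), float(s.std(ddof=0))
    if sd == 0:
        raise ValueError(f"predictor {s.name!r} is constant across subjects")
    return (s - mu) / sd, mu, sd


def fit_status_model(
    table: pd.DataFrame,
    predictors: tuple[str, ...] = STATUS_PREDICTORS,
    standardize_disc: bool = True,
    model_sequence: bool = False,
    penalized: bool = False,
) -> RiskModelResult:
    """Logistic regression of PTSD status with healthy as the reference.

    ``table`` needs an ``outcome_status`` column in {"healthy", "ptsd"} and
    the predictor columns.  With ``model_sequence=True`` the stepwise
    variant is run: a term named ``lec`` is dropped if non-significant
    (p > 0.10), then a discrimination x deployment-stress interaction is
    tested and retained only if it contributes (p <= 0.10).  On complete
    separation (or with ``penalized=True``) an L2-penalized fit is used and
    flagged.  Other continuous covariates enter on their raw scale.
    """
    df = table.dropna(subset=["outcome_status", *predictors]).copy()
    y = (df["outcome_status"] == "ptsd").astype(float)
    if y.nunique() < 2:
        raise ValueError("both outcome classes must be present")

    notes: list[str] = []
    work = df[list(predictors)].astype(float).copy()
    if standardize_disc and "discrimination_index" in work.columns:
        z, mu, sd = _zscore(work["discrimination_index"])
        work["discrimination_index"] = z
        notes.append(
            f"discrimination_index standardized (mean={mu:.3f}, sd={sd:.3f})"
        )
    _check_variation(work)

    terms = list(work.columns)
    if model_sequence and "lec" in terms:
        res0, conv0 = _logit(work[terms], y, penalized)
        p_lec = _pvalues(res0, terms).get("lec", 0.0)
        if p_lec > 0.10:
            terms.remove("lec")
            notes.append(f"lec dropped (p={p_lec:.3f})")
    if (
        model_sequence
        and "discrimination_index" in terms
        and "drri_composite" in terms
    ):
        inter = work["discrimination_index"] * work["drri_composite"]
        trial = work[terms].assign(disc_x_drri=inter)
        res1, _ = _logit(trial, y, penalized)
        p_int = _pvalues(res1, list(trial.columns)).get("disc_x_drri", 1.0)
        if p_int <= 0.10:
            work["disc_x_drri"] = inter
            terms.append("disc_x_drri")
            notes.append(f"discrimination x deployment-stress kept (p={p_int:.3f})")
        else:
            notes.append(
                f"discrimination x deployment-stress interaction dropped "
                f"(p={p_int:.3f})"
            )

    res, converged = _logit(work[terms], y, penalized)
    if not converged:
        notes.append("separation detected; L2-penalized fallback used")
    params = _logit_table(res, terms)
    return RiskModelResult(
        kind="status",
        params=params,
        reference="healthy",
        converged=converged,
        n=len(df),
        notes=notes,
    )


def _logit(X: pd.DataFrame, y: pd.Series, penalized: bool):
    Xc = sm.add_constant(X, has_constant="add")
    if not penalized:
        try:
            with np.errstate(all="ignore"):
                res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
            if np.all(np.isfinite(res.bse)) and np.max(np.abs(res.params)) < 50:
                return res, True
        except Exception:
            pass
    # ridge-penalized fallback (small L2 on slopes, none on the intercept)
    alpha = np.full(Xc.shape[1], 1e-2)
    alpha[0] = 0.0
    res = sm.GLM(y, Xc, family=sm.families.Binomial()).fit_regularized(
        L1_wt=0.0, alpha=alpha
    )
    return res, False


def _pvalues(res, terms: list[str]) -> dict[str, float]:
    try:
        pv = res.pvalues
        return {t: float(pv[t]) for t in terms if t in pv.index}
    except Exception:
        return {}


def _logit_table(res, terms: list[str]) -> pd.DataFrame:
    params = res.params
    try:
        bse = res.bse
        pvals = res.pvalues
    except Exception:                      # penalized fits lack SEs
        bse = pd.Series(np.nan, index=params.index)
        pvals = pd.Series(np.nan, index=params.index)
    rows = []
    for term in ["const", *terms]:
        if term not in params.index:
            continue
        b = float(params[term])
        rows.append(
            {
                "term": term,
                "coef": b,
                "se": float(bse[term]),
                "p": float(pvals[term]),
                "odds_ratio": float(np.exp(b)),
            }
        )
    return pd.DataFrame(rows)


def fit_severity_model(
    table: pd.DataFrame,
    lr_predictors: tuple[str, ...] = LR_PREDICTORS,
    adjust_for: tuple[str, ...] = (),
) -> RiskModelResult:
    """Linear model of post-deployment CAPS severity on the learning rates.

    The three extracted RW learning rates enter simultaneously; optional
    adjustment covariates (e.g. ``caps_pre``, ``bdi2_pre``, ``lec``) are
    added on their raw scale.  Reports slopes with partial eta-squared and
    emits a partial-residual table for the extinction learning rate
    (observed residuals with the lr_ext contribution added back).
    """
    cols = ["caps_post", *lr_predictors, *adjust_for]
    df = table.dropna(subset=cols).copy()
    if df.empty:
        raise ValueError("no complete rows for severity model")
    X = df[[*lr_predictors, *adjust_for]].astype(float)
    _check_variation(X)
    y = df["caps_post"].astype(float)
    res = sm.OLS(y, sm.add_constant(X)).fit()

    df_resid = res.df_resid
    rows = []
    for term in ["const", *X.columns]:
        t = float(res.tvalues[term])
        rows.append(
            {
                "term": term,
                "coef": float(res.params[term]),
                "se": float(res.bse[term]),
                "t": t,
                "p": float(res.pvalues[term]),
                "partial_eta2": (
                    t * t / (t * t + df_resid) if term != "const" else np.nan
                ),
            }
        )
    params = pd.DataFrame(rows)

    partial = None
    if "lr_ext" in X.columns:
        contrib = res.params["lr_ext"] * X["lr_ext"]
        partial = pd.DataFrame(
            {
                "subject_id": df.get("subject_id", pd.Series(df.index)),
                "lr_ext": X["lr_ext"],
                "partial_residual": res.resid + contrib,
                "fitted_component": contrib,
            }
        ).reset_index(drop=True)

    return RiskModelResult(
        kind="severity",
        params=params,
        reference=None,
        converged=True,
        n=len(df),
        partial_residuals=partial,
    )


def predictor_independence(
    table: pd.DataFrame,
    learning_measures: tuple[str, ...] = ("discrimination_index",
                                          "pct_fear_late"),
    history_measures: tuple[str, ...] = ("lec", "ctq", "drri_composite"),
    deployment_flag: str = "prior_deployment",
) -> dict:
    """Correlations of fear-learning measures with trauma-history measures.

    Returns pairwise Pearson correlations with 95% Fisher-z intervals, and a
    two-sample t-test of each learning measure by prior-deployment status.
    Requires at least 4 complete observations per pair.
    """
    corr_rows = []
    for lm in learning_measures:
        for hm in history_measures:
            sub = table[[lm, hm]].dropna()
            if len(sub) < 4:
                raise ValueError(
                    f"need at least 4 complete observations for {lm} vs {hm}, "
                    f"got {len(sub)}"
                )
            r, p = stats.pearsonr(sub[lm], sub[hm])
            z = np.arctanh(r)
            half = 1.959963984540054 / np.sqrt(len(sub) - 3)
            corr_rows.append(
                {
                    "learning_measure": lm,
                    "history_measure": hm,
                    "r": float(r),
                    "p": float(p),
                    "ci_low": float(np.tanh(z - half)),
                    "ci_high": float(np.tanh(z + half)),
                    "n": len(sub),
                }
            )

    ttest_rows = []
    if deployment_flag in table.columns:
        flag = table[deployment_flag].astype(bool)
        for lm in learning_measures:
            a = table.loc[flag, lm].dropna()
            b = table.loc[~flag, lm].dropna()
            if len(a) >= 2 and len(b) >= 2:
                t, p = stats.ttest_ind(a, b, equal_var=False)
                ttest_rows.append(
                    {
                        "measure": lm,
                        "t": float(t),
                        "p": float(p),
                        "mean_deployed": float(a.mean()),
                        "mean_not_deployed": float(b.mean()),
                    }
                )
    return {
        "correlations": pd.DataFrame(corr_rows),
        "deployment_ttest": pd.DataFrame(ttest_rows),
    }
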