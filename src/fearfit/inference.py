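"""Hierarchical estimation of the RW model family and LOO model comparison.

Two fitting paths share one model definition (the expectation engine and
Gaussian observation model of :mod:`fearfit.rw`):

``method="map"`` (default) — fast path.  Subject parameters (three logit
learning rates and an intercept) are first estimated by penalized maximum
likelihood under Gaussian population priors whose location and scale are
re-estimated from the cohort between sweeps (partial pooling), with the
group-level observation coefficients profiled out by within-subject
centering.  Posterior draws then come from a seeded Gibbs-within-Metropolis
sampler started at that optimum: per-subject Metropolis blocks with
Laplace-shaped proposals, an exact Normal / scaled-inverse-chi-square
conditional draw for the group coefficients and noise SD, and conjugate /
Metropolis updates for the population hyperparameters.  Sampling the joint
posterior (rather than plugging point estimates of the expectations into
the group regression) is what keeps the group coefficients free of
errors-in-regressors attenuation.  Runtime is seconds per cohort and every
draw is reproducible from the seed.

``method="mcmc"`` — reference path: an affine-invariant ensemble sampler
(emcee) over the joint posterior of all subject parameters, group
coefficients, noise SD and population hyperparameters, initialized at the
deterministic solution.  Practical for small cohorts.

Model comparison uses PSIS-smoothed leave-one-out cross-validation on the
per-trial pointwise log-likelihood matrix (arviz), with pairwise elpd
differences and their standard errors; an exact (refit-based)
leave-one-observation-out routine is provided for validating PSIS-LOO on
tiny cohorts.  A left-out trial keeps driving the expectation updates (it
is a predictor for later trials); only its likelihood term is dropped.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logsumexp

from . import _kernels
from .rw import CSM, CSP, NA, PHASE_EXT, STAB, RWModelSpec

__all__ = [
    "PriorConfig",
    "FitResult",
    "LooResult",
    "fit_model",
    "compare_models",
    "psis_loo",
    "exact_loo",
    "extract_learning_rates",
]

logger = logging.getLogger(__name__)

_STIM_CODE = {CSP: 0, CSM: 1, NA: 2}
_LR_NAMES = ("lr_acq_plus", "lr_acq_minus", "lr_ext")
_GROUP_NAMES = ("beta_trial", "beta_discrimination", "beta_generalization",
                "obs_sd")


@dataclass(frozen=True)
class PriorConfig:
    """Weakly informative priors / penalties for the hierarchical fit.

    Learning rates are modeled on the logit scale with Normal population
    distributions; scale-bearing defaults are set from the observed startle
    SD at fit time (``None`` means "derive from data").
    """

    lr_mu_loc: float = 0.0
    lr_mu_scale: float = 1.5
    lr_tau_scale: float = 1.0
    intercept_scale: float | None = None
    beta_scale: float | None = None
    obs_sd_scale: float | None = None
    e0: float = 0.5
    tau_floor: float = 0.10
    tau_cap: float = 2.0


@dataclass
class _Packed:
    """Cohort trials packed into rectangular arrays (equal-length sessions)."""

    subject_ids: list[str]
    stim: np.ndarray     # (n, T) int64; 0 CS+, 1 CS-, 2 NA
    is_ext: np.ndarray   # (n, T) int64
    us: np.ndarray       # (n, T) int64
    t: np.ndarray        # (n, T) float64
    y: np.ndarray        # (n, T) float64
    w: np.ndarray        # (n, T) float64 likelihood weights
    obs_index: pd.DataFrame

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_trials(self) -> int:
        return self.stim.shape[1]


def _pack(trials: pd.DataFrame, exclude_obs=None) -> _Packed:
    modeled = trials[trials["stimulus"] != STAB].copy()
    phase_rank = (modeled["phase"] == PHASE_EXT).astype(int)
    modeled = modeled.assign(_rank=phase_rank).sort_values(
        ["subject_id", "_rank", "trial_index"], kind="stable"
    )
    ids = modeled["subject_id"].drop_duplicates().tolist()
    lengths = modeled.groupby("subject_id").size()
    if lengths.nunique() != 1:
        raise ValueError(
            "all subjects must share the task design (equal trial counts); "
            f"saw counts {sorted(lengths.unique())}"
        )
    T = int(lengths.iloc[0])
    n = len(ids)
    stim = modeled["stimulus"].map(_STIM_CODE)
    if stim.isna().any():
        bad = modeled.loc[stim.isna(), "stimulus"].unique()
        raise ValueError(f"unknown stimulus code(s): {bad}")
    packed = _Packed(
        subject_ids=ids,
        stim=stim.to_numpy(dtype=np.int64).reshape(n, T),
        is_ext=modeled["_rank"].to_numpy(dtype=np.int64).reshape(n, T),
        us=modeled["us"].to_numpy(dtype=np.int64).reshape(n, T),
        t=np.tile(np.arange(T, dtype=float), (n, 1)),
        y=modeled["startle"].to_numpy(dtype=float).reshape(n, T),
        w=np.ones((n, T)),
        obs_index=modeled[["subject_id", "phase", "trial_index"]].reset_index(
            drop=True
        ),
    )
    if exclude_obs is not None:
        flat = packed.w.reshape(-1)
        flat[np.asarray(exclude_obs, dtype=int)] = 0.0
    return packed


def _data_token(p: _Packed) -> str:
    import hashlib

    h = hashlib.sha256()
    h.update(",".join(p.subject_ids).encode())
    h.update(np.round(p.y, 6).tobytes())
    h.update(p.stim.tobytes())
    return h.hexdigest()[:16]


@dataclass
class LooResult:
    """PSIS-LOO comparison across model fits on identical observations."""

    table: pd.DataFrame                     # ranked by elpd_loo, best first
    pairwise: pd.DataFrame                  # elpd differences vs the best fit
    pointwise: dict[str, np.ndarray] = field(default_factory=dict)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"LooResult:\n{self.table.to_string()}"


@dataclass
class FitResult:
    """Posterior summaries, pointwise log-likelihoods and diagnostics."""

    spec: RWModelSpec
    method: str
    seed: int
    subject_summary: pd.DataFrame
    group_summary: pd.DataFrame
    loglik: np.ndarray | None        # (draws, observations)
    group_draws: np.ndarray | None   # (draws, 4): betas + obs_sd
    obs_index: pd.DataFrame
    diagnostics: dict
    point: dict
    data_token: str

    @property
    def converged(self) -> bool:
        return bool(self.diagnostics.get("converged", False))

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.subject_summary.to_csv(out / "subject_summary.csv", index=False)
        self.group_summary.to_csv(out / "group_summary.csv", index=False)
        self.obs_index.to_csv(out / "obs_index.csv", index=False)
        meta = {
            "model_id": self.spec.id,
            "method": self.method,
            "seed": self.seed,
            "diagnostics": self.diagnostics,
            "data_token": self.data_token,
            "point_group": self.point.get("group", {}),
        }
        (out / "fit.json").write_text(json.dumps(meta, indent=2))
        if self.loglik is not None:
            np.savez_compressed(
                out / "loglik.npz",
                loglik=self.loglik,
                group_draws=(
                    self.group_draws
                    if self.group_draws is not None
                    else np.empty((0, 4))
                ),
            )

    @classmethod
    def load(cls, fit_dir: str | Path) -> "FitResult":
        d = Path(fit_dir)
        meta = json.loads((d / "fit.json").read_text())
        ll_path = d / "loglik.npz"
        loglik = group_draws = None
        if ll_path.exists():
            with np.load(ll_path) as npz:
                loglik = npz["loglik"]
                gd = (
                    npz["group_draws"] if "group_draws" in npz.files else None
                )
                group_draws = gd if gd is not None and gd.size else None
        return cls(
            spec=RWModelSpec.from_id(meta["model_id"]),
            method=meta["method"],
            seed=meta["seed"],
            subject_summary=pd.read_csv(d / "subject_summary.csv"),
            group_summary=pd.read_csv(d / "group_summary.csv"),
            loglik=loglik,
            obs_index=pd.read_csv(d / "obs_index.csv"),
            diagnostics=meta["diagnostics"],
            point={"group": meta.get("point_group", {})},
            data_token=meta["data_token"],
        )


def _split_rhat(draws: np.ndarray) -> float:
    """Split-R-hat of a 1-D draw sequence (4 pseudo-chains)."""
    m = 4
    n = draws.size // m
    if n < 2:
        return float("nan")
    chains = draws[: m * n].reshape(m, n)
    chain_means = chains.mean(axis=1)
    chain_vars = chains.var(axis=1, ddof=1)
    W = chain_vars.mean()
    B = n * chain_means.var(ddof=1)
    if W <= 0:
        return 1.0
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def _summary_row(name: str, draws: np.ndarray) -> dict:
    return {
        "parameter": name,
        "mean": float(np.mean(draws)),
        "sd": float(np.std(draws, ddof=1)) if draws.size > 1 else 0.0,
        "q5": float(np.quantile(draws, 0.05)),
        "q95": float(np.quantile(draws, 0.95)),
        "rhat": _split_rhat(draws),
    }


def _numeric_hessian(f, x, h=1e-4) -> np.ndarray:
    k = x.size
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            if i == j:
                fp = f(x + h * _e(k, i))
                fm = f(x - h * _e(k, i))
                H[i, i] = (fp - 2.0 * f(x) + fm) / h**2
            else:
                fpp = f(x + h * (_e(k, i) + _e(k, j)))
                fpm = f(x + h * (_e(k, i) - _e(k, j)))
                fmp = f(x - h * (_e(k, i) - _e(k, j)))
                fmm = f(x - h * (_e(k, i) + _e(k, j)))
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h**2)
    return H


def _e(k: int, i: int) -> np.ndarray:
    v = np.zeros(k)
    v[i] = 1.0
    return v


def _pd_inverse(H: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    vals, vecs = np.linalg.eigh(0.5 * (H + H.T))
    vals = np.clip(vals, floor, None)
    return (vecs / vals) @ vecs.T


class _MapState:
    """Working state of the deterministic empirical-Bayes fit."""

    def __init__(self, packed: _Packed, spec: RWModelSpec, priors: PriorConfig):
        self.p = packed
        self.spec = spec
        self.priors = priors
        y = packed.y[packed.w > 0]
        self.y_mean = float(np.mean(y))
        self.y_sd = float(np.std(y)) or 1.0
        self.two_lr = spec.n_acq_lrs == 2
        self.use_gen = spec.generalization

        n = packed.n_subjects
        self.theta = np.zeros((n, 4))
        self.theta[:, 3] = packed.y.mean(axis=1)
        self.mu = np.array(
            [priors.lr_mu_loc] * 3 + [self.y_mean], dtype=float
        )
        self.tau = np.array(
            [priors.lr_mu_scale] * 3
            + [priors.intercept_scale or 2.0 * self.y_sd],
            dtype=float,
        )
        self.beta = np.zeros(3)        # beta_trial, beta_disc, beta_gen
        self.sigma = self.y_sd

    def expectations(self, theta=None) -> tuple[np.ndarray, np.ndarray]:
        theta = self.theta if theta is None else theta
        n, T = self.p.stim.shape
        ed = np.empty((n, T))
        eg = np.empty((n, T))
        for j in range(n):
            lrp = expit(theta[j, 0])
            lrm = expit(theta[j, 1]) if self.two_lr else lrp
            lre = expit(theta[j, 2])
            ed[j], eg[j] = _kernels.forward_kernel(
                self.p.stim[j], self.p.is_ext[j], self.p.us[j],
                lrp, lrm, lre, self.priors.e0,
            )
        return ed, eg

    def _design(self, ed, eg) -> np.ndarray:
        cols = [self.p.t.reshape(-1), ed.reshape(-1)]
        if self.use_gen:
            cols.append(eg.reshape(-1))
        return np.column_stack(cols)

    def update_group(self) -> None:
        # Subject intercepts are profiled out by within-subject centering,
        # which avoids the slow intercept <-> coefficient alternation the
        # shared generalization/trend regressors would otherwise cause.
        ed, eg = self.expectations()
        X = self._design(ed, eg)
        y = self.p.y.reshape(-1)
        w = self.p.w.reshape(-1)
        n, T = self.p.stim.shape
        sub = np.repeat(np.arange(n), T)
        m = w > 0
        Xc = X.copy()
        yc = y.copy()
        for j in range(n):
            rows = m & (sub == j)
            Xc[rows] -= Xc[rows].mean(axis=0)
            yc[rows] -= yc[rows].mean()
        beta, *_ = np.linalg.lstsq(Xc[m], yc[m], rcond=None)
        self.beta = np.append(beta, 0.0) if not self.use_gen else beta
        # subject intercepts consistent with the new coefficients
        fitted = X @ beta
        for j in range(n):
            rows = m & (sub == j)
            self.theta[j, 3] = float((y[rows] - fitted[rows]).mean())
        resid = yc[m] - Xc[m] @ beta
        self.sigma = max(float(np.sqrt(np.mean(resid**2))), 1e-3)

    def subject_sweep(self) -> float:
        bt, bd, bg = self.beta
        total = 0.0
        for j in range(self.p.n_subjects):
            args = (
                self.p.stim[j], self.p.is_ext[j], self.p.us[j],
                self.p.t[j], self.p.y[j], self.p.w[j],
                bt, bd, bg, self.sigma, self.mu, self.tau,
                self.two_lr, self.use_gen, self.priors.e0,
            )
            res = minimize(
                _kernels.subject_neg_obj,
                self.theta[j],
                args=args,
                method="L-BFGS-B",
                bounds=[(-7, 7)] * 3 + [(None, None)],
            )
            self.theta[j] = res.x
            total += res.fun
        return total

    def update_hyper(self) -> None:
        pr = self.priors
        n = self.p.n_subjects
        for k in range(3):
            vals = self.theta[:, k]
            # posterior-mean-style shrinkage of the population location
            prec = n / max(self.tau[k], pr.tau_floor) ** 2
            prec0 = 1.0 / pr.lr_mu_scale**2
            self.mu[k] = (prec * vals.mean() + prec0 * pr.lr_mu_loc) / (
                prec + prec0
            )
            self.tau[k] = float(
                np.clip(vals.std() + 1e-3, pr.tau_floor, pr.tau_cap)
            )
        vals = self.theta[:, 3]
        self.mu[3] = vals.mean()
        self.tau[3] = float(max(vals.std() + 1e-3, 0.05 * self.y_sd))
        if not self.two_lr:
            # the US- rate carries no data; pin its population to the US+ one
            self.mu[1] = self.mu[0]
            self.tau[1] = self.tau[0]

    def fit(self, outer_iters: int, tol: float = 1e-8) -> dict:
        self.update_group()
        last = np.inf
        history = []
        for it in range(outer_iters):
            obj = self.subject_sweep()
            self.update_hyper()
            self.update_group()
            history.append(obj)
            if abs(last - obj) < tol * (1.0 + abs(obj)):
                break
            last = obj
        return {"n_outer": len(history), "objective": history[-1]}


def _gibbs_draws(
    state: _MapState,
    n_draws: int,
    rng: np.random.Generator,
    burn: int = 300,
    thin: int = 2,
) -> dict:
    """Seeded Gibbs-within-Metropolis draws from the joint posterior.

    Initialized at the deterministic optimum.  Each sweep (1) updates every
    subject's (logit learning rates, intercept) block by a random-walk
    Metropolis step with a Laplace-covariance proposal, adapted during
    burn-in; (2) draws the group coefficients and noise SD from their exact
    Normal / scaled-inverse-chi-square conditional (flat coefficient prior);
    (3) draws population locations conjugately and population scales by a
    Metropolis step under half-Normal priors.  Sampling the joint posterior
    (rather than plugging in point estimates of the expectations) is what
    keeps the group coefficients free of errors-in-regressors attenuation.
    """
    p = state.p
    pr = state.priors
    n, T = p.stim.shape
    n_beta = 3 if state.use_gen else 2

    theta = state.theta.copy()
    beta = state.beta.copy()
    sigma = state.sigma
    mu = state.mu.copy()
    tau = state.tau.copy()

    # Laplace centers/covariances per subject (at the optimization solution);
    # used both for random-walk proposal shapes and for occasional
    # independence proposals that decorrelate the subject field globally.
    chols = []
    prec_chols = []
    centers = theta.copy()
    log_scale = np.full(n, np.log(2.38 / 2.0))
    for j in range(n):
        args = (
            p.stim[j], p.is_ext[j], p.us[j], p.t[j], p.y[j], p.w[j],
            beta[0], beta[1], beta[2], sigma, mu, tau,
            state.two_lr, state.use_gen, pr.e0,
        )

        def f(x, _a=args):
            return _kernels.subject_neg_obj(x, *_a)

        H = _numeric_hessian(f, theta[j])
        cov = _pd_inverse(H)
        chols.append(np.linalg.cholesky(cov))
        prec_chols.append(np.linalg.cholesky(np.linalg.inv(cov)))

    # cached per-subject expectation arrays and objective values
    ed = np.empty((n, T))
    eg = np.empty((n, T))

    def _forward(j, th):
        lrp = expit(th[0])
        lrm = expit(th[1]) if state.two_lr else lrp
        return _kernels.forward_kernel(
            p.stim[j], p.is_ext[j], p.us[j], lrp, lrm, expit(th[2]), pr.e0
        )

    for j in range(n):
        ed[j], eg[j] = _forward(j, theta[j])

    mask = p.w.reshape(-1) > 0
    t_flat = p.t.reshape(-1)
    y_flat = p.y.reshape(-1)
    df = int(mask.sum()) - n_beta
    sub_rep = np.repeat(np.arange(n), T)

    n_sweeps = burn + thin * n_draws
    keep = 0
    out = {
        "lrp": np.empty((n_draws, n)), "lrm": np.empty((n_draws, n)),
        "lre": np.empty((n_draws, n)), "c": np.empty((n_draws, n)),
        "beta": np.empty((n_draws, 3)), "sigma": np.empty(n_draws),
        "loglik": np.empty((n_draws, n * T)),
    }
    accept = np.zeros(n)

    for sweep in range(n_sweeps):
        # --- subject blocks (random-walk Metropolis) ---
        for j in range(n):
            args = (
                p.stim[j], p.is_ext[j], p.us[j], p.t[j], p.y[j], p.w[j],
                beta[0], beta[1], beta[2], sigma, mu, tau,
                state.two_lr, state.use_gen, pr.e0,
            )
            cur = _kernels.subject_neg_obj(theta[j], *args)
            if rng.random() < 0.5:
                # independence proposal from the Laplace approximation
                prop = centers[j] + chols[j] @ rng.standard_normal(4)
                zc = prec_chols[j].T @ (theta[j] - centers[j])
                zp = prec_chols[j].T @ (prop - centers[j])
                log_q = 0.5 * (zp @ zp - zc @ zc)   # log q(cur) - log q(prop)
                adapt = False
            else:
                prop = theta[j] + np.exp(log_scale[j]) * (
                    chols[j] @ rng.standard_normal(4)
                )
                log_q = 0.0
                adapt = True
            if np.all(np.abs(prop[:3]) < 9.0):
                new = _kernels.subject_neg_obj(prop, *args)
                if np.log(rng.random()) < (cur - new) + log_q:
                    theta[j] = prop
                    ed[j], eg[j] = _forward(j, prop)
                    if adapt:
                        accept[j] += 1
            if sweep < burn and (sweep + 1) % 50 == 0:
                rate = accept[j] / 25.0
                log_scale[j] += 0.3 * (rate - 0.30)
                accept[j] = 0.0

        # --- group coefficients and noise SD (conjugate) ---
        cols = [t_flat, ed.reshape(-1)]
        if state.use_gen:
            cols.append(eg.reshape(-1))
        X = np.column_stack(cols)
        r = y_flat - np.repeat(theta[:, 3], T)
        XtX = X[mask].T @ X[mask]
        bhat = np.linalg.solve(XtX, X[mask].T @ r[mask])
        rss = float(np.sum((r[mask] - X[mask] @ bhat) ** 2))
        sigma2 = rss / rng.chisquare(df)
        bdraw = bhat + np.linalg.cholesky(
            sigma2 * np.linalg.inv(XtX)
        ) @ rng.standard_normal(n_beta)
        beta = np.append(bdraw, 0.0) if not state.use_gen else bdraw
        sigma = float(np.sqrt(sigma2))

        # --- population hyperparameters ---
        hyper_locs = [pr.lr_mu_loc] * 3 + [state.y_mean]
        hyper_scales = [pr.lr_mu_scale] * 3 + [
            pr.intercept_scale or 2.0 * state.y_sd
        ]
        tau_scales = [pr.lr_tau_scale] * 3 + [
            pr.intercept_scale or 2.0 * state.y_sd
        ]
        for k in range(4):
            prec = n / tau[k] ** 2 + 1.0 / hyper_scales[k] ** 2
            m = (
                theta[:, k].sum() / tau[k] ** 2
                + hyper_locs[k] / hyper_scales[k] ** 2
            ) / prec
            mu[k] = m + rng.standard_normal() / np.sqrt(prec)
            # Metropolis step on log tau under a half-Normal prior
            lt = np.log(tau[k])
            lt_prop = lt + 0.2 * rng.standard_normal()
            t_prop = np.exp(lt_prop)
            ss = float(np.sum((theta[:, k] - mu[k]) ** 2))

            def _lp(t_, lt_):
                return (
                    -n * lt_
                    - 0.5 * ss / t_**2
                    - 0.5 * (t_ / tau_scales[k]) ** 2
                    + lt_
                )

            if np.log(rng.random()) < _lp(t_prop, lt_prop) - _lp(tau[k], lt):
                tau[k] = float(np.clip(t_prop, 1e-3, None))

        # --- collect ---
        if sweep >= burn and (sweep - burn) % thin == 0 and keep < n_draws:
            lrp = expit(theta[:, 0])
            lrm = expit(theta[:, 1]) if state.two_lr else lrp
            out["lrp"][keep] = lrp
            out["lrm"][keep] = lrm
            out["lre"][keep] = expit(theta[:, 2])
            out["c"][keep] = theta[:, 3]
            out["beta"][keep] = beta
            out["sigma"][keep] = sigma
            resid = r - X @ beta[: X.shape[1]]
            out["loglik"][keep] = (
                -0.5 * _kernels.LOG_2PI - np.log(sigma)
                - 0.5 * (resid / sigma) ** 2
            )
            keep += 1

    return out


def _summaries(
    draws: dict, subject_ids: list[str], two_lr: bool
) -> tuple[pd.DataFrame, pd.DataFrame]:
    sub_rows = []
    for j, sid in enumerate(subject_ids):
        row: dict = {"subject_id": sid}
        for name, arr in (
            ("lr_acq_plus", draws["lrp"]),
            ("lr_acq_minus", draws["lrm"] if two_lr else draws["lrp"]),
            ("lr_ext", draws["lre"]),
            ("beta_intercept", draws["c"]),
        ):
            d = arr[:, j]
            row[f"{name}_mean"] = float(d.mean())
            row[f"{name}_sd"] = float(d.std(ddof=1))
            row[f"{name}_q5"] = float(np.quantile(d, 0.05))
            row[f"{name}_q95"] = float(np.quantile(d, 0.95))
            row[f"{name}_rhat"] = _split_rhat(d)
        sub_rows.append(row)
    group_rows = [
        _summary_row("beta_trial", draws["beta"][:, 0]),
        _summary_row("beta_discrimination", draws["beta"][:, 1]),
        _summary_row("beta_generalization", draws["beta"][:, 2]),
        _summary_row("obs_sd", draws["sigma"]),
    ]
    return pd.DataFrame(sub_rows), pd.DataFrame(group_rows)


def fit_model(
    trials: pd.DataFrame,
    spec: RWModelSpec,
    priors: PriorConfig | None = None,
    method: str = "map",
    seed: int = 0,
    n_draws: int = 400,
    compute_draws: bool = True,
    exclude_obs: np.ndarray | None = None,
    outer_iters: int = 16,
    gibbs_burn: int = 800,
    gibbs_thin: int = 4,
    mcmc_steps: int = 1000,
    mcmc_burn: int = 500,
    rhat_threshold: float = 1.05,
) -> FitResult:
    """Fit one RW model variant to a cohort trial table.

    Parameters
    ----------
    trials:
        Long-format trial table (artifacts imputed); all subjects must share
        the task design.
    spec:
        Which of the four model variants to fit.
    method:
        ``"map"`` (penalized-ML optimization + seeded Gibbs draws, default)
        or ``"mcmc"`` (emcee ensemble over the joint posterior).
    exclude_obs:
        Flat observation indices (row order of ``obs_index``) whose
        likelihood terms are dropped while the trials still drive the
        expectation updates — used by exact LOO.
    compute_draws:
        If False, skip draws and the pointwise log-likelihood matrix
        (point estimates only; model comparison unavailable).
    """
    if method not in ("map", "mcmc"):
        raise ValueError(f"unknown method {method!r}")
    priors = priors or PriorConfig()
    packed = _pack(trials, exclude_obs=exclude_obs)
    if packed.n_subjects == 1:
        logger.warning(
            "single-subject cohort: population hyperparameters are "
            "prior-dominated and posteriors will be wide"
        )
    token = _data_token(packed)
    rng = np.random.default_rng(seed)

    state = _MapState(packed, spec, priors)
    info = state.fit(outer_iters)
    diagnostics: dict = {
        "method": method,
        "n_outer": info["n_outer"],
        "objective": float(info["objective"]),
        "divergences": 0,
        "converged": True,
    }

    if method == "mcmc":
        draws = _run_mcmc(
            state, n_draws=n_draws, steps=mcmc_steps, burn=mcmc_burn,
            seed=seed, priors=priors,
        )
        diagnostics.update(draws.pop("_diagnostics"))
        diagnostics["converged"] = (
            diagnostics.get("rhat_max", np.inf) < rhat_threshold
        )
    elif compute_draws:
        draws = _gibbs_draws(
            state, n_draws, rng, burn=gibbs_burn, thin=gibbs_thin
        )
    else:
        draws = None

    if draws is not None:
        subject_summary, group_summary = _summaries(
            draws, packed.subject_ids, state.two_lr
        )
        loglik = draws["loglik"]
        group_draws = np.column_stack([draws["beta"], draws["sigma"]])
        rhats = [group_summary["rhat"].max()]
        rhats += [
            subject_summary[c].max()
            for c in subject_summary.columns
            if c.endswith("_rhat")
        ]
        diagnostics["rhat_max"] = float(np.nanmax(rhats))
    else:
        point_sub = _point_subject_frame(state, packed.subject_ids)
        subject_summary = point_sub
        group_summary = pd.DataFrame(
            [
                {"parameter": n_, "mean": v, "sd": np.nan,
                 "q5": np.nan, "q95": np.nan, "rhat": np.nan}
                for n_, v in zip(
                    _GROUP_NAMES,
                    [state.beta[0], state.beta[1], state.beta[2], state.sigma],
                )
            ]
        )
        loglik = None
        group_draws = None

    point = {
        "group": {
            "beta_trial": float(state.beta[0]),
            "beta_discrimination": float(state.beta[1]),
            "beta_generalization": float(state.beta[2]),
            "obs_sd": float(state.sigma),
        },
        "theta": state.theta.copy(),
        "hyper_mu": state.mu.copy(),
        "hyper_tau": state.tau.copy(),
    }
    return FitResult(
        spec=spec,
        method=method,
        seed=seed,
        subject_summary=subject_summary,
        group_summary=group_summary,
        loglik=loglik,
        group_draws=group_draws,
        obs_index=packed.obs_index,
        diagnostics=diagnostics,
        point=point,
        data_token=token,
    )


def _point_subject_frame(state: _MapState, ids: list[str]) -> pd.DataFrame:
    lrp = expit(state.theta[:, 0])
    lrm = expit(state.theta[:, 1]) if state.two_lr else lrp
    return pd.DataFrame(
        {
            "subject_id": ids,
            "lr_acq_plus_mean": lrp,
            "lr_acq_minus_mean": lrm,
            "lr_ext_mean": expit(state.theta[:, 2]),
            "beta_intercept_mean": state.theta[:, 3],
        }
    )


def _run_mcmc(
    state: _MapState, n_draws: int, steps: int, burn: int, seed: int,
    priors: PriorConfig,
) -> dict:
    import emcee

    p = state.p
    n, T = p.stim.shape
    n_beta = 3 if state.use_gen else 2
    dim = 4 * n + n_beta + 1 + 8   # thetas, betas, log sigma, hyper mu/log tau

    y_mean, y_sd = state.y_mean, state.y_sd
    beta_scale = priors.beta_scale or 10.0 * y_sd
    obs_scale = priors.obs_sd_scale or 2.0 * y_sd
    int_scale = priors.intercept_scale or 2.0 * y_sd

    def unpack(v):
        thetas = v[: 4 * n].reshape(n, 4)
        k = 4 * n
        betas = np.zeros(3)
        betas[:n_beta] = v[k: k + n_beta]
        log_sigma = v[k + n_beta]
        mu = v[k + n_beta + 1: k + n_beta + 5]
        log_tau = v[k + n_beta + 5: k + n_beta + 9]
        return thetas, betas, log_sigma, mu, log_tau

    def log_prob(v):
        thetas, betas, log_sigma, mu, log_tau = unpack(v)
        if abs(log_sigma) > 12 or np.any(np.abs(log_tau) > 8):
            return -np.inf
        sigma = np.exp(log_sigma)
        tau = np.exp(log_tau)
        ll = -_kernels.cohort_neg_ll(
            thetas, p.stim, p.is_ext, p.us, p.t, p.y, p.w,
            betas[0], betas[1], betas[2], sigma,
            state.two_lr, state.use_gen, priors.e0,
        )
        lp = 0.0
        # subject-level priors
        for k in range(4):
            d = (thetas[:, k] - mu[k]) / tau[k]
            lp += -0.5 * np.sum(d * d) - n * np.log(tau[k])
        # hyperpriors
        lp += -0.5 * np.sum(
            ((mu[:3] - priors.lr_mu_loc) / priors.lr_mu_scale) ** 2
        )
        lp += -0.5 * ((mu[3] - y_mean) / int_scale) ** 2
        lp += -0.5 * np.sum((tau[:3] / priors.lr_tau_scale) ** 2)
        lp += -0.5 * (tau[3] / int_scale) ** 2
        lp += np.sum(log_tau)          # Jacobians
        lp += -0.5 * np.sum((betas[:n_beta] / beta_scale) ** 2)
        lp += -0.5 * (sigma / obs_scale) ** 2 + log_sigma
        return ll + lp

    x0 = np.concatenate(
        [
            state.theta.reshape(-1),
            state.beta[:n_beta],
            [np.log(state.sigma)],
            state.mu,
            np.log(np.maximum(state.tau, 1e-3)),
        ]
    )
    rng = np.random.default_rng(seed)
    nwalkers = max(2 * dim + 2, 8)
    nwalkers += nwalkers % 2
    p0 = x0 + 1e-3 * rng.normal(size=(nwalkers, dim)) * (1.0 + np.abs(x0))
    sampler = emcee.EnsembleSampler(nwalkers, dim, log_prob)
    sampler.random_state = np.random.RandomState(seed)
    sampler.run_mcmc(p0, steps, progress=False)

    chain = sampler.get_chain(discard=burn)          # (kept, walkers, dim)
    flat = chain.reshape(-1, dim)
    idx = rng.choice(flat.shape[0], size=min(n_draws, flat.shape[0]),
                     replace=False)
    sel = flat[idx]

    # walker-split R-hat on the group-level coordinates
    rhats = []
    for d in range(4 * n, 4 * n + n_beta + 1):
        arr = chain[:, :, d].T.reshape(-1)
        rhats.append(_split_rhat(arr))
    diag = {
        "rhat_max": float(np.nanmax(rhats)),
        "acceptance_fraction": float(np.mean(sampler.acceptance_fraction)),
        "n_steps": steps,
        "n_walkers": nwalkers,
    }

    S = sel.shape[0]
    lrp = np.empty((S, n))
    lrm = np.empty((S, n))
    lre = np.empty((S, n))
    c = np.empty((S, n))
    beta_draws = np.empty((S, 3))
    sigma_draws = np.empty(S)
    loglik = np.empty((S, n * T))
    for s in range(S):
        thetas, betas, log_sigma, _, _ = unpack(sel[s])
        lrp[s] = expit(thetas[:, 0])
        lrm[s] = expit(thetas[:, 1]) if state.two_lr else lrp[s]
        lre[s] = expit(thetas[:, 2])
        c[s] = thetas[:, 3]
        beta_draws[s] = betas
        sigma_draws[s] = np.exp(log_sigma)
        for j in range(n):
            ed, eg = _kernels.forward_kernel(
                p.stim[j], p.is_ext[j], p.us[j],
                lrp[s, j], lrm[s, j], lre[s, j], priors.e0,
            )
            mean = c[s, j] + betas[0] * p.t[j] + betas[1] * ed
            if state.use_gen:
                mean = mean + betas[2] * eg
            z = (p.y[j] - mean) / sigma_draws[s]
            loglik[s, j * T: (j + 1) * T] = (
                -0.5 * _kernels.LOG_2PI - np.log(sigma_draws[s]) - 0.5 * z * z
            )

    return {
        "lrp": lrp, "lrm": lrm, "lre": lre, "c": c,
        "beta": beta_draws, "sigma": sigma_draws, "loglik": loglik,
        "_diagnostics": diag,
    }


def psis_loo(fit: FitResult) -> dict:
    """PSIS-smoothed LOO for one fit (elpd, SE, LOOIC, Pareto-k tallies)."""
    if fit.loglik is None:
        raise ValueError("fit has no pointwise log-likelihood draws")
    import warnings

    import arviz as az

    posterior = {}
    if fit.group_draws is not None:
        for i, name in enumerate(_GROUP_NAMES):
            posterior[name] = fit.group_draws[np.newaxis, :, i]
    else:
        posterior["_dummy"] = np.zeros((1, fit.loglik.shape[0]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        idata = az.from_dict(
            posterior=posterior,
            log_likelihood={"startle": fit.loglik[np.newaxis, :, :]},
        )
        res = az.loo(idata, pointwise=True)
    k = np.asarray(res.pareto_k)
    return {
        "elpd_loo": float(res.elpd_loo),
        "se": float(res.se),
        "looic": float(-2.0 * res.elpd_loo),
        "looic_se": float(2.0 * res.se),
        "p_loo": float(res.p_loo),
        "pareto_k_high_frac": float(np.mean(k > 0.7)),
        "pointwise": np.asarray(res.loo_i),
    }


def compare_models(fits: list[FitResult], force: bool = False) -> LooResult:
    """Rank model fits on identical data by PSIS-LOO elpd.

    Pairwise elpd differences (vs. the top-ranked fit) carry standard
    errors computed from the pointwise elpd contrasts.  Refuses fits on
    different observation sets, and unconverged fits unless ``force``.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    tokens = {f.data_token for f in fits}
    if len(tokens) != 1:
        raise ValueError("fits are not on identical observation sets")
    for f in fits:
        if not f.converged and not force:
            raise ValueError(
                f"fit {f.spec.id} is not converged; pass force=True to "
                "compare anyway"
            )

    rows = []
    pointwise = {}
    for f in fits:
        loo = psis_loo(f)
        pointwise[f.spec.id] = loo.pop("pointwise")
        rows.append({"model": f.spec.id, "method": f.method, **loo})
    table = (
        pd.DataFrame(rows)
        .sort_values("elpd_loo", ascending=False)
        .reset_index(drop=True)
    )
    table["rank"] = np.arange(1, len(table) + 1)

    best = table.loc[0, "model"]
    pw_rows = []
    for m, pw in pointwise.items():
        if m == best:
            continue
        d = pointwise[best] - pw
        pw_rows.append(
            {
                "model": m,
                "elpd_diff": float(d.sum()),
                "diff_se": float(np.sqrt(d.size * np.var(d, ddof=1))),
            }
        )
    pairwise = pd.DataFrame(pw_rows)
    return LooResult(table=table, pairwise=pairwise, pointwise=pointwise)


def exact_loo(
    trials: pd.DataFrame,
    spec: RWModelSpec,
    priors: PriorConfig | None = None,
    seed: int = 0,
    n_draws: int = 200,
    outer_iters: int = 6,
    **fit_kwargs,
) -> dict:
    """Exact (refit-based) leave-one-observation-out elpd.

    For every modeled trial the model is refit with that trial's likelihood
    term removed (the trial still drives expectation updates), and the
    left-out log predictive density is averaged over the refit's posterior
    draws.  Only practical for tiny cohorts; used to validate PSIS-LOO.
    """
    packed = _pack(trials)
    n_obs = packed.n_subjects * packed.n_trials
    elpd_i = np.empty(n_obs)
    for i in range(n_obs):
        fit = fit_model(
            trials, spec, priors=priors, seed=seed + i, n_draws=n_draws,
            exclude_obs=np.array([i]), outer_iters=outer_iters, **fit_kwargs,
        )
        ll_i = fit.loglik[:, i]
        elpd_i[i] = logsumexp(ll_i) - np.log(ll_i.size)
    return {
        "elpd_exact": float(elpd_i.sum()),
        "se": float(np.sqrt(n_obs * np.var(elpd_i, ddof=1))),
        "pointwise": elpd_i,
    }


def extract_learning_rates(fit: FitResult) -> pd.DataFrame:
    """Per-subject posterior-mean learning rates for downstream association."""
    cols = ["subject_id"] + [f"{n}_mean" for n in _LR_NAMES]
    out = fit.subject_summary[cols].copy()
    out.columns = ["subject_id", *_LR_NAMES]
    return out
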