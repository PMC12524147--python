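"""Compiled inner loops for model fitting.

These re-implement the forward expectation pass of :mod:`fearfit.rw` on
packed integer arrays so that per-subject optimization and per-draw
pointwise log-likelihoods are fast enough for simulation studies.  The
readable pandas implementation in :mod:`fearfit.rw` remains the reference;
equality of the two paths is covered by the test suite.

Stimulus codes: 0 = CS+, 1 = CS-, 2 = NA.
"""

from __future__ import annotations

import numpy as np
from numba import njit

LOG_2PI = float(np.log(2.0 * np.pi))


@njit(cache=True)
def forward_kernel(stim, is_ext, us, lrp, lrm, lre, e0):
    """Forward RW pass for one subject; returns (e_disc, e_gen) per trial.

    Entries are the pre-update expectations of the shown stimulus, 0.0 on
    NA trials.
    """
    T = stim.shape[0]
    e_disc = np.zeros(T)
    e_gen_out = np.zeros(T)
    ed = np.empty(2)
    ed[0] = e0
    ed[1] = e0
    eg = e0
    for i in range(T):
        s = stim[i]
        if s == 2:
            continue
        e_disc[i] = ed[s]
        e_gen_out[i] = eg
        if is_ext[i] == 1:
            lr = lre
        elif us[i] == 1:
            lr = lrp
        else:
            lr = lrm
        u = 1.0 if us[i] == 1 else 0.0
        ed[s] = (1.0 - lr) * ed[s] + lr * u
        eg = (1.0 - lr) * eg + lr * u
    return e_disc, e_gen_out


@njit(cache=True)
def subject_neg_obj(
    theta, stim, is_ext, us, t, y, w,
    bt, bd, bg, sigma, mu, tau, two_lr, use_gen, e0,
):
    """Negative penalized log-likelihood for one subject.

    ``theta`` = (logit lr_acq_plus, logit lr_acq_minus, logit lr_ext,
    beta_intercept); the penalty is the Gaussian population prior with
    location ``mu`` and scale ``tau`` (length 4).  Weights ``w`` zero out
    observations excluded from the likelihood (exact LOO) while the trial
    still drives the expectation updates.
    """
    lrp = 1.0 / (1.0 + np.exp(-theta[0]))
    lrm = 1.0 / (1.0 + np.exp(-theta[1])) if two_lr else lrp
    lre = 1.0 / (1.0 + np.exp(-theta[2]))
    c = theta[3]

    ed0 = e0
    ed1 = e0
    eg = e0
    nll = 0.0
    inv2s2 = 0.5 / (sigma * sigma)
    log_norm = 0.5 * LOG_2PI + np.log(sigma)
    T = stim.shape[0]
    for i in range(T):
        s = stim[i]
        if s == 2:
            m = c + bt * t[i]
        else:
            e_d = ed0 if s == 0 else ed1
            m = c + bt * t[i] + bd * e_d
            if use_gen:
                m += bg * eg
            if is_ext[i] == 1:
                lr = lre
            elif us[i] == 1:
                lr = lrp
            else:
                lr = lrm
            u = 1.0 if us[i] == 1 else 0.0
            if s == 0:
                ed0 = (1.0 - lr) * ed0 + lr * u
            else:
                ed1 = (1.0 - lr) * ed1 + lr * u
            eg = (1.0 - lr) * eg + lr * u
        r = y[i] - m
        nll += w[i] * (inv2s2 * r * r + log_norm)

    for k in range(4):
        d = (theta[k] - mu[k]) / tau[k]
        nll += 0.5 * d * d
    return nll


@njit(cache=True)
def forward_draws(stim, is_ext, us, lrp, lrm, lre, e0):
    """Forward pass for one subject under S parameter draws.

    ``lrp``/``lrm``/``lre`` have shape (S,); returns (S, T) arrays of
    pre-update expectations (0.0 on NA trials).
    """
    S = lrp.shape[0]
    T = stim.shape[0]
    e_disc = np.zeros((S, T))
    e_gen = np.zeros((S, T))
    for s_ix in range(S):
        ed0 = e0
        ed1 = e0
        eg = e0
        for i in range(T):
            s = stim[i]
            if s == 2:
                continue
            e_disc[s_ix, i] = ed0 if s == 0 else ed1
            e_gen[s_ix, i] = eg
            if is_ext[i] == 1:
                lr = lre[s_ix]
            elif us[i] == 1:
                lr = lrp[s_ix]
            else:
                lr = lrm[s_ix]
            u = 1.0 if us[i] == 1 else 0.0
            if s == 0:
                ed0 = (1.0 - lr) * ed0 + lr * u
            else:
                ed1 = (1.0 - lr) * ed1 + lr * u
            eg = (1.0 - lr) * eg + lr * u
    return e_disc, e_gen


@njit(cache=True)
def cohort_neg_ll(
    thetas, stim, is_ext, us, t, y, w,
    bt, bd, bg, sigma, two_lr, use_gen, e0,
):
    """Total weighted negative log-likelihood over a packed cohort.

    ``thetas`` has shape (n_subjects, 4); trial arrays are
    (n_subjects, T).  No penalty terms — priors are added by the caller.
    """
    n = thetas.shape[0]
    total = 0.0
    zero_mu = np.zeros(4)
    inf_tau = np.full(4, 1e30)
    for j in range(n):
        total += subject_neg_obj(
            thetas[j], stim[j], is_ext[j], us[j], t[j], y[j], w[j],
            bt, bd, bg, sigma, zero_mu, inf_tau, two_lr, use_gen, e0,
        )
    return total
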