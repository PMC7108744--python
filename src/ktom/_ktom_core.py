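"""Numba engine for recursive theory-of-mind (k-ToM) learners.

A k-ToM learner models its opponent as a kappa-ToM learner with kappa < k,
holding for each candidate level kappa:

* a Gaussian belief (mu, Sigma) over the opponent's hidden parameters
  x^kappa = (log sigma_op, log beta_op), assumed to drift with the learner's
  own volatility sigma^k (random-walk prior, variance inflation per trial);
* a posterior probability lambda^kappa that the opponent reasons at level
  kappa (for k = 1 this is the point mass lambda = 1).

Each level-kappa hypothesis yields a probability that the opponent plays
action 1: p^{op,kappa} = s(v^kappa(x)), where v^kappa is the opponent's
softmax log-odds obtained by running a kappa-ToM learner (in the opponent's
role) over the history and reading out its policy at parameters x.  The
learner's overall prediction is the lambda-weighted mixture of the
uncertainty-corrected level predictions.

v^kappa and its gradient W w.r.t. x are evaluated *online*: per level the
learner carries a bank of five simulated opponents, updated trial by trial at
parameter values mu + {0, +-h e1, +-h e2} that track the drifting posterior
mean.  The central replica gives v^kappa(mu) and the perturbed pairs its
central finite-difference gradient.  This keeps every trial O(1) in history
length; the exact full-history replay definition lives in
``ktom._ktom_reference.simulate_level`` and is used as a test oracle.

State is flattened into a single float64 vector per learner so the whole
update runs inside numba.  Layouts (0-based offsets):

k=1 (17): lam[0] | mu 1:3, Sig 3:7, bank0 7:17 (5 x [mu, Sig] scalars)
k=2 (109): lam 0:2 | L0: mu 2:4, Sig 4:8, bank0 8:18
           | L1: mu 18:20, Sig 20:24, bank1 24:109 (5 x 17)
k=3 (661): lam 0:3 | L0: mu 3:5, Sig 5:9, bank0 9:19
           | L1: mu 19:21, Sig 21:25, bank1 25:110 (5 x 17)
           | L2: mu 110:112, Sig 112:116, bank2 116:661 (5 x 109)

Moment closure: E[s(x)] for x ~ N(mu, v) is approximated by
s(mu / sqrt(1 + a*v)) with a = 3/pi^2; Gauss-Hermite quadrature serves as the
test oracle for this approximation.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

#: moment-matching constant for the Gaussian expectation of a sigmoid
A_MOM = 3.0 / math.pi**2
#: finite-difference step for the gradient of v^kappa in x-space
FD_STEP = 1e-3
#: eigenvalue floor used when a covariance update loses positive definiteness
EIG_FLOOR = 1e-8
#: clipping of level predictions inside the lambda (level posterior) update
P_CLIP = 1e-12
#: bound on log-space parameters before exponentiation
X_CLIP = 30.0

_OFF0 = (0.0, FD_STEP, -FD_STEP, 0.0, 0.0)
_OFF1 = (0.0, 0.0, 0.0, FD_STEP, -FD_STEP)

# layout offsets: per k, per level: (mu, Sigma, bank, replica_size)
N_STATE = {0: 2, 1: 17, 2: 109, 3: 661}
LAYOUT = {
    1: ((1, 3, 7, 2),),
    2: ((2, 4, 8, 2), (18, 20, 24, 17)),
    3: ((3, 5, 9, 2), (19, 21, 25, 17), (110, 112, 116, 109)),
}


def init_state(k: int) -> np.ndarray:
    """Prior state vector: mu = 0, Sigma = I, lambda uniform, recursively."""

    def build(kk: int) -> list:
        if kk == 0:
            return [0.0, 1.0]
        out = [1.0 / kk] * kk
        for kappa in range(kk):
            out += [0.0, 0.0, 1.0, 0.0, 0.0, 1.0]
            rep = [0.0, 1.0] if kappa == 0 else build(kappa)
            for _ in range(5):
                out += list(rep)
        return out

    state = np.asarray(build(k), dtype=np.float64)
    assert state.size == N_STATE[k]
    return state


_INIT = {k: init_state(k) for k in range(4)}


@njit(cache=True)
def _sig(x):
    if x >= 0.0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


@njit(cache=True)
def _cexp(x):
    if x > X_CLIP:
        x = X_CLIP
    elif x < -X_CLIP:
        x = -X_CLIP
    return math.exp(x)


@njit(cache=True)
def _sim0_predict(mu, sig, sigma):
    # posterior expectation of s(x) under N(mu, sig + sigma)
    return _sig(mu / math.sqrt(1.0 + A_MOM * (sig + sigma)))


@njit(cache=True)
def _sim0_update(S, base, sigma, a):
    # variance first, then mean (Laplace-style update of the log-odds belief)
    mu = S[base]
    sig = S[base + 1]
    p = _sig(mu)
    sig_new = 1.0 / (1.0 / (sig + sigma) + p * (1.0 - p))
    S[base] = mu + sig_new * (a - p)
    S[base + 1] = sig_new


@njit(cache=True)
def _v0(mu_rep, sig_rep, x0, x1, role_op):
    # softmax log-odds of a simulated 0-ToM opponent at parameters (x0, x1)
    p = _sim0_predict(mu_rep, sig_rep, _cexp(x0))
    return role_op * (2.0 * p - 1.0) / _cexp(x1)


@njit(cache=True)
def _fix2x2(a, b, d):
    """Symmetrize/floor the eigenvalues of [[a, b], [b, d]]; returns repair flag."""
    m = 0.5 * (a + d)
    r = math.sqrt(0.25 * (a - d) * (a - d) + b * b)
    lo = m - r
    if lo >= EIG_FLOOR and math.isfinite(a + b + d):
        return a, b, d, 0
    hi = m + r
    if not math.isfinite(hi) or hi < EIG_FLOOR:
        # degenerate: reset to the floor
        return EIG_FLOOR, 0.0, EIG_FLOOR, 1
    lo = EIG_FLOOR
    # eigenvector (c, s) for the largest eigenvalue
    if abs(b) > 1e-300:
        t0 = hi - d
        nrm = math.sqrt(t0 * t0 + b * b)
        c = t0 / nrm
        s = b / nrm
    elif a >= d:
        c, s = 1.0, 0.0
    else:
        c, s = 0.0, 1.0
    na = hi * c * c + lo * s * s
    nb = (hi - lo) * c * s
    nd = hi * s * s + lo * c * c
    return na, nb, nd, 1


@njit(cache=True)
def _level_stats0(S, mo, so, bo, sigma, role_op):
    """(v_c, W0, W1, corrected prediction) for a level-0 hypothesis."""
    mu0 = S[mo]
    mu1 = S[mo + 1]
    v0 = _v0(S[bo], S[bo + 1], mu0, mu1, role_op)
    v1 = _v0(S[bo + 2], S[bo + 3], mu0 + FD_STEP, mu1, role_op)
    v2 = _v0(S[bo + 4], S[bo + 5], mu0 - FD_STEP, mu1, role_op)
    v3 = _v0(S[bo + 6], S[bo + 7], mu0, mu1 + FD_STEP, role_op)
    v4 = _v0(S[bo + 8], S[bo + 9], mu0, mu1 - FD_STEP, role_op)
    w0 = (v1 - v2) / (2.0 * FD_STEP)
    w1 = (v3 - v4) / (2.0 * FD_STEP)
    var = (
        w0 * w0 * (S[so] + sigma)
        + 2.0 * w0 * w1 * S[so + 1]
        + w1 * w1 * (S[so + 3] + sigma)
    )
    return v0, w0, w1, _sig(v0 / math.sqrt(1.0 + A_MOM * var))


@njit(cache=True)
def _gauss_update(S, mo, so, sigma, lam, v0, w0, w1, a_op):
    """Eq-style mean/covariance update for one level; returns repair flag."""
    sv = _sig(v0)
    # precision of the drift-inflated prior
    pa = S[so] + sigma
    pb = S[so + 1]
    pd = S[so + 3] + sigma
    det = pa * pd - pb * pb
    ia = pd / det
    ib = -pb / det
    idd = pa / det
    c = sv * (1.0 - sv) * lam
    qa = ia + c * w0 * w0
    qb = ib + c * w0 * w1
    qd = idd + c * w1 * w1
    det2 = qa * qd - qb * qb
    sa = qd / det2
    sb = -qb / det2
    sd = qa / det2
    sa, sb, sd, rep = _fix2x2(sa, sb, sd)
    S[so] = sa
    S[so + 1] = sb
    S[so + 2] = sb
    S[so + 3] = sd
    g = lam * (a_op - sv)
    S[mo] += g * (sa * w0 + sb * w1)
    S[mo + 1] += g * (sb * w0 + sd * w1)
    return rep


# All learner functions below address one flat state vector S through a base
# offset b (the start of the learner's slice) instead of array views: the
# nesting is deep enough that view creation dominates the runtime otherwise.

# ----------------------------------------------------------------- k = 1

@njit(cache=True)
def _predict_1(S, b, sigma, role):
    v0, w0, w1, p = _level_stats0(S, b + 1, b + 3, b + 7, sigma, -role)
    return p


@njit(cache=True)
def _update_1(S, b, sigma, role, a_self, a_op):
    v0, w0, w1, p = _level_stats0(S, b + 1, b + 3, b + 7, sigma, -role)
    S[b] = 1.0  # degenerate level posterior
    rep = _gauss_update(S, b + 1, b + 3, sigma, 1.0, v0, w0, w1, a_op)
    for r in range(5):
        s_r = _cexp(S[b + 1] + _OFF0[r])
        _sim0_update(S, b + 7 + 2 * r, s_r, a_self)
    return rep


# ----------------------------------------------------------------- k = 2

@njit(cache=True)
def _v_sub1(S, base, x0, x1, role_op):
    # softmax log-odds of a simulated 1-ToM opponent at parameters (x0, x1)
    p = _predict_1(S, base, _cexp(x0), role_op)
    return role_op * (2.0 * p - 1.0) / _cexp(x1)


@njit(cache=True)
def _level_stats1(S, mo, so, bo, sigma, role_op):
    """(v_c, W0, W1, corrected prediction) for a level-1 hypothesis."""
    mu0 = S[mo]
    mu1 = S[mo + 1]
    v0 = _v_sub1(S, bo, mu0, mu1, role_op)
    v1 = _v_sub1(S, bo + 17, mu0 + FD_STEP, mu1, role_op)
    v2 = _v_sub1(S, bo + 34, mu0 - FD_STEP, mu1, role_op)
    v3 = _v_sub1(S, bo + 51, mu0, mu1 + FD_STEP, role_op)
    v4 = _v_sub1(S, bo + 68, mu0, mu1 - FD_STEP, role_op)
    w0 = (v1 - v2) / (2.0 * FD_STEP)
    w1 = (v3 - v4) / (2.0 * FD_STEP)
    var = (
        w0 * w0 * (S[so] + sigma)
        + 2.0 * w0 * w1 * S[so + 1]
        + w1 * w1 * (S[so + 3] + sigma)
    )
    return v0, w0, w1, _sig(v0 / math.sqrt(1.0 + A_MOM * var))


@njit(cache=True)
def _predict_2(S, b, sigma, role):
    v0a, w0a, w1a, p0 = _level_stats0(S, b + 2, b + 4, b + 8, sigma, -role)
    v0b, w0b, w1b, p1 = _level_stats1(S, b + 18, b + 20, b + 24, sigma, -role)
    return S[b] * p0 + S[b + 1] * p1


@njit(cache=True)
def _clip_p(p):
    if p < P_CLIP:
        return P_CLIP
    if p > 1.0 - P_CLIP:
        return 1.0 - P_CLIP
    return p


@njit(cache=True)
def _update_2(S, b, sigma, role, a_self, a_op):
    v0a, w0a, w1a, p0 = _level_stats0(S, b + 2, b + 4, b + 8, sigma, -role)
    v0b, w0b, w1b, p1 = _level_stats1(S, b + 18, b + 20, b + 24, sigma, -role)
    # Bayes over sophistication levels
    p0c = _clip_p(p0)
    p1c = _clip_p(p1)
    l0 = S[b] * (p0c if a_op == 1 else 1.0 - p0c)
    l1 = S[b + 1] * (p1c if a_op == 1 else 1.0 - p1c)
    tot = l0 + l1
    S[b] = l0 / tot
    S[b + 1] = l1 / tot
    rep = _gauss_update(S, b + 2, b + 4, sigma, S[b], v0a, w0a, w1a, a_op)
    rep += _gauss_update(S, b + 18, b + 20, sigma, S[b + 1], v0b, w0b, w1b, a_op)
    for r in range(5):
        s_r = _cexp(S[b + 2] + _OFF0[r])
        _sim0_update(S, b + 8 + 2 * r, s_r, a_self)
    for r in range(5):
        # the simulated opponent plays the opposite role and sees swapped actions
        rep += _update_1(
            S, b + 24 + 17 * r, _cexp(S[b + 18] + _OFF0[r]), -role, a_op, a_self
        )
    return rep


# ----------------------------------------------------------------- k = 3

@njit(cache=True)
def _v_sub2(S, base, x0, x1, role_op):
    # softmax log-odds of a simulated 2-ToM opponent at parameters (x0, x1)
    p = _predict_2(S, base, _cexp(x0), role_op)
    return role_op * (2.0 * p - 1.0) / _cexp(x1)


@njit(cache=True)
def _level_stats2(S, mo, so, bo, sigma, role_op):
    """(v_c, W0, W1, corrected prediction) for a level-2 hypothesis."""
    mu0 = S[mo]
    mu1 = S[mo + 1]
    v0 = _v_sub2(S, bo, mu0, mu1, role_op)
    v1 = _v_sub2(S, bo + 109, mu0 + FD_STEP, mu1, role_op)
    v2 = _v_sub2(S, bo + 218, mu0 - FD_STEP, mu1, role_op)
    v3 = _v_sub2(S, bo + 327, mu0, mu1 + FD_STEP, role_op)
    v4 = _v_sub2(S, bo + 436, mu0, mu1 - FD_STEP, role_op)
    w0 = (v1 - v2) / (2.0 * FD_STEP)
    w1 = (v3 - v4) / (2.0 * FD_STEP)
    var = (
        w0 * w0 * (S[so] + sigma)
        + 2.0 * w0 * w1 * S[so + 1]
        + w1 * w1 * (S[so + 3] + sigma)
    )
    return v0, w0, w1, _sig(v0 / math.sqrt(1.0 + A_MOM * var))


@njit(cache=True)
def _predict_3(S, b, sigma, role):
    v0a, w0a, w1a, p0 = _level_stats0(S, b + 3, b + 5, b + 9, sigma, -role)
    v0b, w0b, w1b, p1 = _level_stats1(S, b + 19, b + 21, b + 25, sigma, -role)
    v0c, w0c, w1c, p2 = _level_stats2(S, b + 110, b + 112, b + 116, sigma, -role)
    return S[b] * p0 + S[b + 1] * p1 + S[b + 2] * p2


@njit(cache=True)
def _update_3(S, b, sigma, role, a_self, a_op):
    v0a, w0a, w1a, p0 = _level_stats0(S, b + 3, b + 5, b + 9, sigma, -role)
    v0b, w0b, w1b, p1 = _level_stats1(S, b + 19, b + 21, b + 25, sigma, -role)
    v0c, w0c, w1c, p2 = _level_stats2(S, b + 110, b + 112, b + 116, sigma, -role)
    p0c = _clip_p(p0)
    p1c = _clip_p(p1)
    p2c = _clip_p(p2)
    l0 = S[b] * (p0c if a_op == 1 else 1.0 - p0c)
    l1 = S[b + 1] * (p1c if a_op == 1 else 1.0 - p1c)
    l2 = S[b + 2] * (p2c if a_op == 1 else 1.0 - p2c)
    tot = l0 + l1 + l2
    S[b] = l0 / tot
    S[b + 1] = l1 / tot
    S[b + 2] = l2 / tot
    rep = _gauss_update(S, b + 3, b + 5, sigma, S[b], v0a, w0a, w1a, a_op)
    rep += _gauss_update(S, b + 19, b + 21, sigma, S[b + 1], v0b, w0b, w1b, a_op)
    rep += _gauss_update(S, b + 110, b + 112, sigma, S[b + 2], v0c, w0c, w1c, a_op)
    for r in range(5):
        s_r = _cexp(S[b + 3] + _OFF0[r])
        _sim0_update(S, b + 9 + 2 * r, s_r, a_self)
    for r in range(5):
        rep += _update_1(
            S, b + 25 + 17 * r, _cexp(S[b + 19] + _OFF0[r]), -role, a_op, a_self
        )
    for r in range(5):
        rep += _update_2(
            S, b + 116 + 109 * r, _cexp(S[b + 110] + _OFF0[r]), -role, a_op, a_self
        )
    return rep


# ------------------------------------------------------------- dispatch

@njit(cache=True)
def predict_k(S, k, sigma, role):
    """Probability the learner assigns to its opponent playing action 1."""
    if k == 0:
        return _sim0_predict(S[0], S[1], sigma)
    elif k == 1:
        return _predict_1(S, 0, sigma, role)
    elif k == 2:
        return _predict_2(S, 0, sigma, role)
    return _predict_3(S, 0, sigma, role)


@njit(cache=True)
def update_k(S, k, sigma, role, a_self, a_op):
    """One-trial belief update after observing both actions; returns repair count."""
    if k == 0:
        _sim0_update(S, 0, sigma, a_op)
        return 0
    elif k == 1:
        return _update_1(S, 0, sigma, role, a_self, a_op)
    elif k == 2:
        return _update_2(S, 0, sigma, role, a_self, a_op)
    return _update_3(S, 0, sigma, role, a_self, a_op)


@njit(cache=True)
def session_loglik_ktom(k, S_init, a_self, a_op, sigma, beta, bias, role):
    """Log-likelihood of the focal player's action sequence under a k-ToM model.

    The model replays the observed session: at each trial it emits the softmax
    probability of the observed own action given the history, then its state is
    updated with both observed actions (the opponent is never simulated).
    """
    S = S_init.copy()
    ll = 0.0
    n = a_self.shape[0]
    for t in range(n):
        p_op = predict_k(S, k, sigma, role)
        z = (role * (2.0 * p_op - 1.0) + bias) / beta
        if z > 35.0:
            sp = z
        elif z < -35.0:
            sp = 0.0
        else:
            sp = math.log1p(math.exp(z))
        ll += a_self[t] * z - sp
        update_k(S, k, sigma, role, a_self[t], a_op[t])
    return ll


# ---------------------------------------------------- simple-model kernels
# Likelihood loops for the non-recursive learners; these mirror the pure
# update functions in ktom.agents (cross-checked by tests).

@njit(cache=True)
def _softplus(z):
    if z > 35.0:
        return z
    if z < -35.0:
        return 0.0
    return math.log1p(math.exp(z))


@njit(cache=True)
def session_loglik_wsls(a_self, rewards, beta, bias):
    ll = 0.0
    v0 = 0.0
    v1 = 0.0
    for t in range(a_self.shape[0]):
        z = ((v1 - v0) + bias) / beta
        ll += a_self[t] * z - _softplus(z)
        r_signed = 1.0 if rewards[t] == 1 else -1.0
        if a_self[t] == 1:
            v1 = r_signed
            v0 = -r_signed
        else:
            v0 = r_signed
            v1 = -r_signed
    return ll


@njit(cache=True)
def session_loglik_rl(a_self, rewards, alpha, beta, bias):
    ll = 0.0
    v0 = 0.0
    v1 = 0.0
    for t in range(a_self.shape[0]):
        z = ((v1 - v0) + bias) / beta
        ll += a_self[t] * z - _softplus(z)
        if a_self[t] == 1:
            v1 = v1 + alpha * (rewards[t] - v1)
        else:
            v0 = v0 + alpha * (rewards[t] - v0)
    return ll


@njit(cache=True)
def session_loglik_inf(a_self, a_op, eta, w, beta, bias, role, clip):
    ll = 0.0
    p = 0.5
    for t in range(a_self.shape[0]):
        z = (role * (2.0 * p - 1.0) + bias) / beta
        ll += a_self[t] * z - _softplus(z)
        logit_p = math.log(p / (1.0 - p))
        p = (
            p
            + eta * (a_op[t] - p)
            + w * p * (1.0 - p) * (1.0 - 2.0 * a_self[t] - beta * logit_p)
        )
        if p < clip:
            p = clip
        elif p > 1.0 - clip:
            p = 1.0 - clip
    return ll
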