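"""Recursive pure-Python reference for the k-ToM learner.

This mirrors :mod:`ktom._ktom_core` operation for operation, written as small
recursive classes instead of flattened arrays.  It exists (a) as readable
documentation of the update scheme and (b) as an independent implementation
against which the numba engine is cross-checked; it is far too slow for the
fitting pipeline.

It also provides :func:`simulate_level`, the replay definition of the
level-kappa opponent prediction v^kappa: run a fresh kappa-ToM learner (in the
opponent's role, at fixed parameters x = (log sigma, log beta)) over the full
history and read out its policy.  The online engine approximates this with
incrementally maintained replica banks; tests compare the two.
"""

from __future__ import annotations

import math

import numpy as np

from ._ktom_core import A_MOM, EIG_FLOOR, FD_STEP, P_CLIP, X_CLIP

_OFFSETS = [
    np.array([0.0, 0.0]),
    np.array([FD_STEP, 0.0]),
    np.array([-FD_STEP, 0.0]),
    np.array([0.0, FD_STEP]),
    np.array([0.0, -FD_STEP]),
]


def _sig(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def _cexp(x: float) -> float:
    return math.exp(min(max(x, -X_CLIP), X_CLIP))


class RefSim0:
    """Belief over an opponent's choice log-odds (the 0-ToM tracker)."""

    def __init__(self) -> None:
        self.mu = 0.0
        self.sig = 1.0

    def predict(self, sigma: float) -> float:
        return _sig(self.mu / math.sqrt(1.0 + A_MOM * (self.sig + sigma)))

    def update(self, sigma: float, a: int) -> None:
        p = _sig(self.mu)
        sig_new = 1.0 / (1.0 / (self.sig + sigma) + p * (1.0 - p))
        self.mu = self.mu + sig_new * (a - p)
        self.sig = sig_new


class RefKTom:
    """k-ToM learner (k >= 1) in a given role (+1 seeker, -1 hider)."""

    def __init__(self, k: int, role: int) -> None:
        if k < 1:
            raise ValueError("RefKTom requires k >= 1")
        self.k = k
        self.role = role
        self.lam = np.full(k, 1.0 / k)
        self.mu = [np.zeros(2) for _ in range(k)]
        self.Sig = [np.eye(2) for _ in range(k)]
        self.banks = []
        for kappa in range(k):
            if kappa == 0:
                self.banks.append([RefSim0() for _ in range(5)])
            else:
                self.banks.append([RefKTom(kappa, -role) for _ in range(5)])
        self.n_repairs = 0

    # -- level statistics -------------------------------------------------
    def _replica_v(self, kappa: int, r: int, x: np.ndarray) -> float:
        rep = self.banks[kappa][r]
        role_op = -self.role
        if kappa == 0:
            p = rep.predict(_cexp(x[0]))
        else:
            p = rep.predict_opponent(_cexp(x[0]))
        return role_op * (2.0 * p - 1.0) / _cexp(x[1])

    def _level_stats(self, kappa: int, sigma: float):
        v = [self._replica_v(kappa, r, self.mu[kappa] + _OFFSETS[r]) for r in range(5)]
        w = np.array(
            [(v[1] - v[2]) / (2 * FD_STEP), (v[3] - v[4]) / (2 * FD_STEP)]
        )
        var = float(w @ (self.Sig[kappa] + sigma * np.eye(2)) @ w)
        p_corr = _sig(v[0] / math.sqrt(1.0 + A_MOM * var))
        return v[0], w, p_corr

    # -- public contract --------------------------------------------------
    def predict_opponent(self, sigma: float) -> float:
        return float(
            sum(
                self.lam[kappa] * self._level_stats(kappa, sigma)[2]
                for kappa in range(self.k)
            )
        )

    def update(self, sigma: float, a_self: int, a_op: int) -> None:
        stats = [self._level_stats(kappa, sigma) for kappa in range(self.k)]
        # level posterior (Bayes over sophistication levels)
        lik = np.array(
            [
                np.clip(p, P_CLIP, 1 - P_CLIP)
                if a_op == 1
                else 1.0 - np.clip(p, P_CLIP, 1 - P_CLIP)
                for (_, _, p) in stats
            ]
        )
        self.lam = self.lam * lik
        self.lam = self.lam / self.lam.sum()
        # Gaussian belief per level: precision update then mean step along W
        for kappa, (v0, w, _) in enumerate(stats):
            sv = _sig(v0)
            prior = self.Sig[kappa] + sigma * np.eye(2)
            prec = np.linalg.inv(prior) + sv * (1 - sv) * self.lam[kappa] * np.outer(
                w, w
            )
            new = np.linalg.inv(prec)
            new = 0.5 * (new + new.T)
            evals, evecs = np.linalg.eigh(new)
            if evals.min() < EIG_FLOOR or not np.all(np.isfinite(new)):
                evals = np.maximum(evals, EIG_FLOOR)
                new = (evecs * evals) @ evecs.T
                self.n_repairs += 1
            self.Sig[kappa] = new
            self.mu[kappa] = self.mu[kappa] + self.lam[kappa] * new @ w * (
                a_op - sv
            )
        # replica banks track the new posterior mean; the simulated opponents
        # observe the trial with the action labels swapped
        for kappa in range(self.k):
            for r in range(5):
                x = self.mu[kappa] + _OFFSETS[r]
                rep = self.banks[kappa][r]
                if kappa == 0:
                    rep.update(_cexp(x[0]), a_self)
                else:
                    rep.update(_cexp(x[0]), a_self=a_op, a_op=a_self)


def simulate_level(
    kappa: int,
    x: np.ndarray,
    a_self: np.ndarray,
    a_op: np.ndarray,
    role: int,
) -> float:
    """Replay definition of the level prediction p^{op,kappa}.

    Runs a fresh kappa-ToM learner in the opponent's role (-role) with
    parameters fixed at x = (log sigma, log beta) over the full observed
    history, and returns the probability it assigns to playing action 1 on the
    next trial.  Deterministic in (kappa, x, history).
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    if len(a_self) != len(a_op):
        raise ValueError("histories must have equal length")
    x = np.asarray(x, dtype=float)
    sigma = _cexp(x[0])
    beta = _cexp(x[1])
    role_op = -role
    if kappa == 0:
        learner = RefSim0()
        for a in a_self:
            learner.update(sigma, int(a))
        p_pred = learner.predict(sigma)
    else:
        learner = RefKTom(kappa, role_op)
        for s, o in zip(a_self, a_op):
            learner.update(sigma, a_self=int(o), a_op=int(s))
        p_pred = learner.predict_opponent(sigma)
    v = role_op * (2.0 * p_pred - 1.0) / beta
    return _sig(v)
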