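"""Model fitting: per-session likelihoods, MAP + Laplace evidence, posteriors.

Each of the eight candidate strategies defines a trial-by-trial probability of
the focal player's observed choices; free parameters live in an unconstrained
transformed space (log for sigma/beta, logit for alpha/eta/influence weight,
identity for the bias) with independent standard-normal priors.  The log
model evidence log p(a_1:60 | m) is approximated by a Laplace integral around
the MAP found by multi-start quasi-Newton optimisation; a dense-grid
marginalisation oracle for the low-dimensional models lives in the tests.

Fitting always *replays* the participant's observed session: model states are
updated with both observed actions (and the realised reward), never with a
simulated opponent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import _ktom_core as _core
from .agents import MODEL_NAMES
from .game import ROLE_SIGN, SEEKER, SessionRecord

__all__ = [
    "ModelSpec",
    "MODEL_SPECS",
    "FitResult",
    "EvidenceMatrix",
    "session_log_likelihood",
    "fit_session",
    "fit_cohort",
    "model_posterior",
    "FitConfig",
]

_LOG_2PI = math.log(2.0 * math.pi)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -700, 700)))


def _bernoulli_ll(p: float, a: int) -> float:
    p = min(max(p, 1e-12), 1.0 - 1e-12)
    return math.log(p) if a == 1 else math.log(1.0 - p)


@dataclass(frozen=True)
class ModelSpec:
    """A candidate strategy: free parameters with their transforms.

    ``transforms[i]`` maps the i-th unconstrained coordinate to the natural
    parameter: 'log', 'logit' or 'identity'.  Priors are standard normal in
    the unconstrained space.
    """

    name: str
    parameters: tuple
    transforms: tuple

    @property
    def n_params(self) -> int:
        return len(self.parameters)

    def to_natural(self, theta: np.ndarray) -> dict:
        out = {}
        for name, tr, val in zip(self.parameters, self.transforms, theta):
            if tr == "log":
                out[name] = math.exp(min(max(val, -30.0), 30.0))
            elif tr == "logit":
                out[name] = 1.0 / (1.0 + math.exp(-min(max(val, -30.0), 30.0)))
            else:
                out[name] = float(val)
        return out


MODEL_SPECS = {
    "BN": ModelSpec("BN", ("bias",), ("identity",)),
    "WSLS": ModelSpec("WSLS", ("beta", "bias"), ("log", "identity")),
    "RL": ModelSpec("RL", ("alpha", "beta", "bias"), ("logit", "log", "identity")),
    "0-ToM": ModelSpec("0-ToM", ("sigma", "beta", "bias"), ("log", "log", "identity")),
    "Inf": ModelSpec(
        "Inf",
        ("eta", "influence_weight", "beta", "bias"),
        ("logit", "logit", "log", "identity"),
    ),
    "1-ToM": ModelSpec("1-ToM", ("sigma", "beta", "bias"), ("log", "log", "identity")),
    "2-ToM": ModelSpec("2-ToM", ("sigma", "beta", "bias"), ("log", "log", "identity")),
    "3-ToM": ModelSpec("3-ToM", ("sigma", "beta", "bias"), ("log", "log", "identity")),
}
assert tuple(MODEL_SPECS) == MODEL_NAMES


# ------------------------------------------------------------- likelihoods

def session_log_likelihood(
    session: SessionRecord, model: str | ModelSpec, theta: np.ndarray
) -> float:
    """Sum over trials of log P(a_self_t | history_<t, theta, m).

    ``theta`` is in the unconstrained (transformed) space.  The focal player
    is the seeker; opponent actions and realised rewards are taken from the
    record, never re-simulated.
    """
    spec = MODEL_SPECS[model] if isinstance(model, str) else model
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (spec.n_params,):
        raise ValueError(
            f"theta must have shape ({spec.n_params},) for {spec.name}, got {theta.shape}"
        )
    pars = spec.to_natural(theta)
    a_self = session.a_self
    a_op = session.a_op
    rewards = session.rewards
    role = float(ROLE_SIGN[SEEKER])
    name = spec.name

    if name == "BN":
        # closed form: constant choice probability s(bias)
        p1 = float(_sigmoid(np.array([pars["bias"]]))[0])
        n1 = int(a_self.sum())
        return n1 * _bernoulli_ll(p1, 1) + (len(a_self) - n1) * _bernoulli_ll(p1, 0)

    if name in ("0-ToM", "1-ToM", "2-ToM", "3-ToM"):
        k = 0 if name == "0-ToM" else int(name[0])
        ll = _core.session_loglik_ktom(
            k,
            _core.init_state(k),
            a_self,
            a_op,
            pars["sigma"],
            pars["beta"],
            pars["bias"],
            role,
        )
        if not math.isfinite(ll):
            raise FloatingPointError(f"non-finite likelihood for {name}")
        return float(ll)

    beta = pars["beta"]
    bias = pars["bias"]
    if name == "WSLS":
        return float(_core.session_loglik_wsls(a_self, rewards, beta, bias))
    if name == "RL":
        return float(
            _core.session_loglik_rl(a_self, rewards, pars["alpha"], beta, bias)
        )
    if name == "Inf":
        from .agents import INFLUENCE_CLIP

        return float(
            _core.session_loglik_inf(
                a_self, a_op, pars["eta"], pars["influence_weight"], beta, bias,
                role, INFLUENCE_CLIP,
            )
        )
    raise ValueError(f"unknown model {name!r}")


# --------------------------------------------------------------- fitting

@dataclass(frozen=True)
class FitConfig:
    """Optimisation settings for the MAP + Laplace evidence approximation."""

    n_restarts: int = 8
    seed: int = 0
    maxiter: int = 200
    hessian_step: float = 1e-3
    bound: float = 8.0  # box on the unconstrained coordinates


@dataclass
class FitResult:
    model: str
    log_evidence: float
    map_parameters: np.ndarray
    map_natural: dict
    posterior_sd: np.ndarray
    log_likelihood: float
    diagnostics: dict = field(default_factory=dict)


def _neg_log_joint(theta, session, spec):
    ll = session_log_likelihood(session, spec, theta)
    log_prior = -0.5 * float(theta @ theta) - 0.5 * spec.n_params * _LOG_2PI
    return -(ll + log_prior)


def _fd_hessian(f, x, step):
    d = len(x)
    H = np.empty((d, d))
    f0 = f(x)
    for i in range(d):
        for j in range(i, d):
            ei = np.zeros(d)
            ej = np.zeros(d)
            ei[i] = step
            ej[j] = step
            if i == j:
                H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / step**2
            else:
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4.0 * step**2)
    return H


def fit_session(
    session: SessionRecord,
    model: str | ModelSpec,
    config: FitConfig = FitConfig(),
) -> FitResult:
    """MAP fit with multi-start L-BFGS-B and Laplace log evidence.

    log p(a|m) ~= log p(a|theta*) + log prior(theta*) + (d/2) log 2pi
    - 1/2 log det H, with H the Hessian of the negative log joint at the MAP.
    If H is not positive definite the evidence falls back to a BIC-style
    penalty and the result is flagged in the diagnostics.
    """
    spec = MODEL_SPECS[model] if isinstance(model, str) else model
    d = spec.n_params
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    starts = rng.standard_normal((config.n_restarts, d))
    bounds = [(-config.bound, config.bound)] * d

    best = None
    n_failed = 0
    for theta0 in starts:
        try:
            res = minimize(
                _neg_log_joint,
                theta0,
                args=(session, spec),
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": config.maxiter},
            )
        except FloatingPointError:
            n_failed += 1
            continue
        if not np.all(np.isfinite(res.x)) or not math.isfinite(res.fun):
            n_failed += 1
            continue
        # strict '<' keeps the first of equal-best optima by restart index
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError(
            f"all {config.n_restarts} restarts failed for model {spec.name}"
        )

    theta_star = best.x
    nlj_star = best.fun
    ll_star = session_log_likelihood(session, spec, theta_star)

    H = _fd_hessian(
        lambda th: _neg_log_joint(th, session, spec), theta_star, config.hessian_step
    )
    H = 0.5 * (H + H.T)
    evals = np.linalg.eigvalsh(H)
    diagnostics = {
        "optimizer_status": int(best.status),
        "n_restarts": int(config.n_restarts),
        "n_failed_restarts": int(n_failed),
        "hessian_pd": bool(evals.min() > 0),
        "bic_fallback": False,
        "clipped_at_zero": False,
    }
    if evals.min() > 0:
        log_evidence = (
            -nlj_star + 0.5 * d * _LOG_2PI - 0.5 * float(np.log(evals).sum())
        )
        posterior_sd = np.sqrt(np.diag(np.linalg.inv(H)))
    else:
        n = len(session.trials)
        log_evidence = ll_star - 0.5 * d * math.log(n)
        posterior_sd = np.full(d, np.nan)
        diagnostics["bic_fallback"] = True
    if log_evidence > 0.0:
        # the evidence of a binary sequence cannot exceed 1
        log_evidence = -1e-9
        diagnostics["clipped_at_zero"] = True

    return FitResult(
        model=spec.name,
        log_evidence=float(log_evidence),
        map_parameters=theta_star.copy(),
        map_natural=spec.to_natural(theta_star),
        posterior_sd=posterior_sd,
        log_likelihood=float(ll_star),
        diagnostics=diagnostics,
    )


# ---------------------------------------------------------- evidence matrix

@dataclass
class EvidenceMatrix:
    """Per-session x per-model log evidences as a tidy DataFrame.

    Columns: subject_id, opponent, framing, repetition, model, log_evidence.
    """

    df: pd.DataFrame

    KEY = ["subject_id", "opponent", "framing", "repetition"]

    def validate(self, models: tuple = MODEL_NAMES) -> None:
        counts = self.df.groupby(self.KEY)["model"].nunique()
        missing = counts[counts != len(models)]
        if len(missing):
            raise ValueError(
                f"incomplete evidence matrix: {len(missing)} sessions lack models "
                f"(first: {missing.index[0]})"
            )
        if not np.all(np.isfinite(self.df["log_evidence"].to_numpy())):
            raise ValueError("non-finite log evidence present")

    def session_evidences(self, subject_id, opponent, framing, repetition):
        sub = self.df[
            (self.df.subject_id == subject_id)
            & (self.df.opponent == opponent)
            & (self.df.framing == framing)
            & (self.df.repetition == str(repetition))
        ]
        s = sub.set_index("model")["log_evidence"]
        return s.reindex(list(MODEL_NAMES)).to_numpy()

    def posterior(self, subject_id, opponent, framing, repetition, prior=None):
        return model_posterior(
            self.session_evidences(subject_id, opponent, framing, repetition), prior
        )


def fit_cohort(
    sessions: list,
    models: tuple = MODEL_NAMES,
    config: FitConfig = FitConfig(),
    n_jobs: int = 1,
    progress: bool = False,
) -> EvidenceMatrix:
    """Fit every model to every session; returns the full evidence matrix.

    Deterministic given ``config.seed``: each (session, model) fit derives its
    restart seed from the base seed and its position.
    """

    def one(i, session, model):
        cfg = FitConfig(
            n_restarts=config.n_restarts,
            seed=int(
                np.random.SeedSequence(config.seed, spawn_key=(i,)).generate_state(1)[0]
                % (2**31 - 1)
            ),
            maxiter=config.maxiter,
            hessian_step=config.hessian_step,
            bound=config.bound,
        )
        fr = fit_session(session, model, cfg)
        return {
            "subject_id": session.subject_id,
            "opponent": session.opponent,
            "framing": session.framing,
            "repetition": str(session.repetition),
            "model": model,
            "log_evidence": fr.log_evidence,
        }

    tasks = [
        (i * len(models) + j, s, m)
        for i, s in enumerate(sessions)
        for j, m in enumerate(models)
    ]
    if n_jobs != 1:
        from joblib import Parallel, delayed

        rows = Parallel(n_jobs=n_jobs)(delayed(one)(*t) for t in tasks)
    else:
        rows = []
        it = tasks
        if progress:
            try:
                from tqdm import tqdm

                it = tqdm(tasks, desc="fitting")
            except ImportError:
                pass
        for t in it:
            rows.append(one(*t))
    em = EvidenceMatrix(pd.DataFrame(rows))
    em.validate(models)
    return em


def model_posterior(log_evidences: np.ndarray, prior: np.ndarray | None = None):
    """Posterior over models from log evidences (uniform prior by default).

    Computed stably via max-subtraction; invariant to adding a constant to all
    log evidences.
    """
    le = np.asarray(log_evidences, dtype=float)
    if le.ndim != 1 or not np.all(np.isfinite(le)):
        raise ValueError("log evidences must be a finite 1-D array")
    if prior is None:
        z = le
    else:
        prior = np.asarray(prior, dtype=float)
        if prior.shape != le.shape or np.any(prior < 0):
            raise ValueError("prior must be a nonnegative vector matching evidences")
        z = le + np.log(np.maximum(prior, 1e-300))
    z = z - z.max()
    w = np.exp(z)
    return w / w.sum()
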