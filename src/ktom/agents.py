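"""The eight adaptation strategies: RB, BN, WSLS, RL, influence learning, k-ToM.

Every agent exposes the same contract used by :func:`ktom.game.play_game` and
by the fitting code:

* ``predict_value_difference()`` — expected payoff difference dV for its role;
* ``act(rng)`` — sample an action from the shared softmax policy (the
  pseudo-random-bias opponent ignores the policy and follows its schedule);
* ``observe(a_self, a_op, reward)`` — trial-by-trial state update.

Update rules are also available as pure functions on small state objects
(``tom0_update``, ``influence_update``, ``rl_update``, ``wsls_update``,
``ktom_update``), which is the form the model-fitting code replays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _ktom_core as _core
from .game import (
    SEEKER,
    ROLE_SIGN,
    SoftmaxPolicy,
    choice_probability,
    expected_value_difference,
)

__all__ = [
    "MODEL_NAMES",
    "DEFAULT_PARAMS",
    "RBSchedule",
    "Tom0State",
    "KTomState",
    "InfluenceState",
    "RLState",
    "WSLSState",
    "tom0_update",
    "tom0_predict",
    "ktom_update",
    "ktom_predict",
    "ktom_simulate_level",
    "influence_update",
    "rl_update",
    "wsls_update",
    "agent_act",
    "make_agent",
]

#: canonical model order used everywhere (evidence matrices, repertoires)
MODEL_NAMES = ("BN", "WSLS", "RL", "0-ToM", "Inf", "1-ToM", "2-ToM", "3-ToM")

#: default generative parameters for synthetic agents, calibrated so that the
#: strategies are behaviourally distinguishable at 60 trials and reproduce the
#: documented competitive dynamics (mentalizers exploit frequency trackers;
#: influence learning beats 0-ToM but loses to k-ToM with k >= 1)
DEFAULT_PARAMS = {
    "beta": 0.25,
    "bias": 0.0,
    "sigma": 1.0,
    "eta": 0.3,
    "influence_weight": 0.5,
    "alpha": 0.7,
}

#: clipping constant keeping the influence learner's estimate inside (0, 1)
INFLUENCE_CLIP = 1e-4


# ====================================================================== RB

@dataclass(frozen=True)
class RBSchedule:
    """Predetermined pseudo-random sequence with a 65% bias for one option.

    Exactly round(0.65 * n) trials equal the preferred option, in a seeded
    shuffled order fixed before the game; the sequence never depends on the
    other player's actions.
    """

    sequence: tuple
    bias_level: float = 0.65

    @classmethod
    def generate(
        cls, n_trials: int = 60, preferred: int = 1, bias_level: float = 0.65,
        seed: int | np.random.Generator = 0,
    ) -> "RBSchedule":
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        n_pref = round(bias_level * n_trials)
        seq = np.full(n_trials, 1 - preferred, dtype=np.int64)
        seq[:n_pref] = preferred
        rng.shuffle(seq)
        return cls(sequence=tuple(int(a) for a in seq), bias_level=bias_level)


class RBAgent:
    """Non-reactive opponent following a fixed biased pseudo-random schedule."""

    name = "RB"

    def __init__(self, role: str = "hider", schedule: RBSchedule | None = None,
                 seed: int = 0, preferred: int = 1):
        self.role = role
        self.schedule = schedule or RBSchedule.generate(seed=seed, preferred=preferred)
        self._t = 0

    def act(self, rng=None) -> int:
        a = self.schedule.sequence[self._t]
        return a

    def observe(self, a_self: int, a_op: int, reward: int) -> None:
        self._t += 1


# ====================================================================== BN

class BNAgent:
    """Biased Nash: value difference pinned at zero, only the option bias acts."""

    name = "BN"

    def __init__(self, role: str = SEEKER, beta: float = 1.0, bias: float = 0.0):
        self.role = role
        self.policy = SoftmaxPolicy(beta=beta, bias=bias)

    def predict_value_difference(self) -> float:
        return 0.0

    def act(self, rng) -> int:
        return int(rng.random() < choice_probability(0.0, self.policy))

    def observe(self, a_self: int, a_op: int, reward: int) -> None:
        pass


# ==================================================================== WSLS

@dataclass(frozen=True)
class WSLSState:
    """Win-stay/lose-switch action values: +-R_signed on (chosen, unchosen).

    Rewards in {0, 1} are re-centred to a signed reward (+1 win, -1 loss) so
    the rule always yields a strict stay/switch preference whose determinism
    is set by the softmax temperature.
    """

    values: tuple = (0.0, 0.0)


def wsls_update(state: WSLSState, a_self: int, reward: int) -> WSLSState:
    r_signed = 1.0 if reward == 1 else -1.0
    v = [0.0, 0.0]
    v[a_self] = r_signed
    v[1 - a_self] = -r_signed
    return WSLSState(values=(v[0], v[1]))


# ====================================================================== RL

@dataclass(frozen=True)
class RLState:
    """Rescorla-Wagner action values; only the chosen action's value moves."""

    values: tuple = (0.0, 0.0)
    alpha: float = 0.7

    def __post_init__(self):
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError(f"alpha must lie in (0, 1], got {self.alpha}")


def rl_update(state: RLState, a_self: int, reward: int) -> RLState:
    v = list(state.values)
    v[a_self] = v[a_self] + state.alpha * (reward - v[a_self])
    return replace(state, values=(v[0], v[1]))


class _ValueAgent:
    """Shared machinery for agents that learn direct action values."""

    def __init__(self, role: str, beta: float, bias: float):
        self.role = role
        self.policy = SoftmaxPolicy(beta=beta, bias=bias)

    def predict_value_difference(self) -> float:
        v0, v1 = self.state.values
        return v1 - v0

    def act(self, rng) -> int:
        p1 = choice_probability(self.predict_value_difference(), self.policy)
        return int(rng.random() < p1)


class WSLSAgent(_ValueAgent):
    name = "WSLS"

    def __init__(self, role: str = SEEKER, beta: float = DEFAULT_PARAMS["beta"],
                 bias: float = 0.0):
        super().__init__(role, beta, bias)
        self.state = WSLSState()

    def observe(self, a_self: int, a_op: int, reward: int) -> None:
        self.state = wsls_update(self.state, a_self, reward)


class RLAgent(_ValueAgent):
    name = "RL"

    def __init__(self, role: str = SEEKER, alpha: float = DEFAULT_PARAMS["alpha"],
                 beta: float = DEFAULT_PARAMS["beta"], bias: float = 0.0):
        super().__init__(role, beta, bias)
        self.state = RLState(alpha=alpha)

    def observe(self, a_self: int, a_op: int, reward: int) -> None:
        self.state = rl_update(self.state, a_self, reward)


# =============================================================== influence

@dataclass(frozen=True)
class InfluenceState:
    """Opponent-frequency estimate with a self-influence correction.

    ``p_op`` tracks the opponent's probability of playing 1; ``eta`` weighs
    the prediction error, ``influence_weight`` the adjustment for how one's
    own action steers the opponent, and ``beta_inf`` is the temperature inside
    the influence term (shared with the decision softmax when fitted).
    """

    p_op: float = 0.5
    eta: float = 0.6
    influence_weight: float = 0.3
    beta_inf: float = DEFAULT_PARAMS["beta"]
    n_clips: int = 0


def influence_update(state: InfluenceState, a_op: int, a_self: int) -> InfluenceState:
    p = state.p_op
    logit_p = math.log(p / (1.0 - p))
    p_new = (
        p
        + state.eta * (a_op - p)
        + state.influence_weight
        * p
        * (1.0 - p)
        * (1.0 - 2.0 * a_self - state.beta_inf * logit_p)
    )
    clipped = p_new < INFLUENCE_CLIP or p_new > 1.0 - INFLUENCE_CLIP
    p_new = min(max(p_new, INFLUENCE_CLIP), 1.0 - INFLUENCE_CLIP)
    return replace(state, p_op=p_new, n_clips=state.n_clips + int(clipped))


class InfluenceAgent:
    name = "Inf"

    def __init__(self, role: str = SEEKER, eta: float = DEFAULT_PARAMS["eta"],
                 influence_weight: float = DEFAULT_PARAMS["influence_weight"],
                 beta: float = DEFAULT_PARAMS["beta"], bias: float = 0.0):
        self.role = role
        self.policy = SoftmaxPolicy(beta=beta, bias=bias)
        self.state = InfluenceState(
            eta=eta, influence_weight=influence_weight, beta_inf=beta
        )

    def predict_value_difference(self) -> float:
        return expected_value_difference(self.state.p_op, self.role)

    def act(self, rng) -> int:
        p1 = choice_probability(self.predict_value_difference(), self.policy)
        return int(rng.random() < p1)

    def observe(self, a_self: int, a_op: int, reward: int) -> None:
        self.state = influence_update(self.state, a_op=a_op, a_self=a_self)


# =================================================================== 0-ToM

@dataclass(frozen=True)
class Tom0State:
    """Gaussian belief (mu, sigma2) over the opponent's choice log-odds."""

    mu: float = 0.0
    sigma2: float = 1.0
    volatility: float = 1.0

    def __post_init__(self):
        if self.sigma2 <= 0 or self.volatility <= 0:
            raise ValueError("sigma2 and volatility must be strictly positive")


def tom0_update(state: Tom0State, a_op: int) -> Tom0State:
    """Laplace-style Bayes update: variance first, then the mean step."""
    if not (math.isfinite(state.mu) and math.isfinite(state.sigma2)):
        raise ValueError("non-finite 0-ToM state")
    p = 1.0 / (1.0 + math.exp(-state.mu))
    sig_new = 1.0 / (1.0 / (state.sigma2 + state.volatility) + p * (1.0 - p))
    mu_new = state.mu + sig_new * (a_op - p)
    return replace(state, mu=mu_new, sigma2=sig_new)


def tom0_predict(state: Tom0State) -> float:
    """Posterior expectation of s(x) under N(mu, sigma2 + volatility).

    Uses the probit-style moment closure s(mu / sqrt(1 + a v)), a = 3/pi^2;
    always strictly inside (0, 1).
    """
    return _core._sim0_predict(state.mu, state.sigma2, state.volatility)


class Tom0Agent:
    name = "0-ToM"

    def __init__(self, role: str = "hider", sigma: float = DEFAULT_PARAMS["sigma"],
                 beta: float = DEFAULT_PARAMS["beta"], bias: float = 0.0):
        self.role = role
        self.policy = SoftmaxPolicy(beta=beta, bias=bias)
        self.state = Tom0State(volatility=sigma)

    def predict_opponent(self) -> float:
        return tom0_predict(self.state)

    def predict_value_difference(self) -> float:
        return expected_value_difference(self.predict_opponent(), self.role)

    def act(self, rng) -> int:
        p1 = choice_probability(self.predict_value_difference(), self.policy)
        return int(rng.random() < p1)

    def observe(self, a_self: int, a_op: int, reward: int) -> None:
        self.state = tom0_update(self.state, a_op)


# =================================================================== k-ToM

@dataclass
class KTomState:
    """Flattened belief state of a k-ToM learner (see ktom._ktom_core).

    Accessors unpack the level posterior lambda and the per-level Gaussian
    beliefs (mu, Sigma) over the opponent's (log sigma, log beta).
    """

    k: int
    role: int  # +1 seeker, -1 hider
    volatility: float
    vec: np.ndarray = None
    history: list = field(default_factory=list)
    n_repairs: int = 0

    def __post_init__(self):
        if not 1 <= self.k <= 3:
            raise ValueError("k must be in {1, 2, 3}")
        if self.volatility <= 0:
            raise ValueError("volatility must be strictly positive")
        if self.vec is None:
            self.vec = _core.init_state(self.k)

    @property
    def level_posterior(self) -> np.ndarray:
        return self.vec[: self.k].copy()

    def level_mean(self, kappa: int) -> np.ndarray:
        mo = _core.LAYOUT[self.k][kappa][0]
        return self.vec[mo : mo + 2].copy()

    def level_cov(self, kappa: int) -> np.ndarray:
        so = _core.LAYOUT[self.k][kappa][1]
        return self.vec[so : so + 4].reshape(2, 2).copy()


def ktom_update(state: KTomState, a_op: int, a_self: int) -> KTomState:
    """Full Eq-style update: level posterior, Gaussian beliefs, replica banks."""
    vec = state.vec.copy()
    rep = _core.update_k(vec, state.k, state.volatility, float(state.role), a_self, a_op)
    return KTomState(
        k=state.k,
        role=state.role,
        volatility=state.volatility,
        vec=vec,
        history=state.history + [(a_self, a_op)],
        n_repairs=state.n_repairs + int(rep),
    )


def ktom_predict(state: KTomState) -> float:
    """lambda-weighted mixture of uncertainty-corrected level predictions."""
    return _core.predict_k(state.vec, state.k, state.volatility, float(state.role))


def ktom_simulate_level(kappa, x, a_self, a_op, role=SEEKER):
    """Replay definition of the level prediction (see _ktom_reference)."""
    from ._ktom_reference import simulate_level

    role_sign = ROLE_SIGN[role] if isinstance(role, str) else int(role)
    return simulate_level(kappa, np.asarray(x, float), np.asarray(a_self),
                          np.asarray(a_op), role_sign)


class KTomAgent:
    """Mentalizing learner of sophistication k in {1, 2, 3}."""

    def __init__(self, k: int, role: str = "hider",
                 sigma: float = DEFAULT_PARAMS["sigma"],
                 beta: float = DEFAULT_PARAMS["beta"], bias: float = 0.0):
        self.name = f"{k}-ToM"
        self.k = k
        self.role = role
        self._role_sign = float(ROLE_SIGN[role])
        self.sigma = float(sigma)
        self.policy = SoftmaxPolicy(beta=beta, bias=bias)
        self.vec = _core.init_state(k)
        self.n_repairs = 0

    @property
    def state(self) -> KTomState:
        return KTomState(
            k=self.k,
            role=int(self._role_sign),
            volatility=self.sigma,
            vec=self.vec.copy(),
            n_repairs=self.n_repairs,
        )

    def predict_opponent(self) -> float:
        return _core.predict_k(self.vec, self.k, self.sigma, self._role_sign)

    def predict_value_difference(self) -> float:
        return expected_value_difference(self.predict_opponent(), self.role)

    def act(self, rng) -> int:
        p1 = choice_probability(self.predict_value_difference(), self.policy)
        return int(rng.random() < p1)

    def observe(self, a_self: int, a_op: int, reward: int) -> None:
        self.n_repairs += int(
            _core.update_k(self.vec, self.k, self.sigma, self._role_sign, a_self, a_op)
        )


# ================================================================= factory

def agent_act(agent, rng) -> int:
    """Sample one action from an agent's policy (RB ignores the rng)."""
    return agent.act(rng)


def make_agent(name: str, role: str = SEEKER, seed: int = 0, **params):
    """Instantiate any of the eight strategies (plus RB) by model name.

    Unknown parameter keys are rejected so configuration typos fail loudly.
    """
    p = dict(DEFAULT_PARAMS)
    unknown = set(params) - {
        "beta", "bias", "sigma", "eta", "influence_weight", "alpha", "preferred",
    }
    if unknown:
        raise ValueError(f"unknown agent parameters for {name!r}: {sorted(unknown)}")
    p.update(params)
    if name == "RB":
        return RBAgent(role=role, seed=seed, preferred=p.get("preferred", 1))
    if name == "BN":
        return BNAgent(role=role, bias=p["bias"])
    if name == "WSLS":
        return WSLSAgent(role=role, beta=p["beta"], bias=p["bias"])
    if name == "RL":
        return RLAgent(role=role, alpha=p["alpha"], beta=p["beta"], bias=p["bias"])
    if name == "Inf":
        return InfluenceAgent(
            role=role, eta=p["eta"], influence_weight=p["influence_weight"],
            beta=p["beta"], bias=p["bias"],
        )
    if name == "0-ToM":
        return Tom0Agent(role=role, sigma=p["sigma"], beta=p["beta"], bias=p["bias"])
    if name in ("1-ToM", "2-ToM", "3-ToM"):
        k = int(name[0])
        return KTomAgent(k=k, role=role, sigma=p["sigma"], beta=p["beta"],
                         bias=p["bias"])
    raise ValueError(f"unknown model name {name!r}")
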