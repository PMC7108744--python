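"""Competitive hide-and-seek game: payoffs, softmax policy, sessions, performance.

The game is a repeated two-player matching-pennies variant: on every trial the
hider picks one of two locations and the seeker guesses one.  The seeker wins
the trial iff the guesses match; payoffs are zero-sum complementary (one point
is awarded per trial, to exactly one player).  All value-based agents share a
single decision rule, a softmax (logistic) policy on the expected payoff
difference between the two options plus an additive option bias.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HIDER",
    "SEEKER",
    "OPPONENTS",
    "FRAMINGS",
    "REPETITIONS",
    "PayoffTable",
    "SoftmaxPolicy",
    "TrialRecord",
    "SessionRecord",
    "expected_value_difference",
    "choice_probability",
    "play_game",
    "net_correct_rate",
]

SEEKER = "seeker"
HIDER = "hider"

#: condition label sets for one experimental session
OPPONENTS = ("RB", "0-ToM", "1-ToM", "2-ToM")
FRAMINGS = ("social", "non-social")
REPETITIONS = ("1", "2")

#: role sign used throughout: seeker -> +1 (wants to match), hider -> -1
ROLE_SIGN = {SEEKER: +1, HIDER: -1}


def _role_sign(role: str) -> int:
    try:
        return ROLE_SIGN[role]
    except KeyError:
        raise ValueError(f"role must be 'seeker' or 'hider', got {role!r}") from None


@dataclass(frozen=True)
class PayoffTable:
    """Player-specific utilities U(a_self, a_op) of the competitive game.

    ``utilities[(role, a_self, a_op)]`` is the payoff (0 or 1) of the focal
    player.  The default table is the standard hide-and-seek one: the seeker
    wins iff actions match, the hider iff they differ, and every cell is
    zero-sum complementary (hider payoff + seeker payoff = 1).
    """

    utilities: dict = field(
        default_factory=lambda: {
            (role, a_self, a_op): (
                int(a_self == a_op) if role == SEEKER else int(a_self != a_op)
            )
            for role in (SEEKER, HIDER)
            for a_self in (0, 1)
            for a_op in (0, 1)
        }
    )

    def payoff(self, role: str, a_self: int, a_op: int) -> int:
        _role_sign(role)
        return self.utilities[(role, a_self, a_op)]

    def validate(self) -> None:
        """Check zero-sum complementarity and the win conditions."""
        for a_h in (0, 1):
            for a_s in (0, 1):
                u_h = self.utilities[(HIDER, a_h, a_s)]
                u_s = self.utilities[(SEEKER, a_s, a_h)]
                if u_h + u_s != 1:
                    raise ValueError(
                        f"payoff table not zero-sum complementary at "
                        f"(hider={a_h}, seeker={a_s}): {u_h} + {u_s} != 1"
                    )
                if u_s != int(a_s == a_h):
                    raise ValueError("seeker must win exactly when actions match")


#: module-level default table shared by every agent
DEFAULT_PAYOFFS = PayoffTable()
DEFAULT_PAYOFFS.validate()


@dataclass(frozen=True)
class SoftmaxPolicy:
    """Softmax (logistic) decision rule on the value difference.

    P(a=1) = 1 / (1 + exp(-(dV + bias) / beta)).  ``beta`` is the behavioural
    temperature (>0, dimensionless): small beta means near-deterministic value
    maximisation, large beta means near-random choice.  ``bias`` is an additive
    preference for option 1 on the value-difference scale.
    """

    beta: float = 1.0
    bias: float = 0.0

    def __post_init__(self) -> None:
        if not (self.beta > 0 and math.isfinite(self.beta)):
            raise ValueError(f"beta must be strictly positive, got {self.beta}")
        if not math.isfinite(self.bias):
            raise ValueError(f"bias must be finite, got {self.bias}")


def expected_value_difference(p_op: float, role: str) -> float:
    """Expected payoff difference between own actions 1 and 0.

    ``p_op`` is the probability that the opponent plays action 1.  Under the
    competitive payoff table the seeker's difference is 2*p_op - 1 (match the
    opponent) and the hider's is 1 - 2*p_op (avoid them); the two roles are
    exactly anti-symmetric.
    """
    if not (0.0 <= p_op <= 1.0):
        raise ValueError(f"p_op must lie in [0, 1], got {p_op}")
    return _role_sign(role) * (2.0 * p_op - 1.0)


def choice_probability(delta_v: float, policy: SoftmaxPolicy) -> float:
    """P(a=1) under the softmax policy; strictly inside (0, 1) for finite input."""
    z = (delta_v + policy.bias) / policy.beta
    # numerically stable logistic
    if z >= 0:
        p = 1.0 / (1.0 + math.exp(-z))
    else:
        ez = math.exp(z)
        p = ez / (1.0 + ez)
    tiny = 1e-15
    return min(max(p, tiny), 1.0 - tiny)


@dataclass(frozen=True)
class TrialRecord:
    """One trial from the focal player's perspective (1-based index)."""

    index: int
    a_self: int
    a_op: int
    reward: int

    def validate(self, role: str, payoffs: PayoffTable = DEFAULT_PAYOFFS) -> None:
        if self.a_self not in (0, 1) or self.a_op not in (0, 1):
            raise ValueError(f"trial {self.index}: actions must be 0/1")
        expected = payoffs.payoff(role, self.a_self, self.a_op)
        if self.reward != expected:
            raise ValueError(
                f"trial {self.index}: reward {self.reward} inconsistent with "
                f"payoff table ({expected} expected for role {role!r})"
            )


N_TRIALS = 60


@dataclass
class SessionRecord:
    """One 60-trial game plus its condition labels, focal player = seeker."""

    subject_id: str
    opponent: str
    framing: str
    repetition: str
    trials: list

    def validate(self, n_trials: int = N_TRIALS) -> None:
        if self.opponent not in OPPONENTS:
            raise ValueError(f"unknown opponent label {self.opponent!r}")
        if self.framing not in FRAMINGS:
            raise ValueError(f"unknown framing label {self.framing!r}")
        if str(self.repetition) not in REPETITIONS:
            raise ValueError(f"unknown repetition label {self.repetition!r}")
        if len(self.trials) != n_trials:
            raise ValueError(
                f"session {self.subject_id}/{self.opponent}/{self.framing}/"
                f"{self.repetition}: expected {n_trials} trials, got {len(self.trials)}"
            )
        for i, tr in enumerate(self.trials, start=1):
            if tr.index != i:
                raise ValueError(
                    f"trial indices must be 1..{n_trials} strictly increasing; "
                    f"position {i} has index {tr.index}"
                )
            tr.validate(SEEKER)

    @property
    def a_self(self) -> np.ndarray:
        return np.array([t.a_self for t in self.trials], dtype=np.int64)

    @property
    def a_op(self) -> np.ndarray:
        return np.array([t.a_op for t in self.trials], dtype=np.int64)

    @property
    def rewards(self) -> np.ndarray:
        return np.array([t.reward for t in self.trials], dtype=np.int64)

    @property
    def condition(self) -> tuple:
        return (self.opponent, self.framing, str(self.repetition))


def play_game(
    agent_self,
    agent_op,
    n_trials: int = N_TRIALS,
    seed: int | np.random.Generator = 0,
    *,
    subject_id: str = "sim",
    opponent: str = "0-ToM",
    framing: str = "social",
    repetition: str = "1",
    payoffs: PayoffTable = DEFAULT_PAYOFFS,
) -> SessionRecord:
    """Simulate a repeated game between two agents; simultaneous moves.

    ``agent_self`` plays the seeker and ``agent_op`` the hider (the roles the
    agents were constructed with must match).  After each trial both agents
    observe both actions.  Identical seed gives a bit-identical record.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    trials = []
    for t in range(1, n_trials + 1):
        a_s = agent_self.act(rng)
        a_o = agent_op.act(rng)
        reward = payoffs.payoff(agent_self.role, a_s, a_o)
        try:
            agent_self.observe(a_self=a_s, a_op=a_o, reward=reward)
            agent_op.observe(
                a_self=a_o, a_op=a_s, reward=payoffs.payoff(agent_op.role, a_o, a_s)
            )
        except Exception as exc:  # annotate with the trial index and re-raise
            raise RuntimeError(f"agent update failed at trial {t}: {exc}") from exc
        trials.append(TrialRecord(index=t, a_self=a_s, a_op=a_o, reward=reward))
    return SessionRecord(
        subject_id=subject_id,
        opponent=opponent,
        framing=framing,
        repetition=repetition,
        trials=trials,
    )


def net_correct_rate(session: SessionRecord) -> float:
    """(n_correct - n_incorrect) / n_trials for the focal player.

    Equals 2*(fraction of rewarded trials) - 1: +1 when every trial is won,
    0 at chance, -1 when every trial is lost.
    """
    n = len(session.trials)
    if n == 0:
        raise ValueError("net_correct_rate undefined for an empty session")
    n_c = int(sum(t.reward for t in session.trials))
    return (n_c - (n - n_c)) / n
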