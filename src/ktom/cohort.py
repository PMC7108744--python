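"""Synthetic cohort generator: ground-truth participants, sessions, symptoms.

Each synthetic participant owns a *behavioural repertoire*: one probability
distribution over the eight strategies per framing condition.  For every
opponent condition a strategy is drawn from the social-framing repertoire;
the matched non-social session keeps that strategy with probability
1 - switch_rate_framing (otherwise it is re-drawn from the non-social
repertoire), and the second repetition of each framing re-draws with
probability switch_rate_repetition.  The drawn strategy then plays 60 trials
against the condition's opponent.

Group profiles emulate the qualitative structure reported for autistic-like
(AS) and neurotypical-like (NT) adults: AS participants are dominated by
influence learning in both framings with low switch rates, NT participants
lean on simple non-mentalizing strategies in the non-social framing but
recruit recursive mentalizers when they know they face an intentional
opponent.  AS participants additionally carry a graded "NT-likeness" latent
u in [0, 1] (Beta-distributed) that tilts their social repertoire toward the
NT social profile and raises their switch rates: without such inter-individual
variation, phenotype-symptom regressions would have no signal to recover,
whereas the analysis this package supports is precisely that phenotype
variation predicts symptom severity.

Symptom scores are generated from the participant's *true* phenotype
contrasts: social = b0 + b_k * dk_true + b_f * df_true + noise (truncated at
zero), with the stereotyped-behaviour score pure noise, independent of the
phenotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .agents import DEFAULT_PARAMS, MODEL_NAMES, make_agent
from .game import FRAMINGS, OPPONENTS, REPETITIONS, SEEKER, SessionRecord, play_game

__all__ = [
    "GroupProfile",
    "SymptomModel",
    "CohortSpec",
    "SyntheticParticipant",
    "draw_participant",
    "generate_cohort",
    "true_phenotypes",
    "AS_PROFILE",
    "NT_PROFILE",
]

_M = {name: i for i, name in enumerate(MODEL_NAMES)}


def _simplex(weights: dict) -> np.ndarray:
    v = np.zeros(len(MODEL_NAMES))
    for name, w in weights.items():
        v[_M[name]] = w
    if not np.isclose(v.sum(), 1.0):
        raise ValueError(f"repertoire weights sum to {v.sum()}, not 1")
    if np.any(v < 0):
        raise ValueError("repertoire weights must be nonnegative")
    return v


#: base repertoires; order follows MODEL_NAMES
AS_BASE = _simplex(
    {"BN": 0.02, "WSLS": 0.04, "RL": 0.04, "0-ToM": 0.06, "Inf": 0.75,
     "1-ToM": 0.05, "2-ToM": 0.02, "3-ToM": 0.02}
)
NT_SOCIAL_BASE = _simplex(
    {"BN": 0.02, "WSLS": 0.04, "RL": 0.04, "0-ToM": 0.08, "Inf": 0.10,
     "1-ToM": 0.40, "2-ToM": 0.30, "3-ToM": 0.02}
)
NT_NONSOCIAL_BASE = _simplex(
    {"BN": 0.04, "WSLS": 0.25, "RL": 0.30, "0-ToM": 0.25, "Inf": 0.08,
     "1-ToM": 0.04, "2-ToM": 0.02, "3-ToM": 0.02}
)


@dataclass(frozen=True)
class GroupProfile:
    """Generative settings for one group's repertoires and switch rates."""

    social_base: np.ndarray
    nonsocial_base: np.ndarray
    switch_rate_repetition: float
    switch_rate_framing: float
    dirichlet_concentration: float = 8.0
    #: Beta(a, b) of the per-participant NT-likeness latent u (AS group);
    #: (0, 0) disables the latent (u = 0 for everyone)
    nt_likeness_beta: tuple = (0.0, 0.0)
    #: how strongly u raises the switch rates
    u_framing_gain: float = 1.0
    u_repetition_gain: float = 0.55


AS_PROFILE = GroupProfile(
    social_base=AS_BASE,
    nonsocial_base=AS_BASE,
    switch_rate_repetition=0.08,
    switch_rate_framing=0.0,
    nt_likeness_beta=(0.8, 2.5),
)
NT_PROFILE = GroupProfile(
    social_base=NT_SOCIAL_BASE,
    nonsocial_base=NT_NONSOCIAL_BASE,
    switch_rate_repetition=0.30,
    switch_rate_framing=1.0,
)


@dataclass(frozen=True)
class SymptomModel:
    """Linear map from true phenotype contrasts to the social subscore."""

    intercept: float = 10.0
    coef_delta_k: float = -3.0
    coef_delta_f: float = -5.0
    noise_sd: float = 1.5
    stereotyped_mean: float = 8.0
    stereotyped_sd: float = 2.5

    def __post_init__(self):
        if self.noise_sd < 0 or self.stereotyped_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters of a synthetic cohort (24 + 24 by default)."""

    n_per_group: int = 24
    seed: int = 0
    as_profile: GroupProfile = AS_PROFILE
    nt_profile: GroupProfile = NT_PROFILE
    symptom_model: SymptomModel = SymptomModel()
    agent_params: dict = field(default_factory=lambda: dict(DEFAULT_PARAMS))
    n_trials: int = 60

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")


@dataclass
class SyntheticParticipant:
    """Ground truth for one simulated participant."""

    subject_id: str
    group: str  # "AS" or "NT"
    repertoire_social: np.ndarray
    repertoire_nonsocial: np.ndarray
    switch_rate_repetition: float
    switch_rate_framing: float
    nt_likeness: float
    strategy_params: dict
    symptom_social: int = 0
    symptom_stereotyped: int = 0
    true_delta_k: float = 0.0
    true_delta_f: float = 0.0

    def validate(self) -> None:
        for rep in (self.repertoire_social, self.repertoire_nonsocial):
            if rep.shape != (len(MODEL_NAMES),) or np.any(rep < 0):
                raise ValueError("repertoire must be a nonnegative 8-vector")
            if abs(rep.sum() - 1.0) > 1e-9:
                raise ValueError("repertoire must sum to 1")
        for s in (self.switch_rate_repetition, self.switch_rate_framing):
            if not 0.0 <= s <= 1.0:
                raise ValueError("switch rates must lie in [0, 1]")


def _tom_depth(rep: np.ndarray) -> float:
    """Expected recursion depth of a repertoire (non-ToM strategies count 0)."""
    return float(
        1 * rep[_M["1-ToM"]] + 2 * rep[_M["2-ToM"]] + 3 * rep[_M["3-ToM"]]
    )


def true_phenotypes(p: SyntheticParticipant) -> tuple:
    """(delta_k, delta_f) implied by the participant's generative settings.

    delta_k: expected depth difference between social sessions and the
    effective non-social mixture (the non-social strategy equals the social
    one unless re-drawn).  delta_f: probability the strategies differ across
    framings minus the mean probability they differ across repetitions.
    """
    sf = p.switch_rate_framing
    sr = p.switch_rate_repetition
    ps, pn = p.repertoire_social, p.repertoire_nonsocial
    k_soc = _tom_depth(ps)
    k_ns_eff = (1.0 - sf) * k_soc + sf * _tom_depth(pn)
    delta_k = k_soc - k_ns_eff
    f_framing = sf * (1.0 - float(ps @ pn))
    f_rep = sr * 0.5 * ((1.0 - float(ps @ ps)) + (1.0 - float(pn @ pn)))
    delta_f = f_framing - f_rep
    return delta_k, delta_f


def draw_participant(
    spec: CohortSpec, group: str, rng: np.random.Generator, index: int = 0
) -> SyntheticParticipant:
    """Draw one participant's repertoires, switch rates and symptom scores."""
    profile = spec.as_profile if group == "AS" else spec.nt_profile
    a, b = profile.nt_likeness_beta
    u = float(rng.beta(a, b)) if a > 0 and b > 0 else 0.0

    social_base = (1.0 - u) * profile.social_base + u * NT_SOCIAL_BASE
    nonsocial_base = profile.nonsocial_base
    conc = profile.dirichlet_concentration
    # Dirichlet jitter around the base mix models idiosyncratic preferences
    rep_soc = rng.dirichlet(conc * social_base + 1e-3)
    rep_ns = rng.dirichlet(conc * nonsocial_base + 1e-3)

    sw_rep = float(
        np.clip(profile.switch_rate_repetition + profile.u_repetition_gain * u, 0, 1)
    )
    sw_fra = float(
        np.clip(profile.switch_rate_framing + profile.u_framing_gain * u, 0, 1)
    )

    part = SyntheticParticipant(
        subject_id=f"{group}{index:03d}",
        group=group,
        repertoire_social=rep_soc,
        repertoire_nonsocial=rep_ns,
        switch_rate_repetition=sw_rep,
        switch_rate_framing=sw_fra,
        nt_likeness=u,
        strategy_params=dict(spec.agent_params),
    )
    part.validate()

    dk, df = true_phenotypes(part)
    part.true_delta_k = dk
    part.true_delta_f = df
    sm = spec.symptom_model
    social = (
        sm.intercept
        + sm.coef_delta_k * dk
        + sm.coef_delta_f * df
        + (sm.noise_sd * rng.standard_normal() if sm.noise_sd > 0 else 0.0)
    )
    part.symptom_social = int(max(0, round(social)))
    part.symptom_stereotyped = int(
        max(0, round(sm.stereotyped_mean + sm.stereotyped_sd * rng.standard_normal()))
    )
    return part


def _strategy_agent(name: str, params: dict, rng: np.random.Generator):
    kw = {}
    if name != "BN":
        kw["beta"] = params["beta"]
    if name in ("0-ToM", "1-ToM", "2-ToM", "3-ToM"):
        kw["sigma"] = params["sigma"]
    if name == "Inf":
        kw["eta"] = params["eta"]
        kw["influence_weight"] = params["influence_weight"]
    if name == "RL":
        kw["alpha"] = params["alpha"]
    kw["bias"] = params.get("bias", 0.0)
    if name == "RB":  # only used as an opponent
        kw = {}
    return make_agent(
        name,
        role=SEEKER if name != "RB" else "hider",
        seed=int(rng.integers(2**31 - 1)),
        **kw,
    )


def _opponent_agent(name: str, params: dict, rng: np.random.Generator):
    if name == "RB":
        return make_agent(
            "RB", role="hider", seed=int(rng.integers(2**31 - 1)),
            preferred=int(rng.integers(2)),
        )
    kw = dict(beta=params["beta"], bias=0.0)
    if name in ("0-ToM", "1-ToM", "2-ToM"):
        kw["sigma"] = params["sigma"]
    return make_agent(name, role="hider", **kw)


def generate_cohort(spec: CohortSpec):
    """Simulate the full cohort: participants, 16 sessions each, ground truth.

    Returns ``(participants, sessions, truth)`` where ``truth`` maps
    (subject_id, opponent, framing, repetition) -> generating strategy name.
    Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    participants: list[SyntheticParticipant] = []
    sessions: list[SessionRecord] = []
    truth: dict = {}

    for group, n in (("AS", spec.n_per_group), ("NT", spec.n_per_group)):
        for i in range(n):
            part = draw_participant(spec, group, rng, index=i)
            participants.append(part)
            # one strategy table per participant: strategy[(opponent, framing, rep)]
            for opponent in OPPONENTS:
                m_soc1 = _draw(rng, part.repertoire_social)
                if rng.random() < part.switch_rate_framing:
                    m_ns1 = _draw(rng, part.repertoire_nonsocial)
                else:
                    m_ns1 = m_soc1
                m_soc2 = (
                    _draw(rng, part.repertoire_social)
                    if rng.random() < part.switch_rate_repetition
                    else m_soc1
                )
                m_ns2 = (
                    _draw(rng, part.repertoire_nonsocial)
                    if rng.random() < part.switch_rate_repetition
                    else m_ns1
                )
                chosen = {
                    ("social", "1"): m_soc1,
                    ("social", "2"): m_soc2,
                    ("non-social", "1"): m_ns1,
                    ("non-social", "2"): m_ns2,
                }
                for (framing, repetition), strategy in chosen.items():
                    agent = _strategy_agent(strategy, part.strategy_params, rng)
                    opp = _opponent_agent(opponent, part.strategy_params, rng)
                    sess = play_game(
                        agent,
                        opp,
                        spec.n_trials,
                        seed=np.random.default_rng(rng.integers(2**31 - 1)),
                        subject_id=part.subject_id,
                        opponent=opponent,
                        framing=framing,
                        repetition=repetition,
                    )
                    sessions.append(sess)
                    truth[(part.subject_id, opponent, framing, repetition)] = strategy
    return participants, sessions, truth


def _draw(rng: np.random.Generator, simplex: np.ndarray) -> str:
    return MODEL_NAMES[int(rng.choice(len(MODEL_NAMES), p=simplex))]


def participants_frame(participants: list) -> pd.DataFrame:
    """Cohort metadata table (one row per participant)."""
    return pd.DataFrame(
        {
            "subject_id": [p.subject_id for p in participants],
            "group": [p.group for p in participants],
            "symptom_social": [p.symptom_social for p in participants],
            "symptom_stereotyped": [p.symptom_stereotyped for p in participants],
            "true_delta_k": [p.true_delta_k for p in participants],
            "true_delta_f": [p.true_delta_f for p in participants],
            "nt_likeness": [p.nt_likeness for p in participants],
        }
    )
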