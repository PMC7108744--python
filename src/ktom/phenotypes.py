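"""Computational phenotypes: repertoire flexibility and ToM sophistication.

Flexibility between two conditions is the posterior probability that the
participant used *different* strategies in them,

    f(1,2) = 1 - sum_m p(m | a^(1)) p(m | a^(2)),

computed from the per-session model posteriors.  ToM sophistication is the
posterior-expected recursion depth,

    k = sum_k k * p(m = k-ToM | a),

summed over the k-ToM members of the full eight-model posterior (non-ToM
strategies contribute zero depth).  By default the posterior is *not*
renormalised over the ToM subset; ``renormalize=True`` provides the
renormalised variant for sensitivity analyses.

A participant's profile averages flexibility over matched session pairs
(everything but the contrasted factor held constant) and sophistication over
the eight sessions of each framing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .agents import MODEL_NAMES
from .game import FRAMINGS, OPPONENTS, REPETITIONS
from .inference import EvidenceMatrix

__all__ = [
    "PhenotypeProfile",
    "flexibility",
    "tom_sophistication",
    "participant_profile",
    "cohort_profiles",
]

_TOM_DEPTH = np.array(
    [0, 0, 0, 0, 0, 1, 2, 3], dtype=float
)  # depth per model in MODEL_NAMES order
assert MODEL_NAMES[5:] == ("1-ToM", "2-ToM", "3-ToM")


@dataclass(frozen=True)
class PhenotypeProfile:
    """Per-participant phenotypes and their contrasts.

    ``delta_f`` (the flexibility gap) and ``delta_k`` are exactly
    ``f_framing - f_repetitions`` and ``k_social - k_nonsocial``.
    """

    subject_id: str
    f_framing: float
    f_repetitions: float
    k_social: float
    k_nonsocial: float

    @property
    def delta_f(self) -> float:
        return self.f_framing - self.f_repetitions

    @property
    def delta_k(self) -> float:
        return self.k_social - self.k_nonsocial

    def validate(self) -> None:
        for f in (self.f_framing, self.f_repetitions):
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"flexibility {f} outside [0, 1]")
        for k in (self.k_social, self.k_nonsocial):
            if not 0.0 <= k <= 3.0:
                raise ValueError(f"sophistication {k} outside [0, 3]")


def flexibility(posterior_1: np.ndarray, posterior_2: np.ndarray) -> float:
    """1 - overlap of two model posteriors; 0 iff identical point masses."""
    p1 = np.asarray(posterior_1, dtype=float)
    p2 = np.asarray(posterior_2, dtype=float)
    if p1.shape != p2.shape or p1.ndim != 1:
        raise ValueError("posteriors must be 1-D over the same model set")
    return float(1.0 - p1 @ p2)


def tom_sophistication(posterior: np.ndarray, renormalize: bool = False) -> float:
    """Expected recursion depth under the model posterior (in [0, 3])."""
    p = np.asarray(posterior, dtype=float)
    if p.shape != (len(MODEL_NAMES),):
        raise ValueError(f"posterior must cover the {len(MODEL_NAMES)}-model set")
    mass = float(p @ _TOM_DEPTH)
    if renormalize:
        tom_mass = float(p[_TOM_DEPTH > 0].sum() + p[3])  # include 0-ToM at depth 0
        return mass / tom_mass if tom_mass > 0 else 0.0
    return mass


def participant_profile(
    evidence: EvidenceMatrix,
    subject_id: str,
    include_rb: bool = True,
    renormalize: bool = False,
) -> PhenotypeProfile:
    """Phenotypes for one participant from their 16 session posteriors.

    f_framing averages flexibility over the 8 matched (opponent, repetition)
    pairs contrasting social vs non-social; f_repetitions over the 8 matched
    (opponent, framing) pairs contrasting the two repetitions; k_social and
    k_nonsocial average sophistication over each framing's 8 sessions.
    ``include_rb=False`` drops the random-bias opponent from all averages.
    """
    opponents = OPPONENTS if include_rb else tuple(o for o in OPPONENTS if o != "RB")
    post = {}
    missing = []
    for opp in opponents:
        for fra in FRAMINGS:
            for rep in REPETITIONS:
                try:
                    post[(opp, fra, rep)] = evidence.posterior(
                        subject_id, opp, fra, rep
                    )
                except Exception:
                    missing.append((opp, fra, rep))
    if missing:
        raise ValueError(
            f"subject {subject_id}: missing conditions {missing}"
        )
    f_fra = float(
        np.mean(
            [
                flexibility(post[(o, "social", r)], post[(o, "non-social", r)])
                for o in opponents
                for r in REPETITIONS
            ]
        )
    )
    f_rep = float(
        np.mean(
            [
                flexibility(post[(o, f, "1")], post[(o, f, "2")])
                for o in opponents
                for f in FRAMINGS
            ]
        )
    )
    k_soc = float(
        np.mean(
            [
                tom_sophistication(post[(o, "social", r)], renormalize)
                for o in opponents
                for r in REPETITIONS
            ]
        )
    )
    k_ns = float(
        np.mean(
            [
                tom_sophistication(post[(o, "non-social", r)], renormalize)
                for o in opponents
                for r in REPETITIONS
            ]
        )
    )
    prof = PhenotypeProfile(
        subject_id=subject_id,
        f_framing=f_fra,
        f_repetitions=f_rep,
        k_social=k_soc,
        k_nonsocial=k_ns,
    )
    prof.validate()
    return prof


def cohort_profiles(
    evidence: EvidenceMatrix,
    groups: dict | None = None,
    include_rb: bool = True,
    renormalize: bool = False,
) -> pd.DataFrame:
    """Phenotype table for every subject in the evidence matrix."""
    rows = []
    for sid in sorted(evidence.df["subject_id"].unique()):
        prof = participant_profile(evidence, sid, include_rb, renormalize)
        rows.append(
            {
                "subject_id": sid,
                "group": (groups or {}).get(sid, ""),
                "f_framing": prof.f_framing,
                "f_repetitions": prof.f_repetitions,
                "k_social": prof.k_social,
                "k_nonsocial": prof.k_nonsocial,
                "delta_f": prof.delta_f,
                "delta_k": prof.delta_k,
            }
        )
    return pd.DataFrame(rows)
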