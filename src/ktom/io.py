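"""File formats: session/cohort CSVs, evidence TSV, ground truth and config JSON.

Everything is plain text and human-inspectable; a cohort is ~46k CSV rows.
``read_sessions``/``write_sessions`` round-trip exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .game import FRAMINGS, OPPONENTS, REPETITIONS, SessionRecord, TrialRecord
from .inference import EvidenceMatrix

__all__ = [
    "RunConfig",
    "read_sessions",
    "write_sessions",
    "write_cohort_table",
    "read_cohort_table",
    "write_truth",
    "read_truth",
    "write_evidence",
    "read_evidence",
]

SESSION_COLUMNS = [
    "subject_id",
    "opponent",
    "framing",
    "repetition",
    "trial",
    "a_self",
    "a_op",
    "reward",
]


@dataclass
class RunConfig:
    """Serializable configuration of a pipeline run.

    Unknown keys in a config file are rejected so typos fail loudly; the
    config (with the seed) is echoed verbatim into every output directory.
    """

    seed: int = 0
    n_per_group: int = 24
    n_trials: int = 60
    n_restarts: int = 2
    maxiter: int = 100
    n_permutations: int = 1000
    include_rb: bool = True
    outdir: str = "ktom-output"
    agent_params: dict = field(default_factory=dict)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def write_sessions(sessions: list, path) -> None:
    """One CSV row per trial, header mandatory, actions coded 0/1."""
    rows = []
    for s in sessions:
        for t in s.trials:
            rows.append(
                (s.subject_id, s.opponent, s.framing, str(s.repetition),
                 t.index, t.a_self, t.a_op, t.reward)
            )
    pd.DataFrame(rows, columns=SESSION_COLUMNS).to_csv(path, index=False)


def read_sessions(path, n_trials: int = 60) -> list:
    """Parse and validate a session CSV; raises naming the offending rows."""
    df = pd.read_csv(path, dtype={"repetition": str})
    missing = set(SESSION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"session CSV lacks columns: {sorted(missing)}")
    bad = df[~df["a_self"].isin([0, 1]) | ~df["a_op"].isin([0, 1])]
    if len(bad):
        raise ValueError(
            f"actions outside {{0,1}} at CSV rows {list(bad.index[:5])}"
        )
    key = ["subject_id", "opponent", "framing", "repetition"]
    dup = df.duplicated(subset=key + ["trial"])
    if dup.any():
        raise ValueError(
            f"duplicate (subject, condition, trial) keys at rows "
            f"{list(df.index[dup][:5])}"
        )
    sessions = []
    for (sid, opp, fra, rep), g in df.groupby(key, sort=True):
        g = g.sort_values("trial")
        if len(g) != n_trials:
            raise ValueError(
                f"session {sid}/{opp}/{fra}/{rep} has {len(g)} trials, "
                f"expected {n_trials}"
            )
        trials = [
            TrialRecord(
                index=int(r.trial),
                a_self=int(r.a_self),
                a_op=int(r.a_op),
                reward=int(r.reward),
            )
            for r in g.itertuples()
        ]
        s = SessionRecord(
            subject_id=str(sid), opponent=str(opp), framing=str(fra),
            repetition=str(rep), trials=trials,
        )
        s.validate(n_trials)
        sessions.append(s)
    return sessions


def write_cohort_table(participants_df: pd.DataFrame, path) -> None:
    participants_df.to_csv(path, index=False)


def read_cohort_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"subject_id", "group", "symptom_social", "symptom_stereotyped"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV lacks columns: {sorted(missing)}")
    return df


def write_truth(truth: dict, path) -> None:
    """Ground-truth strategies as JSON with 'subject|opponent|framing|rep' keys."""
    enc = {"|".join(k): v for k, v in truth.items()}
    Path(path).write_text(json.dumps(enc, indent=0, sort_keys=True) + "\n")


def read_truth(path) -> dict:
    enc = json.loads(Path(path).read_text())
    return {tuple(k.split("|")): v for k, v in enc.items()}


def write_evidence(em: EvidenceMatrix, path) -> None:
    em.df.to_csv(path, sep="\t", index=False)


def read_evidence(path) -> EvidenceMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"repetition": str})
    em = EvidenceMatrix(df)
    em.validate()
    return em
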