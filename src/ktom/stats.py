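"""Cohort-level statistics: group classification and symptom regression.

Classification follows the simple scheme the task calls for: a plain
L2-regularised logistic regression (fixed C = 1, no nested tuning) on
per-subject features — the eight net-correct-rate scores (4 opponents x 2
framings, averaged over repetitions), optionally augmented with the four
computational phenotypes — evaluated by leave-one-out cross-validation, with
chance level assessed by re-running the whole LOO loop under label
permutations.  Features are z-scored inside each training fold only.

Symptom regression is ordinary least squares of a symptom subscore on the
four phenotypes, with univariate one-sided follow-ups on the contrasts
delta_k and delta_f (the direction of interest being negative: milder
deficits with higher sophistication gain and flexibility gap).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import LeaveOneOut
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .game import FRAMINGS, OPPONENTS, net_correct_rate

__all__ = [
    "FeatureTable",
    "ClassificationReport",
    "assemble_features",
    "loo_classify",
    "symptom_regression",
]

PHENOTYPE_FEATURES = ("f_framing", "f_repetitions", "k_social", "k_nonsocial")


@dataclass
class FeatureTable:
    """Per-subject feature matrix plus group labels."""

    df: pd.DataFrame  # index: subject_id; columns: features
    labels: pd.Series  # group label per subject
    feature_names: tuple

    @property
    def X(self) -> np.ndarray:
        return self.df[list(self.feature_names)].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.labels.to_numpy()


@dataclass
class ClassificationReport:
    loo_accuracy: float
    predictions: pd.Series
    p_value: float | None = None
    n_permutations: int = 0
    permutation_accuracies: np.ndarray = field(default_factory=lambda: np.array([]))


def assemble_features(
    sessions: list,
    groups: dict,
    profiles: pd.DataFrame | None = None,
    include_phenotypes: bool = False,
) -> FeatureTable:
    """Build the classifier feature table.

    Performance features: net correct rate per (opponent, framing), averaged
    over the two repetitions — 8 columns.  With ``include_phenotypes`` the
    four phenotype columns from ``profiles`` are appended (12 columns).
    Constant columns are dropped with a warning.
    """
    rows: dict = {}
    for s in sessions:
        rows.setdefault(s.subject_id, {}).setdefault(
            (s.opponent, s.framing), []
        ).append(net_correct_rate(s))
    recs = {}
    for sid, cells in rows.items():
        rec = {}
        for opp in OPPONENTS:
            for fra in FRAMINGS:
                if (opp, fra) not in cells:
                    raise ValueError(f"subject {sid} lacks condition ({opp}, {fra})")
                rec[f"perf_{opp}_{fra}"] = float(np.mean(cells[(opp, fra)]))
        recs[sid] = rec
    df = pd.DataFrame.from_dict(recs, orient="index").sort_index()

    if include_phenotypes:
        if profiles is None:
            raise ValueError("include_phenotypes requires a profiles table")
        prof = profiles.set_index("subject_id")[list(PHENOTYPE_FEATURES)]
        missing = set(df.index) - set(prof.index)
        if missing:
            raise ValueError(f"profiles missing for subjects: {sorted(missing)[:5]}")
        df = df.join(prof)

    keep = []
    for c in df.columns:
        if df[c].nunique() <= 1:
            warnings.warn(f"dropping constant feature column {c!r}", stacklevel=2)
        else:
            keep.append(c)
    df = df[keep]
    labels = pd.Series({sid: groups[sid] for sid in df.index}, name="group")
    return FeatureTable(df=df, labels=labels, feature_names=tuple(keep))


def _loo_accuracy(X: np.ndarray, y: np.ndarray, C: float) -> tuple:
    preds = np.empty(len(y), dtype=object)
    for train, test in LeaveOneOut().split(X):
        if len(np.unique(y[train])) < 2:
            raise ValueError("a training fold contains a single class")
        clf = make_pipeline(
            StandardScaler(), LogisticRegression(C=C, max_iter=1000)
        )
        clf.fit(X[train], y[train])
        preds[test[0]] = clf.predict(X[test])[0]
    return float(np.mean(preds == y)), preds


def loo_classify(
    features: FeatureTable,
    n_permutations: int = 1000,
    seed: int = 0,
    C: float = 1.0,
) -> ClassificationReport:
    """Leave-one-out logistic classification with a permutation null.

    The permutation p-value is (1 + #{perm accuracy >= observed}) /
    (1 + n_permutations); set ``n_permutations=0`` to skip the null.
    """
    X, y = features.X, features.y
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2 or counts.min() < 2:
        raise ValueError("need two groups with >= 2 subjects each")
    acc, preds = _loo_accuracy(X, y, C)
    report = ClassificationReport(
        loo_accuracy=acc,
        predictions=pd.Series(preds, index=features.df.index, name="prediction"),
    )
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        perm_acc = np.empty(n_permutations)
        for b in range(n_permutations):
            yp = rng.permutation(y)
            while len(np.unique(yp[:-1])) < 2:  # guard degenerate folds
                yp = rng.permutation(y)
            perm_acc[b] = _loo_accuracy(X, yp, C)[0]
        report.p_value = float((1 + np.sum(perm_acc >= acc)) / (1 + n_permutations))
        report.n_permutations = n_permutations
        report.permutation_accuracies = perm_acc
    return report


def symptom_regression(
    profiles: pd.DataFrame,
    symptom: pd.Series | np.ndarray,
) -> dict:
    """OLS of a symptom score on the four phenotypes, with delta follow-ups.

    Returns overall R^2 and F statistics plus, for each of delta_k and
    delta_f, the univariate slope and the one-sided p-value for a negative
    association.  Raises on rank-deficient designs, naming the collinear
    columns.
    """
    X = profiles[list(PHENOTYPE_FEATURES)].to_numpy(dtype=float)
    y = np.asarray(symptom, dtype=float)
    if len(y) != len(X):
        raise ValueError("symptom vector length must match profiles")
    if len(y) <= X.shape[1] + 1:
        raise ValueError("group size must exceed number of predictors + 1")
    Xc = sm.add_constant(X)
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        corr = np.corrcoef(X, rowvar=False)
        pairs = [
            (PHENOTYPE_FEATURES[i], PHENOTYPE_FEATURES[j])
            for i in range(len(PHENOTYPE_FEATURES))
            for j in range(i + 1, len(PHENOTYPE_FEATURES))
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise ValueError(f"rank-deficient design; collinear columns: {pairs}")
    fit = sm.OLS(y, Xc).fit()
    out = {
        "r_squared": float(fit.rsquared),
        "f_statistic": float(fit.fvalue),
        "f_pvalue": float(fit.f_pvalue),
        "n": int(len(y)),
        "slopes": dict(zip(("const",) + PHENOTYPE_FEATURES, map(float, fit.params))),
    }
    for name in ("delta_k", "delta_f"):
        x = profiles[name].to_numpy(dtype=float)
        uni = sm.OLS(y, sm.add_constant(x)).fit()
        slope = float(uni.params[1])
        tval = float(uni.tvalues[1])
        p_onesided = float(sps.t.cdf(tval, df=uni.df_resid))  # H1: slope < 0
        out[name] = {
            "slope": slope,
            "t": tval,
            "p_one_sided_negative": p_onesided,
            "r_squared": float(uni.rsquared),
        }
    return out
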