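"""Group classification by L1 logistic regression with repeated hold-out.

Features (per-patient frequencies) are transformed x -> log(1e-3 + x) and
z-normalized across the dataset before modeling. Each repeated hold-out
(RHO) repetition samples 10 training patients per group, picks the L1
strength by stratified cross-validation on that training sample, fits, and
scores the held-out patients by AUC. Feature importance is the z-score of
the absolute coefficient across repetitions.

The CN functional-state alteration score of a cell subset compares, over RHO
AUC samples, a model using only the subset's overall frequency against one
adding its CN-specific frequencies: score = -log10 p of the one-sided
(Welch) t-test that the richer model has greater mean AUC. The whole
procedure is repeated (default 10 times) to expose its sampling variability.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegressionCV
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

log = logging.getLogger(__name__)


@dataclass
class ClassifierReport:
    aucs: np.ndarray                 # per-repetition held-out AUC
    coefficients: np.ndarray         # (n_reps, n_features)
    feature_names: list[str]
    n_reps: int
    train_per_group: int
    importance: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        a = np.abs(self.coefficients)
        sd = a.std(axis=0, ddof=0)
        mean = a.mean(axis=0)
        z = np.where(sd > 0, mean / np.where(sd > 0, sd, 1.0), 0.0)
        self.importance = pd.Series(z, index=self.feature_names,
                                    name="importance").sort_values(ascending=False)


def _transform(x: np.ndarray, pseudocount: float, leak_free: bool = False,
               train_idx: np.ndarray | None = None) -> np.ndarray:
    lx = np.log(pseudocount + x)
    ref = lx[train_idx] if (leak_free and train_idx is not None) else lx
    mu, sd = ref.mean(axis=0), ref.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (lx - mu) / sd


def classify_groups(features: pd.DataFrame, labels: pd.Series,
                    n_reps: int = 1000, train_per_group: int = 10,
                    seed: int = 0, pseudocount: float = 1e-3,
                    cv_folds: int = 5, n_cs: int = 10,
                    leak_free: bool = False) -> ClassifierReport:
    """Repeated-hold-out L1 logistic regression report.

    ``labels`` is a 0/1 per-patient series aligned to ``features``' index.
    z-normalization is over all patients by default, as in the published
    protocol (``leak_free=True`` normalizes on the training sample only).
    """
    y = labels.reindex(features.index).to_numpy(int)
    xraw = features.to_numpy(float)
    xraw = np.nan_to_num(xraw, nan=0.0)
    idx0, idx1 = np.flatnonzero(y == 0), np.flatnonzero(y == 1)
    if min(len(idx0), len(idx1)) < train_per_group + 1:
        raise ValueError("need at least train_per_group + 1 patients per group")
    rng = np.random.default_rng(seed)
    x_all = None if leak_free else _transform(xraw, pseudocount)
    aucs = np.empty(n_reps)
    coefs = np.empty((n_reps, xraw.shape[1]))
    for rep in range(n_reps):
        tr = np.concatenate([rng.choice(idx0, train_per_group, replace=False),
                             rng.choice(idx1, train_per_group, replace=False)])
        te = np.setdiff1d(np.arange(len(y)), tr)
        x = (_transform(xraw, pseudocount, leak_free=True, train_idx=tr)
             if leak_free else x_all)
        cv = StratifiedKFold(cv_folds, shuffle=True,
                             random_state=int(rng.integers(2**31)))
        clf = LogisticRegressionCV(Cs=n_cs, cv=cv, penalty="l1",
                                   solver="liblinear", max_iter=2000,
                                   scoring="accuracy",
                                   random_state=int(rng.integers(2**31)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            # liblinear hitting its iteration cap on strongly-penalized tiny
            # fits is routine in the hold-out loop and not informative
            warnings.simplefilter("ignore", ConvergenceWarning)
            clf.fit(x[tr], y[tr])
        score = clf.decision_function(x[te])
        aucs[rep] = roc_auc_score(y[te], score)
        coefs[rep] = clf.coef_[0]
    return ClassifierReport(aucs, coefs, list(map(str, features.columns)),
                            n_reps, train_per_group)


def feature_importance(report: ClassifierReport, cutoff: float = 0.3) -> pd.DataFrame:
    """Ranked importance table with the selection flag at the cutoff."""
    imp = report.importance
    return pd.DataFrame({"importance": imp, "selected": imp >= cutoff})


@dataclass
class AlterationScore:
    subset: str
    scores: np.ndarray          # one -log10 p per outer repeat
    auc_overall: np.ndarray     # (outer, rho) AUCs of the overall-only model
    auc_spatial: np.ndarray     # (outer, rho) AUCs of the CN-augmented model

    @property
    def median(self) -> float:
        return float(np.median(self.scores))


def alteration_score(tables, subset_name: str, labels: pd.Series,
                     rho_reps: int = 200, outer_reps: int = 10,
                     train_per_group: int = 10, seed: int = 0,
                     pseudocount: float = 1e-3) -> AlterationScore:
    """CN functional-state alteration score for one subset.

    Model 1 uses the subset's overall frequency; model 2 adds its CN-specific
    frequencies in all non-excluded CNs. Per outer repeat, both models'
    AUC distributions over ``rho_reps`` hold-outs are compared by a one-sided
    Welch t-test (model 2 greater); score = -log10 p.
    """
    if subset_name not in tables.overall.columns:
        raise ValueError(f"subset {subset_name!r} absent from frequency tables")
    f1 = tables.overall[[subset_name]]
    cn_cols = [c for c in tables.cn_specific.columns if c[1] == subset_name]
    if not cn_cols:
        raise ValueError(f"subset {subset_name!r} has no CN-specific columns")
    f2 = pd.concat([f1, tables.cn_specific[cn_cols].set_axis(
        [f"{subset_name}@CN{c}" for c, _ in cn_cols], axis=1)], axis=1)
    rng = np.random.default_rng(seed)
    scores = np.empty(outer_reps)
    a1 = np.empty((outer_reps, rho_reps))
    a2 = np.empty((outer_reps, rho_reps))
    for o in range(outer_reps):
        s1, s2 = rng.integers(2**31), rng.integers(2**31)
        r1 = classify_groups(f1, labels, n_reps=rho_reps,
                             train_per_group=train_per_group, seed=int(s1),
                             pseudocount=pseudocount)
        r2 = classify_groups(f2, labels, n_reps=rho_reps,
                             train_per_group=train_per_group, seed=int(s2),
                             pseudocount=pseudocount)
        t, p = sps.ttest_ind(r2.aucs, r1.aucs, equal_var=False,
                             alternative="greater")
        scores[o] = -np.log10(max(p, 1e-300))
        a1[o], a2[o] = r1.aucs, r2.aucs
    return AlterationScore(subset_name, scores, a1, a2)
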