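"""SVM / random-forest biomarker evaluation.

Two regimes mirror the benchmark design: (1) single-cohort evaluation
of classifiers separating ANL from stage I/II LUAD samples within one
cohort (mean 10-fold cross-validated error for SVMs, out-of-bag error
for 300-tree random forests), and (2) cross-cohort generalization,
where models are trained on the largest cohort using only features
differentially expressed/frequent there, hyperparameters are tuned by
seeded random search (SVM box constraint and kernel scale against
5-fold CV error; RF minimum leaf size <= 20 and per-node feature
fraction <= 70% against OOB error), and AUCs are reported on the
held-out cohorts.  SVM features are standardized with statistics fitted
on training data only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from statsmodels.stats.multitest import multipletests

__all__ = [
    "FeatureTable",
    "build_feature_table",
    "select_differential_features",
    "single_cohort_eval",
    "cross_cohort_eval",
]

EARLY_STAGES = ("IA", "IB", "IIA", "IIB", "I", "II")


@dataclass
class FeatureTable:
    """Samples x features with binary labels (ANL vs stage I/II LUAD)."""

    X: pd.DataFrame
    y: pd.Series  # 1 = LUAD, 0 = ANL
    kind: str
    mode: str  # "rpm" | "frequency"

    def __post_init__(self) -> None:
        if self.mode == "frequency" and self.X.isna().any().any():
            raise ValueError("frequency tables must not contain undefined entries")
        if self.y.nunique() != 2:
            raise ValueError("feature table must contain both classes")


def _eligible_samples(sheet: pd.DataFrame, cohort: str) -> pd.DataFrame:
    sub = sheet[sheet["cohort"] == cohort]
    anl = sub["group"] == "ANL"
    early = (sub["group"] == "LUAD") & sub["stage"].isin(EARLY_STAGES)
    return sub[anl | early]


def build_feature_table(
    values: pd.DataFrame,
    sheet: pd.DataFrame,
    cohort: str,
    kind: str,
    mode: str,
    features: Optional[Sequence[str]] = None,
) -> FeatureTable:
    """Assemble the classifier input for one cohort.

    ``values`` is a samples x names matrix (RPM or frequency).  Stage
    III+ tumors are excluded.  In frequency mode, features undefined in
    any included sample are dropped; an empty feature set is rejected.
    """
    sub = _eligible_samples(sheet, cohort)
    samples = [s for s in sub["sample_id"] if s in values.index]
    X = values.loc[samples]
    if features is not None:
        X = X[[f for f in features if f in X.columns]]
    if mode == "frequency":
        X = X.dropna(axis=1)
    else:
        X = X.fillna(0.0)
    if X.shape[1] == 0:
        raise ValueError(f"no usable {kind}/{mode} features for cohort {cohort}")
    y = (sub.set_index("sample_id").loc[samples, "group"] == "LUAD").astype(int)
    return FeatureTable(X=X, y=y, kind=kind, mode=mode)


def select_differential_features(
    values: pd.DataFrame,
    sheet: pd.DataFrame,
    cohort: str,
    candidates: Sequence[str],
    alpha: float = 0.05,
) -> list[str]:
    """Features differential between the training cohort's ANL and stage
    I/II LUAD samples (Welch t-test, BH-FDR < alpha)."""
    sub = _eligible_samples(sheet, cohort)
    anl = [s for s in sub.loc[sub["group"] == "ANL", "sample_id"] if s in values.index]
    luad = [s for s in sub.loc[sub["group"] == "LUAD", "sample_id"] if s in values.index]
    names, pvals = [], []
    for name in candidates:
        if name not in values.columns:
            continue
        a = values.loc[anl, name].dropna()
        b = values.loc[luad, name].dropna()
        if len(a) < 3 or len(b) < 3 or (a.std() == 0 and b.std() == 0):
            continue
        _, p = sps.ttest_ind(a, b, equal_var=False)
        if np.isfinite(p):
            names.append(name)
            pvals.append(p)
    if not names:
        return []
    rej, _, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return [n for n, r in zip(names, rej) if r]


def single_cohort_eval(table: FeatureTable, model: str, seed: int = 0,
                       n_folds: int = 10, n_trees: int = 300) -> float:
    """Classification error within one cohort.

    SVM: mean error over stratified 10-fold CV with per-fold
    standardization.  RF: out-of-bag error of a 300-tree forest.
    """
    X = table.X.to_numpy(dtype=float)
    y = table.y.to_numpy()
    if len(y) < 20:
        raise ValueError("need >= 20 samples for single-cohort evaluation")
    if model == "svm":
        clf = make_pipeline(StandardScaler(), SVC(kernel="rbf"))
        folds = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        scores = cross_val_score(clf, X, y, cv=folds, scoring="accuracy")
        return float(1.0 - scores.mean())
    if model == "rf":
        clf = RandomForestClassifier(n_estimators=n_trees, oob_score=True,
                                     random_state=seed, n_jobs=1)
        clf.fit(X, y)
        return float(1.0 - clf.oob_score_)
    raise ValueError(f"unknown model {model!r}")


def _tune_svm(X, y, rng, n_iter, n_folds=5):
    folds = StratifiedKFold(n_splits=n_folds, shuffle=True,
                            random_state=int(rng.integers(2**31)))
    best = None
    for _ in range(n_iter):
        c = 10.0 ** rng.uniform(-2, 3)
        gamma = 10.0 ** rng.uniform(-4, 1) / X.shape[1]
        clf = make_pipeline(StandardScaler(), SVC(kernel="rbf", C=c, gamma=gamma))
        err = 1.0 - cross_val_score(clf, X, y, cv=folds, scoring="accuracy").mean()
        if best is None or err < best[0]:
            best = (err, c, gamma)
    return best[1], best[2]


def _tune_rf(X, y, rng, n_iter, n_trees, max_leaf=20, max_feat_frac=0.7):
    best = None
    for _ in range(n_iter):
        leaf = int(rng.integers(1, max_leaf + 1))
        frac = float(rng.uniform(0.05, max_feat_frac))
        clf = RandomForestClassifier(
            n_estimators=n_trees, min_samples_leaf=leaf,
            max_features=max(1, int(round(frac * X.shape[1]))),
            oob_score=True, random_state=int(rng.integers(2**31)), n_jobs=1)
        clf.fit(X, y)
        err = 1.0 - clf.oob_score_
        if best is None or err < best[0]:
            best = (err, leaf, frac)
    return best[1], best[2]


@dataclass
class CrossCohortResult:
    model: str
    kind: str
    mode: str
    n_features: int
    hyperparams: dict
    auc: dict  # test cohort -> AUC
    scores: pd.DataFrame  # sample_id, cohort, label, score

    @property
    def mean_auc(self) -> float:
        return float(np.mean(list(self.auc.values())))


def cross_cohort_eval(
    train: FeatureTable,
    tests: dict,
    model: str,
    seed: int = 0,
    n_iter: int = 20,
    n_trees: int = 300,
) -> CrossCohortResult:
    """Train on one cohort, tune by random search, report test AUCs.

    Features absent from a test table are filled with zero in RPM mode
    and dropped everywhere in frequency mode.  Standardization
    statistics come from the training samples only.
    """
    if any(t is train for t in tests.values()):
        raise ValueError("test cohorts must be disjoint from the training cohort")
    rng = np.random.default_rng(seed)
    features = list(train.X.columns)
    if train.mode == "frequency":
        for t in tests.values():
            features = [f for f in features if f in t.X.columns]
        if not features:
            raise ValueError("no features defined in every train/test sample")
    Xtr = train.X[features].to_numpy(dtype=float)
    ytr = train.y.to_numpy()

    if model == "svm":
        c, gamma = _tune_svm(Xtr, ytr, rng, n_iter)
        clf = make_pipeline(StandardScaler(), SVC(kernel="rbf", C=c, gamma=gamma))
        clf.fit(Xtr, ytr)
        hyper = {"C": c, "gamma": gamma}
        score_fn = clf.decision_function
    elif model == "rf":
        leaf, frac = _tune_rf(Xtr, ytr, rng, n_iter, n_trees)
        clf = RandomForestClassifier(
            n_estimators=n_trees, min_samples_leaf=leaf,
            max_features=max(1, int(round(frac * len(features)))),
            random_state=int(rng.integers(2**31)), n_jobs=1)
        clf.fit(Xtr, ytr)
        hyper = {"min_samples_leaf": leaf, "max_features_frac": frac}
        score_fn = lambda X: clf.predict_proba(X)[:, 1]  # voting fraction
    else:
        raise ValueError(f"unknown model {model!r}")

    aucs = {}
    score_rows = []
    for name, t in tests.items():
        Xte = t.X.reindex(columns=features).fillna(0.0).to_numpy(dtype=float)
        s = score_fn(Xte)
        aucs[name] = float(roc_auc_score(t.y.to_numpy(), s))
        for sid, label, sc in zip(t.X.index, t.y.to_numpy(), s):
            score_rows.append({"sample_id": sid, "cohort": name,
                               "label": int(label), "score": float(sc)})
    return CrossCohortResult(model=model, kind=train.kind, mode=train.mode,
                             n_features=len(features), hyperparams=hyper,
                             auc=aucs, scores=pd.DataFrame(score_rows))
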