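"""Ensemble predictor of pathological complete response.

Architecture: each *predictor* is a chain of collinearity removal (mutual
Pearson |r| > 0.8, keeping the feature most correlated with the response),
k-best ANOVA-F univariable selection, z-scaling, and three classifiers run in
parallel — elastic-net logistic regression, a support vector classifier and a
random forest — whose class probabilities are averaged.  Hyperparameters are
tuned by randomized search scored with stratified five-fold cross-validated
AUC.  A *model* is the average of five predictors tuned with different
cross-validation seeds.  Six nested models add feature modalities one at a
time (clinical -> +DNA -> +RNA -> +DNA+RNA -> +DigPath -> +treatment).

Evaluation reports empirical ROC/AUC with bootstrap SD and DeLong 95% CI plus
precision-recall; feature importance is drop-one AUC change expressed as a
z-score (signed so that value-adding features are negative); the
clinical-impact simulation projects the confusion matrix at a
false-negative-budgeted threshold onto a cohort of 100 patients.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import f_classif
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FeatureMatrix
from .stats import ordinal_trend

NESTED_MODEL_MODALITIES = [
    ["clinical"],
    ["clinical", "DNA"],
    ["clinical", "RNA"],
    ["clinical", "DNA", "RNA"],
    ["clinical", "DNA", "RNA", "DigPath"],
    ["clinical", "DNA", "RNA", "DigPath", "treatment"],
]


# ---------------------------------------------------------------------------
# Data cleaning
# ---------------------------------------------------------------------------


def clean_training_data(
    fm: FeatureMatrix,
    clinical: pd.DataFrame | None = None,
    validation: bool = False,
    exclude_undertreated: bool = True,
    min_chemo_cycles: int = 2,
    min_her2_cycles: int = 2,
) -> FeatureMatrix:
    """Apply the dataset cleaning rules and return a complete matrix.

    Missing tumour size is imputed as 1.1x the largest size in the cohort.
    In training mode, under-treated cases (fewer than ``min_chemo_cycles``
    chemotherapy cycles, or fewer than ``min_her2_cycles`` anti-HER2 cycles
    for HER2+ tumours) are removed when a clinical table is supplied.  In
    validation mode missing treatment features are set to 0.  Any remaining
    missing value is imputed with the cohort median (and flagged), so the
    result satisfies the no-missing-values invariant.
    """
    X = fm.X.copy()
    if fm.y.isna().any():
        raise ValueError("outcome contains missing values")
    if "tumour_size" in X.columns and X["tumour_size"].isna().any():
        X.loc[X["tumour_size"].isna(), "tumour_size"] = 1.1 * X["tumour_size"].max()
    if validation:
        treat = fm.modality[fm.modality == "treatment"].index
        X[list(treat)] = X[list(treat)].fillna(0.0)
    keep = pd.Series(True, index=X.index)
    if not validation and exclude_undertreated and clinical is not None:
        keep &= clinical.loc[X.index, "chemo_cycles"] >= min_chemo_cycles
        her2 = clinical.loc[X.index, "her2_status"].astype(bool)
        keep &= ~her2 | (clinical.loc[X.index, "her2_cycles"] >= min_her2_cycles)
    X = X[keep]
    if X.isna().any().any():
        X = X.fillna(X.median(numeric_only=True))
    return FeatureMatrix(
        X=X,
        modality=fm.modality,
        y=fm.y.loc[X.index],
        rcb=None if fm.rcb is None else fm.rcb.loc[X.index],
    )


# ---------------------------------------------------------------------------
# Feature filtering steps
# ---------------------------------------------------------------------------


def collinearity_filter(
    X: pd.DataFrame, y: np.ndarray | pd.Series, threshold: float = 0.8
) -> list[str]:
    """Greedy collinearity reduction keep-list.

    Features are visited in order of decreasing |Pearson r| with the response
    (ties broken by name); a feature is kept iff its |pairwise r| with every
    already-kept feature is <= threshold (strictly above 0.8 is removed).
    Zero-variance features are dropped with a warning before filtering.
    """
    if X.shape[1] < 1:
        raise ValueError("need at least one feature")
    yv = np.asarray(y, dtype=float)
    sd = X.std(ddof=0)
    flat = list(sd[sd == 0].index)
    if flat:
        warnings.warn(f"dropping zero-variance feature(s): {flat}")
    cols = [c for c in X.columns if c not in flat]
    with np.errstate(invalid="ignore"):
        target_corr = {
            c: abs(float(np.corrcoef(X[c].to_numpy(float), yv)[0, 1])) for c in cols
        }
    order = sorted(cols, key=lambda c: (-target_corr[c], c))
    corr = X[cols].corr()
    kept: list[str] = []
    for c in order:
        if all(abs(corr.loc[c, k]) <= threshold for k in kept):
            kept.append(c)
    return [c for c in X.columns if c in kept]  # original column order


def select_kbest(X: pd.DataFrame, y: np.ndarray | pd.Series, k: int) -> list[str]:
    """Top-k features by one-way ANOVA F against the binary outcome.

    Deterministic: ties in F are broken by feature name; min(k, p) kept.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        F, _ = f_classif(X.to_numpy(float), np.asarray(y, dtype=int))
    F = np.nan_to_num(F, nan=0.0)
    ranked = sorted(zip(X.columns, F), key=lambda t: (-t[1], t[0]))
    kept = {name for name, _ in ranked[: min(k, X.shape[1])]}
    return [c for c in X.columns if c in kept]


# ---------------------------------------------------------------------------
# Hyperparameters
# ---------------------------------------------------------------------------


@dataclass
class Hyperparameters:
    lr_C: float = 1.0
    lr_l1_ratio: float = 0.5
    svm_kernel: str = "rbf"
    svm_gamma: float = 1e-2
    svm_C: float = 1.0
    rf_n_estimators: int = 100
    rf_max_features: float = 0.3
    rf_min_samples_split: int = 2
    k_best: int = 25


@dataclass
class HyperparameterSpace:
    """Randomized-search bounds; C and gamma are sampled log-uniformly."""

    lr_C: tuple[float, float] = (1e-3, 1e3)
    lr_l1_ratio: tuple[float, float] = (0.1, 1.0)
    svm_kernels: tuple[str, ...] = ("rbf", "sigmoid", "linear")
    svm_gamma: tuple[float, float] = (1e-9, 1e-2)
    svm_C: tuple[float, float] = (1e-3, 1e3)
    rf_n_estimators: tuple[int, int] = (5, 100)
    rf_max_features: tuple[float, float] = (0.05, 0.70)
    rf_min_samples_split: tuple[int, int] = (2, 15)
    k_best: tuple[int, int] = (5, 34)

    def sample(self, rng: np.random.Generator) -> Hyperparameters:
        def logu(lo, hi):
            return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

        return Hyperparameters(
            lr_C=logu(*self.lr_C),
            lr_l1_ratio=float(rng.uniform(*self.lr_l1_ratio)),
            svm_kernel=str(rng.choice(list(self.svm_kernels))),
            svm_gamma=logu(*self.svm_gamma),
            svm_C=logu(*self.svm_C),
            rf_n_estimators=int(rng.integers(self.rf_n_estimators[0],
                                             self.rf_n_estimators[1] + 1)),
            rf_max_features=float(rng.uniform(*self.rf_max_features)),
            rf_min_samples_split=int(rng.integers(self.rf_min_samples_split[0],
                                                  self.rf_min_samples_split[1] + 1)),
            k_best=int(rng.integers(self.k_best[0], self.k_best[1] + 1)),
        )


# ---------------------------------------------------------------------------
# Predictor and model
# ---------------------------------------------------------------------------


@dataclass
class Predictor:
    """One fitted preprocessing chain + three-classifier trio."""

    hyperparameters: Hyperparameters
    collinearity_keep: list[str] = field(default_factory=list)
    kbest_keep: list[str] = field(default_factory=list)
    scaler: StandardScaler | None = None
    classifiers: dict = field(default_factory=dict)

    def _transform(self, X: pd.DataFrame) -> np.ndarray:
        sub = X[self.kbest_keep].to_numpy(float)
        return self.scaler.transform(sub)

    def predict_scores(self, X: pd.DataFrame, per_classifier: bool = False):
        Z = self._transform(X)
        probs = {
            name: clf.predict_proba(Z)[:, 1] for name, clf in self.classifiers.items()
        }
        mean = np.mean(list(probs.values()), axis=0)
        if per_classifier:
            return mean, probs
        return mean


class PlattSVC:
    """Support vector classifier with sigmoid (Platt) probability calibration
    fitted on the training data, so margin scores become probabilities that
    can be averaged with the other classifiers'."""

    def __init__(self, kernel: str, gamma: float, C: float, seed: int = 0):
        # max_iter caps pathological libsvm spins at large C on noisy data;
        # it is far above the iterations needed at these cohort sizes
        self.svc = SVC(kernel=kernel, gamma=gamma, C=C, random_state=seed,
                       max_iter=20000)
        self.platt = LogisticRegression(C=1e6, max_iter=1000)

    def fit(self, Z: np.ndarray, y: np.ndarray) -> "PlattSVC":
        self.svc.fit(Z, y)
        d = self.svc.decision_function(Z)[:, None]
        self.platt.fit(d, y)
        return self

    def predict_proba(self, Z: np.ndarray) -> np.ndarray:
        return self.platt.predict_proba(self.svc.decision_function(Z)[:, None])


def _make_classifiers(hp: Hyperparameters, seed: int) -> dict:
    return {
        "logistic": LogisticRegression(
            solver="saga", C=hp.lr_C, l1_ratio=hp.lr_l1_ratio,
            max_iter=5000, random_state=seed,
        ),
        "svm": PlattSVC(hp.svm_kernel, hp.svm_gamma, hp.svm_C, seed),
        "forest": RandomForestClassifier(
            n_estimators=hp.rf_n_estimators,
            max_features=max(hp.rf_max_features, 1e-9),
            min_samples_split=hp.rf_min_samples_split,
            random_state=seed,
        ),
    }


def fit_predictor(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    hp: Hyperparameters | None = None,
    seed: int = 0,
    _keep1: list[str] | None = None,
) -> Predictor:
    """Fit the full chain: collinearity -> k-best -> z-scale -> 3 classifiers.

    The predictor score for a sample is the unweighted mean of the three
    classifiers' class-1 probabilities; SVC probabilities come from sigmoid
    (Platt) calibration fitted within the training data.
    """
    hp = hp or Hyperparameters()
    yv = np.asarray(y, dtype=int)
    if len(np.unique(yv)) < 2:
        raise ValueError("both outcome classes must be present")
    if _keep1 is None:
        _keep1 = collinearity_filter(X, yv)
    keep1 = _keep1
    keep2 = select_kbest(X[keep1], yv, hp.k_best)
    scaler = StandardScaler().fit(X[keep2].to_numpy(float))
    Z = scaler.transform(X[keep2].to_numpy(float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        classifiers = {
            name: clf.fit(Z, yv)
            for name, clf in _make_classifiers(hp, seed).items()
        }
    return Predictor(
        hyperparameters=hp,
        collinearity_keep=keep1,
        kbest_keep=keep2,
        scaler=scaler,
        classifiers=classifiers,
    )


def tune(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    space: HyperparameterSpace | None = None,
    n_iter: int = 100,
    cv_seed: int = 0,
    n_folds: int = 5,
) -> tuple[Hyperparameters, float]:
    """Randomized hyperparameter search scored by stratified k-fold CV AUC.

    Every preprocessing step (collinearity, k-best, scaling) is re-fitted
    inside each training fold, so no information leaks from validation folds.
    Returns the best draw (ties resolved toward the first drawn) and its mean
    CV AUC.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    space = space or HyperparameterSpace()
    yv = np.asarray(y, dtype=int)
    rng = np.random.default_rng([cv_seed, 777])
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                          random_state=cv_seed % (2**31))
    folds = list(skf.split(X, yv))
    # the collinearity keep-list depends only on the training fold, not the
    # draw, so it is computed once per fold
    fold_keep1 = [collinearity_filter(X.iloc[tr], yv[tr]) for tr, _ in folds]
    best_hp, best_auc = None, -np.inf
    for _ in range(n_iter):
        hp = space.sample(rng)
        aucs = []
        for (tr, va), keep1 in zip(folds, fold_keep1):
            pred = fit_predictor(X.iloc[tr], yv[tr], hp, seed=cv_seed,
                                 _keep1=keep1)
            scores = pred.predict_scores(X.iloc[va])
            aucs.append(roc_auc_score(yv[va], scores))
        mean_auc = float(np.mean(aucs))
        if mean_auc > best_auc:
            best_hp, best_auc = hp, mean_auc
    return best_hp, best_auc


@dataclass
class EnsembleModel:
    """Five predictors tuned with distinct CV seeds; score = their mean."""

    predictors: list[Predictor]
    seeds: list[int]
    cv_aucs: list[float]
    feature_names: list[str]

    def predict_scores(self, X: pd.DataFrame) -> np.ndarray:
        return np.mean([p.predict_scores(X[self.feature_names])
                        for p in self.predictors], axis=0)

    def manifest(self) -> dict:
        return {
            "seeds": self.seeds,
            "cv_aucs": self.cv_aucs,
            "feature_names": self.feature_names,
            "predictors": [
                {
                    "hyperparameters": asdict(p.hyperparameters),
                    "collinearity_keep": p.collinearity_keep,
                    "kbest_keep": p.kbest_keep,
                    "scaling_mean": p.scaler.mean_.tolist(),
                    "scaling_sd": p.scaler.scale_.tolist(),
                }
                for p in self.predictors
            ],
        }

    def save_manifest(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.manifest(), fh, indent=1)


def train_model(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    seeds: list[int] | None = None,
    n_iter: int = 100,
    space: HyperparameterSpace | None = None,
) -> EnsembleModel:
    """Train the seed-averaged ensemble model.

    For each CV seed, hyperparameters are tuned by randomized search and the
    predictor is then refitted on the entire training cohort at the optimum.
    """
    seeds = list(seeds) if seeds is not None else [101, 202, 303, 404, 505]
    if len(set(seeds)) < len(seeds):
        warnings.warn("duplicate CV seeds reduce the ensemble to fewer members")
    predictors, cv_aucs = [], []
    for s in seeds:
        hp, auc = tune(X, y, space=space, n_iter=n_iter, cv_seed=s)
        predictors.append(fit_predictor(X, y, hp, seed=s))
        cv_aucs.append(auc)
    return EnsembleModel(
        predictors=predictors,
        seeds=seeds,
        cv_aucs=cv_aucs,
        feature_names=list(X.columns),
    )


def run_nested_models(
    fm: FeatureMatrix,
    seeds: list[int] | None = None,
    n_iter: int = 100,
    space: HyperparameterSpace | None = None,
) -> dict[str, EnsembleModel]:
    """The six nested models with increasing data integration."""
    models = {}
    for modalities in NESTED_MODEL_MODALITIES:
        sub = fm.subset(modalities)
        name = "+".join(modalities)
        models[name] = train_model(sub.X, sub.y, seeds=seeds, n_iter=n_iter,
                                   space=space)
    return models


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


def _midrank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def delong_ci(
    scores: np.ndarray, labels: np.ndarray, alpha: float = 0.05
) -> tuple[float, float, float]:
    """AUC with DeLong 95% confidence interval (normal approximation on the
    AUC scale, clipped to [0, 1])."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    pos, neg = s[y == 1], s[y == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes required")
    all_r = _midrank(np.concatenate([pos, neg]))
    pos_r, neg_r = _midrank(pos), _midrank(neg)
    auc = (all_r[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (all_r[:m] - pos_r) / n  # structural components over positives
    v01 = 1.0 - (all_r[m:] - neg_r) / m
    var = np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n
    z = sps.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(max(var, 0.0))
    return float(auc), float(max(auc - half, 0.0)), float(min(auc + half, 1.0))


@dataclass
class EvaluationReport:
    auc: float
    bootstrap_sd: float
    delong_ci: tuple[float, float]
    average_precision: float
    roc: pd.DataFrame
    precision_recall: pd.DataFrame
    confusion: dict

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "bootstrap_sd": self.bootstrap_sd,
            "delong_ci_low": self.delong_ci[0],
            "delong_ci_high": self.delong_ci[1],
            "average_precision": self.average_precision,
            "confusion": self.confusion,
        }


def evaluate(
    scores: np.ndarray,
    labels: np.ndarray,
    n_bootstrap: int = 100,
    threshold: float = 0.5,
    seed: int = 0,
) -> EvaluationReport:
    """Empirical ROC/AUC with bootstrap SD and DeLong CI, plus
    precision-recall and a confusion matrix at the given score threshold."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present in the test labels")
    auc, lo, hi = delong_ci(s, y)
    rng = np.random.default_rng([seed, 4242])
    boots = []
    idx = np.arange(len(y))
    for _ in range(n_bootstrap):
        b = rng.choice(idx, size=len(idx), replace=True)
        if len(np.unique(y[b])) < 2:
            continue
        boots.append(roc_auc_score(y[b], s[b]))
    fpr, tpr, _ = roc_curve(y, s)
    prec, rec, _ = precision_recall_curve(y, s)
    pred = (s >= threshold).astype(int)
    confusion = {
        "tp": int(((pred == 1) & (y == 1)).sum()),
        "fp": int(((pred == 1) & (y == 0)).sum()),
        "tn": int(((pred == 0) & (y == 0)).sum()),
        "fn": int(((pred == 0) & (y == 1)).sum()),
    }
    return EvaluationReport(
        auc=float(auc),
        bootstrap_sd=float(np.std(boots, ddof=1)) if len(boots) > 1 else float("nan"),
        delong_ci=(lo, hi),
        average_precision=float(average_precision_score(y, s)),
        roc=pd.DataFrame({"fpr": fpr, "tpr": tpr}),
        precision_recall=pd.DataFrame({"precision": prec, "recall": rec}),
        confusion=confusion,
    )


# ---------------------------------------------------------------------------
# Importance and clinical impact
# ---------------------------------------------------------------------------


@dataclass
class ImportanceReport:
    per_algorithm: pd.DataFrame  # features x algorithms, signed z
    signed_z: pd.Series  # averaged; negative = feature adds value
    unsigned_z: pd.Series


def feature_importance(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    hp: Hyperparameters | None = None,
    seed: int = 0,
) -> ImportanceReport:
    """Drop-one feature importance, per algorithm and averaged.

    For each algorithm, the pipeline is refitted with feature i removed and
    the change in training-cohort AUC Delta_i = AUC_nominal - AUC_drop is
    expressed as a z-score against the SD of all changes:
    unsigned z_i = |Delta_i| / sigma(Delta), signed z_i = -Delta_i / sigma
    (negative when dropping the feature lowers the AUC, i.e. it adds value).
    """
    if X.shape[1] < 2:
        raise ValueError("need at least 2 features to drop one")
    hp = hp or Hyperparameters()
    yv = np.asarray(y, dtype=int)
    full = fit_predictor(X, yv, hp, seed=seed)
    _, nominal_probs = full.predict_scores(X, per_classifier=True)
    nominal_auc = {a: roc_auc_score(yv, p) for a, p in nominal_probs.items()}
    deltas = {a: {} for a in nominal_auc}
    for feat in X.columns:
        reduced = fit_predictor(X.drop(columns=[feat]), yv, hp, seed=seed)
        _, probs = reduced.predict_scores(X.drop(columns=[feat]),
                                          per_classifier=True)
        for a, p in probs.items():
            deltas[a][feat] = nominal_auc[a] - roc_auc_score(yv, p)
    per_alg = {}
    for a, d in deltas.items():
        vals = pd.Series(d)
        sd = vals.std(ddof=1)
        per_alg[a] = -vals / sd if sd > 0 else vals * 0.0
    per_algorithm = pd.DataFrame(per_alg)
    signed = per_algorithm.mean(axis=1)
    return ImportanceReport(
        per_algorithm=per_algorithm,
        signed_z=signed,
        unsigned_z=signed.abs(),
    )


def clinical_impact(
    scores: np.ndarray,
    labels: np.ndarray,
    fn_budget: int = 0,
    cohort_size: int = 100,
) -> dict:
    """Projected clinical impact of score-thresholded treatment triage.

    The operating threshold is the highest cut-off leaving at most
    ``fn_budget`` true responders (pCR) below it; patients scoring below the
    threshold are flagged as predicted non-responders.  The resulting
    confusion matrix is rescaled to ``cohort_size`` patients with
    largest-remainder rounding.  Ties in the threshold sweep resolve toward
    the lower threshold (fewer false negatives).
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    if n_pos == 0 or n_pos == len(y):
        raise ValueError("labels must contain both classes")
    if fn_budget >= n_pos:
        raise ValueError("fn_budget must be smaller than the number of responders")
    candidates = np.concatenate([[-np.inf], np.sort(np.unique(s)), [np.inf]])
    best = None
    for t in candidates:
        fn = int(((s < t) & (y == 1)).sum())
        tn = int(((s < t) & (y == 0)).sum())
        if fn <= fn_budget and (best is None or tn > best["tn"]):
            best = {"threshold": float(t), "fn": fn, "tn": tn}
    t = best["threshold"]
    counts = {
        "tn": best["tn"],
        "fn": best["fn"],
        "fp": int(((s >= t) & (y == 0)).sum()),
        "tp": int(((s >= t) & (y == 1)).sum()),
    }
    exact = {k: v * cohort_size / len(y) for k, v in counts.items()}
    floored = {k: int(np.floor(v)) for k, v in exact.items()}
    remainder = cohort_size - sum(floored.values())
    order = sorted(exact, key=lambda k: exact[k] - floored[k], reverse=True)
    for k in order[:remainder]:
        floored[k] += 1
    return {
        "threshold": t,
        "confusion_raw": counts,
        "projected": floored,
        "identified_non_responders": floored["tn"],
        "false_negatives": floored["fn"],
        "cohort_size": cohort_size,
    }


def score_rcb_monotonicity(scores: np.ndarray, rcb_labels) -> float:
    """Ordinal-trend p-value of predictor scores across ordered RCB classes."""
    return ordinal_trend(np.asarray(scores, float), rcb_labels,
                         name="model_score").p_value
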