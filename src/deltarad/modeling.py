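"""Multivariate pCR-prediction models.

The primary learner is logistic regression with an elastic-net penalty:
the mixing parameter (alpha in glmnet notation, ``l1_ratio`` here) is
searched over {0.1, ..., 1.0} and the regularization strength over a
logarithmic path, both by stratified k-fold cross-validation maximizing AUC
on the training set; features with nonzero coefficients are the selected
signature. Evaluation is on a stratified 2:1 hold-out split (train AUC, test
AUC with DeLong 95% CI and a test of AUC = 0.5, accuracy at probability
0.5), with an unstratified pooled k-fold cross-validation alternative and
support-vector-machine comparators (linear and RBF/Gaussian kernels) under
the same hyperparameter protocol.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import GridSearchCV, KFold, StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from deltarad.datatypes import SEQUENCES, TIMEPOINTS
from deltarad.delta import DELTA_MODES, DELTA_PAIRS, delta_label


@dataclass(frozen=True)
class SplitSpec:
    """Stratified train:test split specification (default 2:1)."""

    ratio: tuple[int, int] = (2, 1)
    seed: int = 0

    @property
    def train_fraction(self) -> float:
        return self.ratio[0] / sum(self.ratio)


def stratified_split(labels: np.ndarray, spec: SplitSpec = SplitSpec()) -> tuple[np.ndarray, np.ndarray]:
    """Split patient indices stratified by label.

    Per stratum the training count is the stratum size times the training
    fraction rounded to the nearest integer with halves up — the convention
    under which 78 pCR / 85 non-pCR yields 52 + 57 = 109 training and
    26 + 28 = 54 testing patients at 2:1. Assignment within a stratum is a
    seeded permutation; train and test partition the cohort exactly.
    """
    labels = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(spec.seed)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for value in np.unique(labels):
        stratum = np.nonzero(labels == value)[0]
        if len(stratum) < 2:
            raise ValueError(f"stratum {value} has fewer than 2 members")
        n_train = int(np.floor(len(stratum) * spec.train_fraction + 0.5))
        n_train = min(max(n_train, 1), len(stratum) - 1)
        perm = rng.permutation(stratum)
        train_idx.append(perm[:n_train])
        test_idx.append(perm[n_train:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: feature blocks plus a learner.

    A block is a (block label, sequence) pair, e.g. ``("RD_C2-BL", "DCE")``;
    block labels are raw timepoints or delta labels. Feature columns are
    selected by their ``<sequence>_<block>_`` prefix in the assembled table.
    """

    blocks: tuple[tuple[str, str], ...]
    learner: str = "elastic_net_logistic"
    cv_folds_hyper: int = 5
    eval_mode: str = "holdout"

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("a model needs at least one feature block")
        if self.learner not in ("elastic_net_logistic", "svm_linear", "svm_rbf"):
            raise ValueError(f"unknown learner {self.learner!r}")

    @property
    def name(self) -> str:
        fams = sorted({b for b, _ in self.blocks})
        seqs = sorted({s for _, s in self.blocks})
        return f"{'+'.join(fams)}[{'+'.join(seqs)}]:{self.learner}"

    def column_prefixes(self) -> list[str]:
        return [f"{seq}_{block}_" for block, seq in self.blocks]

    def select_columns(self, table: pd.DataFrame) -> list[str]:
        prefixes = tuple(self.column_prefixes())
        return [c for c in table.columns if c.startswith(prefixes)]

    def to_dict(self) -> dict:
        return {
            "blocks": [list(b) for b in self.blocks],
            "learner": self.learner,
            "cv_folds_hyper": self.cv_folds_hyper,
            "eval_mode": self.eval_mode,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(
            blocks=tuple(tuple(b) for b in d["blocks"]),
            learner=d.get("learner", "elastic_net_logistic"),
            cv_folds_hyper=d.get("cv_folds_hyper", 5),
            eval_mode=d.get("eval_mode", "holdout"),
        )


@dataclass
class ModelResult:
    spec: ModelSpec
    selected_features: list[str]
    coefficients: dict[str, float]
    auc_train: float
    auc_test: float
    accuracy_test: float
    auc_ci: tuple[float, float]
    p_value: float

    def to_dict(self) -> dict:
        return {
            "spec": self.spec.to_dict(),
            "selected_features": self.selected_features,
            "coefficients": self.coefficients,
            "auc_train": self.auc_train,
            "auc_test": self.auc_test,
            "accuracy_test": self.accuracy_test,
            "auc_ci": list(self.auc_ci),
            "p_value": self.p_value,
        }


class FittedModel:
    """Scaler + classifier fitted on training data, with feature bookkeeping."""

    def __init__(self, feature_names: list[str], scaler: StandardScaler, clf, learner: str):
        self.feature_names = feature_names
        self.scaler = scaler
        self.clf = clf
        self.learner = learner

    def scores(self, table: pd.DataFrame) -> np.ndarray:
        X = self.scaler.transform(_impute(table[self.feature_names]))
        if hasattr(self.clf, "predict_proba"):
            return self.clf.predict_proba(X)[:, 1]
        return self.clf.decision_function(X)

    @property
    def coefficients(self) -> dict[str, float]:
        if not hasattr(self.clf, "coef_"):
            return {}
        coef = np.ravel(self.clf.coef_)
        return {n: float(c) for n, c in zip(self.feature_names, coef)}

    @property
    def selected_features(self) -> list[str]:
        return [n for n, c in self.coefficients.items() if c != 0.0]


def _impute(table: pd.DataFrame) -> np.ndarray:
    """Median-impute residual missing values (vanished-tumor patients)."""
    X = table.to_numpy(dtype=float)
    if np.isnan(X).any():
        med = np.nanmedian(X, axis=0)
        med = np.where(np.isnan(med), 0.0, med)
        idx = np.nonzero(np.isnan(X))
        X[idx] = med[idx[1]]
    return X


def _prepare(table: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Drop constant/degenerate feature columns, warn via returned list."""
    X = _impute(table)
    keep = X.std(axis=0) > 0
    dropped = [c for c, k in zip(table.columns, keep) if not k]
    return table.loc[:, keep], dropped


def fit_elastic_net(
    train: pd.DataFrame,
    labels: np.ndarray,
    cv_folds: int = 5,
    seed: int = 0,
    l1_ratios: Sequence[float] = tuple(np.round(np.arange(0.1, 1.01, 0.1), 1)),
    n_cs: int = 25,
    max_iter: int = 5000,
) -> FittedModel:
    """Elastic-net logistic regression with CV-tuned penalty and mixing.

    Features are standardized on training statistics. The mixing parameter
    grid spans 0.1..1.0 in steps of 0.1 and the regularization path holds
    ``n_cs`` logarithmically spaced strengths; the winner maximizes mean
    cross-validated AUC over ``cv_folds`` stratified folds. Constant features
    are dropped before fitting.
    """
    labels = np.asarray(labels, dtype=int)
    if min(np.bincount(labels, minlength=2)) < cv_folds:
        raise ValueError("need at least cv_folds patients per class")
    train, _ = _prepare(train)
    scaler = StandardScaler().fit(_impute(train))
    X = scaler.transform(_impute(train))
    clf = LogisticRegressionCV(
        Cs=n_cs,
        l1_ratios=list(l1_ratios),
        solver="saga",
        scoring="roc_auc",
        cv=StratifiedKFold(cv_folds, shuffle=True, random_state=seed),
        max_iter=max_iter,
        tol=1e-3,
        random_state=seed,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(X, labels)
    return FittedModel(list(train.columns), scaler, clf, "elastic_net_logistic")


def fit_svm(
    train: pd.DataFrame,
    labels: np.ndarray,
    kernel: str = "linear",
    cv_folds: int = 5,
    seed: int = 0,
    c_grid: Sequence[float] = (0.01, 0.1, 1.0, 10.0, 100.0),
) -> FittedModel:
    """SVM comparator (linear or RBF/Gaussian kernel), AUC-tuned C by CV."""
    if kernel not in ("linear", "rbf"):
        raise ValueError("kernel must be 'linear' or 'rbf'")
    labels = np.asarray(labels, dtype=int)
    train, _ = _prepare(train)
    scaler = StandardScaler().fit(_impute(train))
    X = scaler.transform(_impute(train))
    search = GridSearchCV(
        SVC(kernel=kernel, gamma="scale"),
        {"C": list(c_grid)},
        scoring="roc_auc",
        cv=StratifiedKFold(cv_folds, shuffle=True, random_state=seed),
        n_jobs=1,
    )
    search.fit(X, labels)
    return FittedModel(list(train.columns), scaler, search.best_estimator_, f"svm_{kernel}")


def auc_mann_whitney(labels: np.ndarray, scores: np.ndarray) -> float:
    """AUC as the Mann-Whitney concordance (ties one half), unoriented."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes required")
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2
    return float(u / (len(pos) * len(neg)))


def delong_variance(labels: np.ndarray, scores: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance from placement values."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m < 2 or n < 2:
        raise ValueError("need >= 2 per class for a DeLong variance")
    all_ranks = sps.rankdata(np.concatenate([pos, neg]))
    pos_ranks = sps.rankdata(pos)
    neg_ranks = sps.rankdata(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2) / (m * n)
    v01 = (all_ranks[:m] - pos_ranks) / n        # placements of positives
    v10 = 1.0 - (all_ranks[m:] - neg_ranks) / m  # placements of negatives
    var = v01.var(ddof=1) / m + v10.var(ddof=1) / n
    return float(auc), float(var)


def delong_ci(labels: np.ndarray, scores: np.ndarray,
              level: float = 0.95) -> tuple[float, tuple[float, float], float]:
    """AUC, DeLong CI (clipped to [0, 1]) and two-sided p for AUC = 0.5."""
    auc, var = delong_variance(labels, scores)
    se = float(np.sqrt(var))
    z = sps.norm.ppf(0.5 + level / 2)
    lo, hi = max(0.0, auc - z * se), min(1.0, auc + z * se)
    if se > 0:
        p = float(2 * sps.norm.sf(abs(auc - 0.5) / se))
    else:
        p = 1.0 if auc == 0.5 else 0.0
    return auc, (lo, hi), p


def evaluate_holdout(
    model: FittedModel,
    spec: ModelSpec,
    train: pd.DataFrame,
    train_labels: np.ndarray,
    test: pd.DataFrame,
    test_labels: np.ndarray,
) -> ModelResult:
    """Train/test AUCs, test accuracy at probability 0.5, DeLong CI and p.

    Model AUCs are reported as-is (unoriented): a model scoring worse than
    chance reports AUC < 0.5.
    """
    test_labels = np.asarray(test_labels, dtype=int)
    if len(np.unique(test_labels)) < 2:
        raise ValueError("test set contains a single class")
    auc_train = auc_mann_whitney(train_labels, model.scores(train))
    scores = model.scores(test)
    auc_test, ci, p = delong_ci(test_labels, scores)
    if model.learner == "elastic_net_logistic":
        pred = (scores >= 0.5).astype(int)
    else:
        pred = (scores >= 0).astype(int)
    accuracy = float((pred == test_labels).mean())
    return ModelResult(
        spec=spec,
        selected_features=model.selected_features,
        coefficients={k: v for k, v in model.coefficients.items() if v != 0.0},
        auc_train=float(auc_train),
        auc_test=float(auc_test),
        accuracy_test=accuracy,
        auc_ci=ci,
        p_value=p,
    )


def cross_validate(
    table: pd.DataFrame,
    labels: np.ndarray,
    folds: int = 3,
    seed: int = 0,
    learner: str = "elastic_net_logistic",
    fit_kwargs: dict | None = None,
) -> float:
    """Pooled out-of-fold AUC from unstratified k-fold cross-validation.

    Folds are seed-controlled; if a fold's training part loses a class the
    split is redrawn with an incremented seed (logged by exception after 10
    attempts). Out-of-fold scores are pooled into a single AUC.
    """
    labels = np.asarray(labels, dtype=int)
    fit_kwargs = dict(fit_kwargs or {})
    for attempt in range(10):
        kf = KFold(n_splits=folds, shuffle=True, random_state=seed + attempt)
        splits = list(kf.split(table))
        if all(len(np.unique(labels[tr])) == 2 for tr, _ in splits):
            break
    else:
        raise RuntimeError("could not find folds with both classes in training parts")
    scores = np.empty(len(labels))
    for tr, te in splits:
        if learner == "elastic_net_logistic":
            model = fit_elastic_net(table.iloc[tr], labels[tr], seed=seed, **fit_kwargs)
        elif learner in ("svm_linear", "svm_rbf"):
            model = fit_svm(table.iloc[tr], labels[tr],
                            kernel=learner.split("_")[1], seed=seed, **fit_kwargs)
        else:
            raise ValueError(f"unknown learner {learner!r}")
        scores[te] = model.scores(table.iloc[te])
    return auc_mann_whitney(labels, scores)


def enumerate_model_grid(
    timepoints: Sequence[str] = TIMEPOINTS,
    sequences: Sequence[str] = SEQUENCES,
    combinations: Sequence[Sequence[str]] = (("C4", "AD_C4-BL"),),
    learner: str = "elastic_net_logistic",
) -> list[ModelSpec]:
    """Default candidate-model grid.

    One model per timepoint/delta family with all sequences combined (9
    single-family models under the full three-timepoint design), plus the
    configured multi-family combinations (default: the C4 + AD_C4-BL pairing).
    """
    families = list(timepoints)
    present = set(timepoints)
    for mode in DELTA_MODES:
        for late, early in DELTA_PAIRS:
            if late in present and early in present:
                families.append(delta_label(mode, late, early))
    specs = [
        ModelSpec(blocks=tuple((fam, seq) for seq in sequences), learner=learner)
        for fam in families
    ]
    for combo in combinations:
        if all(fam in families for fam in combo):
            specs.append(
                ModelSpec(
                    blocks=tuple((fam, seq) for fam in combo for seq in sequences),
                    learner=learner,
                )
            )
    return specs
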