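"""Univariate AUC screening of radiomic features.

Each feature is scored by the area under the ROC curve for separating pCR
from non-pCR patients, computed from the Mann-Whitney U statistic (ties count
one half) and oriented as max(AUC, 1 - AUC) so that discriminative features
score high regardless of effect direction. Significance comes from the
two-sided normal-approximated Mann-Whitney test with tie correction, the test
canonically paired with the AUC. A feature passes the screen when its AUC
reaches the floor in BOTH the training and testing sets and its training-set
p-value is below the ceiling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class UnivariateResult:
    feature_name: str
    auc_train: float
    auc_test: float
    p_value: float
    passes: bool


def feature_auc(values: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Oriented AUC and two-sided Mann-Whitney p for one feature.

    Missing values are excluded pairwise (with their labels). Raises if
    either class is absent or has fewer than 2 complete observations.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    ok = ~np.isnan(values)
    values, labels = values[ok], labels[ok]
    pos = values[labels == 1]
    neg = values[labels == 0]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("need >= 2 complete observations per class")
    auc, p = _mwu_auc(pos, neg)
    return max(auc, 1.0 - auc), p


def _mwu_auc(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    res = sps.mannwhitneyu(pos, neg, alternative="two-sided", method="asymptotic")
    auc = float(res.statistic) / (len(pos) * len(neg))
    return auc, float(res.pvalue)


def _auc_matrix(X: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise oriented AUC and p over a feature matrix, NaN-tolerant."""
    n_features = X.shape[1]
    aucs = np.full(n_features, np.nan)
    ps = np.full(n_features, np.nan)
    complete = ~np.isnan(X).any(axis=0)
    pos = labels == 1
    if complete.any():
        Xc = X[:, complete]
        res = sps.mannwhitneyu(Xc[pos], Xc[~pos], alternative="two-sided",
                               method="asymptotic", axis=0)
        auc = res.statistic / (pos.sum() * (~pos).sum())
        aucs[complete] = np.maximum(auc, 1.0 - auc)
        ps[complete] = res.pvalue
    for j in np.nonzero(~complete)[0]:
        try:
            aucs[j], ps[j] = feature_auc(X[:, j], labels)
        except ValueError:
            pass
    return aucs, ps


def screen_features(
    train: pd.DataFrame,
    train_labels: np.ndarray,
    test: pd.DataFrame,
    test_labels: np.ndarray,
    auc_floor: float = 0.7,
    p_ceiling: float = 0.001,
) -> pd.DataFrame:
    """Screen every feature column on train and test sets.

    Returns one row per feature with columns ``feature``, ``auc_train``,
    ``auc_test``, ``p_value`` and ``passes``, sorted by min(auc_train,
    auc_test) descending. Features whose AUC is undefined in either set (all
    missing, or a class lost to missingness) never pass.
    """
    if train.empty or test.empty:
        raise ValueError("empty feature table")
    if list(train.columns) != list(test.columns):
        raise ValueError("train and test feature schemas differ")
    auc_tr, p_tr = _auc_matrix(train.to_numpy(dtype=float), np.asarray(train_labels))
    auc_te, _ = _auc_matrix(test.to_numpy(dtype=float), np.asarray(test_labels))
    with np.errstate(invalid="ignore"):
        passes = (auc_tr >= auc_floor) & (auc_te >= auc_floor) & (p_tr < p_ceiling)
    out = pd.DataFrame(
        {
            "feature": train.columns,
            "auc_train": auc_tr,
            "auc_test": auc_te,
            "p_value": p_tr,
            "passes": np.where(np.isnan(auc_tr) | np.isnan(auc_te), False, passes),
        }
    )
    order = np.fmin(out["auc_train"], out["auc_test"]).fillna(-np.inf)
    return out.iloc[np.argsort(-order.to_numpy(), kind="stable")].reset_index(drop=True)
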