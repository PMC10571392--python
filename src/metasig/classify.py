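"""Random-forest case/control classification and CKD-severity analyses.

Discrimination is summarized by the area under the ROC curve (AUC) with a
DeLong 95% confidence interval.  Evaluation designs mirror a two-cohort
study: a stratified 70/30 split within a cohort, whole-cohort transfer
(train on one cohort, test on the other), and CKD generalization — a model
trained on 70% of healthy controls plus all end-stage (ESRD) patients is
tested on earlier-stage patients (CKD3/4, CKD5N) against the held-out
controls.  Severity trends sum the abundance of case- and control-enriched
signature species per sample across the ordered disease groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_curve
from sklearn.model_selection import train_test_split

from .catalog import ValidationError
from .signatures import q_values
from .simulate import GROUP_ORDER


@dataclass
class ClassifierResult:
    train_spec: str
    test_spec: str
    auc: float
    ci95: tuple
    roc_points: pd.DataFrame = field(repr=False, default=None)
    n_train: int = 0
    n_test: int = 0


class CaseControlClassifier(BaseEstimator, ClassifierMixin):
    """Random-forest disease classifier over species abundances.

    Thin sklearn-style estimator: ``fit`` trains the forest, ``predict_proba``
    yields case probabilities, and ``evaluate`` scores a held-out set with
    AUC and a DeLong 95% CI.
    """

    def __init__(self, n_estimators=500, max_features="sqrt",
                 min_samples_leaf=1, random_state=None, n_jobs=1):
        self.n_estimators = n_estimators
        self.max_features = max_features
        self.min_samples_leaf = min_samples_leaf
        self.random_state = random_state
        self.n_jobs = n_jobs

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y).astype(int).ravel()
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValidationError("exactly two classes required")
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_estimators,
            max_features=self.max_features,
            min_samples_leaf=self.min_samples_leaf,
            random_state=self.random_state,
            n_jobs=self.n_jobs,
        ).fit(X, y)
        self.feature_importances_ = self.forest_.feature_importances_
        return self

    def predict(self, X):
        return self.forest_.predict(np.asarray(X, float))

    def predict_proba(self, X):
        return self.forest_.predict_proba(np.asarray(X, float))

    def decision_scores(self, X):
        return self.predict_proba(X)[:, 1]

    def evaluate(self, X, y, train_spec="train", test_spec="test"):
        scores = self.decision_scores(X)
        y = np.asarray(y).astype(int).ravel()
        auc, ci = delong_auc_ci(y, scores)
        fpr, tpr, thr = roc_curve(y, scores)
        roc = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
        return ClassifierResult(train_spec, test_spec, auc, ci, roc,
                                n_test=len(y))


def auc_mann_whitney(y_true, scores) -> float:
    """AUC via the Mann-Whitney identity U / (n1*n0), ties counted half."""
    y_true = np.asarray(y_true).astype(int).ravel()
    scores = np.asarray(scores, float).ravel()
    pos = scores[y_true == 1]
    neg = scores[y_true == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("both classes required")
    greater = (pos[:, None] > neg[None, :]).sum()
    equal = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * equal) / (pos.size * neg.size))


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def delong_auc_ci(y_true, scores, alpha: float = 0.05):
    """AUC with its DeLong variance-based (1-alpha) confidence interval.

    The CI is computed on the logit scale and back-transformed, then clipped
    to [0, 1]; a degenerate variance (e.g. all scores tied) yields the full
    trivial interval around the point estimate.
    """
    y_true = np.asarray(y_true).astype(int).ravel()
    scores = np.asarray(scores, float).ravel()
    pos = scores[y_true == 1]
    neg = scores[y_true == 0]
    m, n = pos.size, neg.size
    if m == 0 or n == 0:
        raise ValidationError("both classes required")
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (all_ranks[:m] - pos_ranks) / n          # structural components
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    var = np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n if m > 1 and n > 1 else 0.0
    if var <= 0:
        return float(auc), (max(0.0, auc - 0.5), min(1.0, auc + 0.5))
    z = stats.norm.ppf(1 - alpha / 2)
    se = np.sqrt(var)
    lo = float(np.clip(auc - z * se, 0.0, 1.0))
    hi = float(np.clip(auc + z * se, 0.0, 1.0))
    return float(auc), (lo, hi)


def _stratified_split(y, test_size, seed):
    idx = np.arange(len(y))
    tr, te = train_test_split(idx, test_size=test_size, random_state=seed,
                              stratify=y)
    if len(np.unique(np.asarray(y)[tr])) < 2 or len(np.unique(np.asarray(y)[te])) < 2:
        raise ValidationError("a class is absent after the stratified split")
    return tr, te


def train_evaluate(table: pd.DataFrame, labels: pd.Series, split: float = 0.7,
                   seed: int = 0, **params) -> ClassifierResult:
    """Stratified split (default 70% train / 30% test), AUC with DeLong CI."""
    labels = labels.reindex(table.index).astype(int)
    tr, te = _stratified_split(labels.values, test_size=1 - split, seed=seed)
    clf = CaseControlClassifier(random_state=seed, **params)
    clf.fit(table.iloc[tr].values, labels.iloc[tr].values)
    res = clf.evaluate(table.iloc[te].values, labels.iloc[te].values,
                       train_spec=f"{split:.0%} split", test_spec="held-out")
    res.n_train = len(tr)
    return res


def cross_cohort_classify(train_table: pd.DataFrame, train_labels: pd.Series,
                          test_table: pd.DataFrame, test_labels: pd.Series,
                          seed: int = 0, **params) -> ClassifierResult:
    """Train on the entirety of one cohort, test on the entirety of the other."""
    shared_ids = set(train_table.index) & set(test_table.index)
    if shared_ids:
        raise ValidationError(
            f"train and test cohorts share samples: {sorted(shared_ids)[:5]}"
        )
    common = [c for c in train_table.columns if c in set(test_table.columns)]
    if not common:
        raise ValidationError("no shared features between cohorts")
    clf = CaseControlClassifier(random_state=seed, **params)
    clf.fit(train_table[common].values,
            train_labels.reindex(train_table.index).astype(int).values)
    res = clf.evaluate(test_table[common].values,
                       test_labels.reindex(test_table.index).astype(int).values,
                       train_spec="cohort A (all)", test_spec="cohort B (all)")
    res.n_train = len(train_table)
    return res


def ckd_generalization(table: pd.DataFrame, metadata: pd.DataFrame,
                       seed: int = 0, group_col: str = "group",
                       **params) -> dict:
    """Generalization of an HC-vs-ESRD model to earlier CKD stages.

    Train on 70% of HC plus all ESRD; test CKD3/4 and CKD5N each against the
    remaining 30% of HC.  Returns a ClassifierResult per CKD group.
    """
    meta = metadata.reindex(table.index)
    groups = set(meta[group_col])
    required = {"HC", "ESRD", "CKD3_4", "CKD5N"}
    if not required <= groups:
        raise ValidationError(f"missing groups: {sorted(required - groups)}")
    hc_idx = meta.index[meta[group_col] == "HC"]
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(hc_idx))
    n_train_hc = int(round(0.7 * len(hc_idx)))
    hc_train = hc_idx[perm[:n_train_hc]]
    hc_test = hc_idx[perm[n_train_hc:]]
    esrd_idx = meta.index[meta[group_col] == "ESRD"]
    train_ids = hc_train.append(esrd_idx)
    y_train = (meta.loc[train_ids, group_col] != "HC").astype(int)
    clf = CaseControlClassifier(random_state=seed, **params)
    clf.fit(table.loc[train_ids].values, y_train.values)
    out = {}
    for ckd in ("CKD3_4", "CKD5N"):
        ckd_idx = meta.index[meta[group_col] == ckd]
        test_ids = hc_test.append(ckd_idx)
        y_test = (meta.loc[test_ids, group_col] != "HC").astype(int)
        res = clf.evaluate(table.loc[test_ids].values, y_test.values,
                           train_spec="70% HC + ESRD",
                           test_spec=f"{ckd} vs 30% HC")
        res.n_train = len(train_ids)
        out[ckd] = res
    return out


def severity_trend(table: pd.DataFrame, case_set, control_set,
                   metadata: pd.DataFrame, group_col: str = "group"):
    """Signature-total abundance across the ordered severity groups.

    Per sample, abundances are summed over the case-enriched and the
    control-enriched signature sets.  Consecutive severity groups are
    compared by two-sided t-tests (BH-adjusted); a Spearman trend over the
    ordered group codes is reported for each set.
    """
    if not case_set or not control_set:
        raise ValidationError("signature sets must be non-empty")
    meta = metadata.reindex(table.index)
    order = [g for g in GROUP_ORDER if g in set(meta[group_col])]
    codes = meta[group_col].map({g: i for i, g in enumerate(order)})
    totals = pd.DataFrame(
        {
            "case_total": table[list(case_set)].sum(axis=1),
            "control_total": table[list(control_set)].sum(axis=1),
            "group": meta[group_col],
            "group_code": codes,
        }
    )
    tests = []
    for which in ("case_total", "control_total"):
        for g1, g2 in zip(order, order[1:]):
            a = totals.loc[totals["group"] == g1, which]
            b = totals.loc[totals["group"] == g2, which]
            if len(a) < 2 or len(b) < 2:
                p = np.nan
            else:
                p = float(stats.ttest_ind(a, b).pvalue)
            tests.append({"set": which, "pair": f"{g1}-{g2}", "p": p})
    tests = pd.DataFrame(tests)
    mask = tests["p"].notna()
    tests["q"] = np.nan
    tests.loc[mask, "q"] = q_values(tests.loc[mask, "p"].values)
    trend = {}
    for which in ("case_total", "control_total"):
        rho, p = stats.spearmanr(totals["group_code"], totals[which])
        trend[which] = {"rho": float(rho), "p": float(p)}
    return totals, tests, trend
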