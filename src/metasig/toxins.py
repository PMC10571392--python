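"""Random-forest explainability of serum uremic toxins from gut species.

For each toxin (IS, PCS, PAG, TMAO) a random-forest regressor is trained on
species relative abundances; leave-one-out cross-validation (LOOCV) yields an
out-of-sample prediction per sample, and the squared Pearson correlation
between LOOCV predictions and observations is the explainability R^2 — the
fraction of the toxin's variability the microbiota accounts for.  Species
are then ranked by permutation importance (IncMSE: increase in mean squared
error when a species' values are permuted), models are refit on growing
top-k prefixes, and the smallest k maximizing LOOCV R^2 defines the selected
contributor set.  Cross-cohort transfer (train on one cohort, test on the
other) probes whether contributors generalize.

Toxin concentrations are log-transformed and z-scored within cohort before
modeling, so results are invariant to affine rescaling of the assay and to
between-cohort quantification batch effects.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import LeaveOneOut, cross_val_predict, train_test_split

from .catalog import ValidationError
from .community import mantel_test  # noqa: F401  (re-exported: toxin-clinical linkage)
from .signatures import q_values


def default_k_grid(n_features: int) -> list:
    """1..30 by 1, then to min(150, p) by 5."""
    grid = list(range(1, min(30, n_features) + 1))
    grid += list(range(35, min(150, n_features) + 1, 5))
    if n_features not in grid and n_features <= 150:
        grid.append(n_features)
    return grid


def standardize_toxin(y: pd.Series, cohorts: pd.Series | None = None,
                      log: bool = True) -> pd.Series:
    """Within-cohort z-score of (log-) toxin concentration."""
    y = y.astype(float)
    if log:
        if (y <= 0).any():
            raise ValidationError("log standardization requires positive values")
        y = np.log(y)
    if cohorts is None:
        return (y - y.mean()) / y.std(ddof=0)
    out = y.copy()
    for c in cohorts.reindex(y.index).unique():
        mask = (cohorts.reindex(y.index) == c).values
        sub = y[mask]
        out[mask] = (sub - sub.mean()) / sub.std(ddof=0)
    return out


def _squared_pearson(pred, obs) -> float:
    pred, obs = np.asarray(pred, float), np.asarray(obs, float)
    if np.std(pred) == 0 or np.std(obs) == 0:
        return np.nan
    return float(np.corrcoef(pred, obs)[0, 1] ** 2)


class ToxinExplainer(BaseEstimator, RegressorMixin):
    """Random-forest explainability model for one toxin.

    Parameters
    ----------
    n_estimators, max_features, min_samples_leaf : forest hyperparameters.
        Defaults follow the R randomForest regression conventions the IncMSE
        measure comes from: 500 trees, p/3 features per split, leaves of 5.
    random_state : seed; required for reproducible LOOCV and importances.
    n_importance_repeats : permutation repeats per species for IncMSE.
    k_grid : iterable of prefix sizes for sequential selection, or None to
        skip the selection stage during ``fit``.

    Fitted attributes
    -----------------
    r2_full_ : LOOCV squared-Pearson R^2 on all species.
    r2_score_ : companion 1 - SSE/SST on the LOOCV predictions.
    importances_ : pd.Series of IncMSE per species (descending).
    ranking_ : species ids by decreasing importance, ties by id.
    r2_curve_, best_k_, selected_species_, r2_best_ : selection stage
        (present only when ``k_grid`` is not None).
    forest_ : RandomForestRegressor fitted on all samples and species.
    """

    def __init__(self, n_estimators=500, max_features=1 / 3,
                 min_samples_leaf=2, random_state=None, n_jobs=1,
                 n_importance_repeats=1, k_grid=None):
        self.n_estimators = n_estimators
        self.max_features = max_features
        self.min_samples_leaf = min_samples_leaf
        self.random_state = random_state
        self.n_jobs = n_jobs
        self.n_importance_repeats = n_importance_repeats
        self.k_grid = k_grid

    def _forest(self):
        return RandomForestRegressor(
            n_estimators=self.n_estimators,
            max_features=self.max_features,
            min_samples_leaf=self.min_samples_leaf,
            random_state=self.random_state,
            n_jobs=self.n_jobs,
        )

    def _validate(self, X, y):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, float))
            X.columns = [f"f{j}" for j in range(X.shape[1])]
        y = pd.Series(np.asarray(y, float).ravel(), index=X.index)
        if len(X) < 10:
            raise ValidationError("need at least 10 samples")
        if not np.isfinite(y).all():
            raise ValidationError("toxin values must be finite")
        return X, y

    def fit(self, X, y):
        X, y = self._validate(X, y)
        self.feature_names_in_ = np.array(X.columns)
        self.n_features_in_ = X.shape[1]
        if y.nunique() == 1:
            # constant target: R^2 undefined
            self.r2_full_ = np.nan
            self.r2_score_ = np.nan
            self.forest_ = self._forest().fit(X.values, y.values)
            self.importances_ = pd.Series(0.0, index=X.columns)
            self.ranking_ = list(X.columns)
            return self
        self.loocv_predictions_ = loocv_predictions(self._forest(), X, y)
        self.r2_full_ = _squared_pearson(self.loocv_predictions_, y)
        resid = y.values - self.loocv_predictions_
        sst = ((y.values - y.values.mean()) ** 2).sum()
        self.r2_score_ = float(1 - (resid**2).sum() / sst)
        self.forest_ = self._forest().fit(X.values, y.values)
        self.importances_ = rank_importance(
            self.forest_, X, y,
            n_repeats=self.n_importance_repeats,
            seed=self.random_state,
        )
        self.ranking_ = list(self.importances_.index)
        if self.k_grid is not None:
            curve, best_k, selected, r2_best = sequential_select(
                self._forest(), X, y, self.ranking_, self.k_grid
            )
            self.r2_curve_ = curve
            self.best_k_ = best_k
            self.selected_species_ = selected
            self.r2_best_ = r2_best
        return self

    def predict(self, X):
        if isinstance(X, pd.DataFrame):
            X = X[list(self.feature_names_in_)].values
        return self.forest_.predict(X)


def loocv_predictions(forest, X: pd.DataFrame, y: pd.Series) -> np.ndarray:
    """Out-of-sample prediction for every sample by leave-one-out refitting."""
    return cross_val_predict(clone(forest), X.values, y.values, cv=LeaveOneOut())


def loocv_explainability(X: pd.DataFrame, y: pd.Series, seed: int,
                         **forest_params) -> float:
    """LOOCV explainability R^2 (squared Pearson of predictions vs observed)."""
    model = ToxinExplainer(random_state=seed, **forest_params)
    X, y = model._validate(X, y)
    if y.nunique() == 1:
        return np.nan
    return _squared_pearson(loocv_predictions(model._forest(), X, y), y)


def rank_importance(forest, X: pd.DataFrame, y: pd.Series,
                    n_repeats: int = 1, seed=None) -> pd.Series:
    """Out-of-bag IncMSE per species, sorted descending (ties by id).

    For every tree, each species' values are permuted within that tree's
    out-of-bag samples and the increase of the tree's out-of-bag MSE is
    recorded; the importance is the average over trees (and ``n_repeats``
    permutations per tree, so the effective number of permutation draws is
    ``n_repeats * n_estimators``).  A constant column can never enter a
    split, so its IncMSE is exactly 0.
    """
    rng = np.random.default_rng(seed)
    xv = X.values
    yv = y.values
    n, p = xv.shape
    constant = np.array([np.all(xv[:, j] == xv[0, j]) for j in range(p)])
    totals = np.zeros(p)
    counts = np.zeros(p)
    for tree, inbag in zip(forest.estimators_, forest.estimators_samples_):
        oob = np.ones(n, dtype=bool)
        oob[inbag] = False
        if oob.sum() < 2:
            continue
        x_oob = xv[oob]
        y_oob = yv[oob]
        base_mse = float(np.mean((y_oob - tree.predict(x_oob)) ** 2))
        xp = x_oob.copy()
        for j in range(p):
            if constant[j]:
                continue
            deltas = 0.0
            for _ in range(n_repeats):
                xp[:, j] = rng.permutation(x_oob[:, j])
                mse = float(np.mean((y_oob - tree.predict(xp)) ** 2))
                deltas += mse - base_mse
            xp[:, j] = x_oob[:, j]
            totals[j] += deltas / n_repeats
            counts[j] += 1
    inc = np.where(counts > 0, totals / np.maximum(counts, 1), 0.0)
    s = pd.Series(inc, index=X.columns)
    order = sorted(s.index, key=lambda name: (-s[name], name))
    return s.loc[order]


def sequential_select(forest, X: pd.DataFrame, y: pd.Series, ranking,
                      k_grid) -> tuple:
    """Refit with top-k species prefixes; return (curve, best_k, selected, r2).

    ``best_k`` is the argmax of LOOCV R^2 over the grid, smallest k on ties.
    """
    k_grid = sorted(set(int(k) for k in k_grid))
    if not k_grid:
        raise ValidationError("k_grid must be non-empty")
    if k_grid[0] < 1 or k_grid[-1] > X.shape[1]:
        raise ValidationError("k_grid must lie within [1, n_species]")
    curve = {}
    for k in k_grid:
        feats = list(ranking[:k])
        curve[k] = _squared_pearson(
            loocv_predictions(clone(forest), X[feats], y), y
        )
    best_k = max(curve, key=lambda k: (np.nan_to_num(curve[k], nan=-1), -k))
    return curve, best_k, list(ranking[:best_k]), curve[best_k]


def transfer_evaluate(X_train, y_train, X_test=None, y_test=None,
                      mode: str = "external", seed: int = 0,
                      **forest_params) -> dict:
    """Transfer R^2: within-cohort 70/30 split or external-cohort evaluation.

    ``split70`` ignores the test arguments and holds out 30% of the training
    cohort; ``external`` trains on the full first cohort and predicts every
    sample of the second.  Overlapping sample ids between train and test are
    a contract violation.
    """
    model = ToxinExplainer(random_state=seed, **forest_params)
    X_train, y_train = model._validate(X_train, y_train)
    if mode == "split70":
        idx_train, idx_test = train_test_split(
            np.arange(len(X_train)), test_size=0.3, random_state=seed
        )
        Xa, ya = X_train.iloc[idx_train], y_train.iloc[idx_train]
        Xb, yb = X_train.iloc[idx_test], y_train.iloc[idx_test]
    elif mode == "external":
        if X_test is None or y_test is None:
            raise ValidationError("external mode needs a test cohort")
        X_test = pd.DataFrame(X_test)
        y_test = pd.Series(np.asarray(y_test, float).ravel(), index=X_test.index)
        shared_ids = set(X_train.index) & set(X_test.index)
        if shared_ids:
            raise ValidationError(
                f"train and test samples overlap: {sorted(shared_ids)[:5]}"
            )
        common = [c for c in X_train.columns if c in set(X_test.columns)]
        if not common:
            raise ValidationError("no shared species between cohorts")
        Xa, ya = X_train[common], y_train
        Xb, yb = X_test[common], y_test
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    forest = model._forest().fit(Xa.values, ya.values)
    pred = forest.predict(Xb.values)
    return {
        "mode": mode,
        "r2_transfer": _squared_pearson(pred, yb.values),
        "n_train": len(Xa),
        "n_test": len(Xb),
    }


def species_toxin_correlation(table: pd.DataFrame,
                              toxins: pd.DataFrame) -> pd.DataFrame:
    """Spearman rho and BH q for every (species, toxin) pair."""
    toxins = toxins.reindex(table.index)
    if len(table) < 5:
        raise ValidationError("need >= 5 paired observations")
    rows = []
    for toxin in toxins.columns:
        yv = toxins[toxin].values.astype(float)
        for sp in table.columns:
            xv = table[sp].values.astype(float)
            if np.unique(xv).size == 1 or np.unique(yv).size == 1:
                rho, p = np.nan, np.nan
            else:
                rho, p = stats.spearmanr(xv, yv)
            rows.append({"species": sp, "toxin": toxin, "rho": rho, "p": p})
    out = pd.DataFrame(rows)
    mask = out["p"].notna()
    out["q"] = np.nan
    out.loc[mask, "q"] = q_values(out.loc[mask, "p"].values)
    return out


def pooled_contributors(results: dict) -> list:
    """Union of selected contributor species over toxins (sorted)."""
    union = set()
    for res in results.values():
        union |= set(res.selected_species_ if hasattr(res, "selected_species_")
                     else res)
    return sorted(union)
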