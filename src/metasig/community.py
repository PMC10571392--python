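"""Community-level distances, ordination and variance partitioning.

Bray-Curtis dissimilarity is the between-sample metric throughout; principal
coordinates analysis (PCoA) eigendecomposes the Gower-centered squared
distance matrix; PERMANOVA partitions distance variance over metadata
factors (Anderson's pseudo-F with permutation p-values, with an exhaustive
enumeration mode for tiny designs); leading ordination axes are screened by
eigenvalue contribution and a Tracy-Widom statistic; alpha diversity reports
richness, Shannon entropy, and Pielou evenness.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .catalog import ValidationError


@dataclass
class PermanovaResult:
    factor: str
    r2: float
    pseudo_f: float
    p: float
    df: int
    n_perm: int


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame   # samples x retained (positive) axes
    eigenvalues: np.ndarray     # all axes, descending, negatives retained
    variance_explained: np.ndarray  # lambda_k / sum of positive lambdas


def bray_curtis(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity: sum|x-y| / sum(x+y)."""
    x = table.values.astype(float)
    if (x < 0).any():
        raise ValidationError("abundances must be nonnegative")
    rowsums = x.sum(axis=1)
    if (rowsums == 0).any():
        bad = list(table.index[rowsums == 0])
        raise ValidationError(f"zero-sum samples have undefined distances: {bad}")
    d = squareform(pdist(x, metric="braycurtis"))
    return pd.DataFrame(d, index=table.index, columns=table.index)


def _check_distance(dist: pd.DataFrame) -> np.ndarray:
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValidationError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0, atol=1e-8):
        raise ValidationError("distance matrix must have zero diagonal")
    return d


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def pcoa(dist: pd.DataFrame) -> OrdinationResult:
    """Classical multidimensional scaling of a distance matrix.

    Eigendecomposition of the double-centered Gower matrix.  Negative
    eigenvalues (non-Euclidean distances) are retained in the report but
    excluded from both the coordinates and the variance-explained
    denominator.
    """
    d = _check_distance(dist)
    g = _gower_center(d)
    eigvals, eigvecs = np.linalg.eigh((g + g.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = 1e-9 * max(1.0, np.abs(eigvals).max())
    pos = eigvals > tol
    pos_sum = eigvals[pos].sum()
    variance = eigvals / pos_sum if pos_sum > 0 else np.zeros_like(eigvals)
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    axes = [f"PC{i + 1}" for i in range(int(pos.sum()))]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=dist.index, columns=axes),
        eigenvalues=eigvals,
        variance_explained=variance,
    )


def _model_matrix(factors: pd.DataFrame) -> np.ndarray:
    cols = [np.ones(len(factors))]
    for name in factors.columns:
        col = factors[name]
        if col.dtype.kind in "fiu" and col.nunique() > 2:
            cols.append(col.values.astype(float) - col.values.astype(float).mean())
        else:
            dummies = pd.get_dummies(col.astype(str), drop_first=True)
            for c in dummies.columns:
                cols.append(dummies[c].values.astype(float))
    return np.column_stack(cols)


def _hat(x: np.ndarray) -> np.ndarray:
    return x @ np.linalg.pinv(x.T @ x) @ x.T


def _pseudo_f(g: np.ndarray, x: np.ndarray):
    """Anderson's pseudo-F of the model matrix ``x`` (with intercept) on the
    Gower-centered matrix ``g``; returns (F, R2, df_model)."""
    n = g.shape[0]
    h = _hat(x)
    rank = int(np.round(np.trace(h)))
    ss_total = np.trace(g)
    ss_model = np.trace(h @ g)
    ss_resid = ss_total - ss_model
    df_model = rank - 1
    df_resid = n - rank
    if df_model < 1 or df_resid < 1 or ss_total <= 0 or ss_resid <= 0:
        return np.nan, np.nan, df_model
    f = (ss_model / df_model) / (ss_resid / df_resid)
    return f, ss_model / ss_total, df_model


def permanova(
    dist: pd.DataFrame,
    factors,
    n_perm: int = 1000,
    seed: int | None = None,
    mode: str = "marginal",
    exhaustive: bool = False,
) -> list:
    """Permutational multivariate ANOVA on a distance matrix.

    ``factors`` is a Series (one factor) or DataFrame (several).  In
    ``marginal`` mode each factor is fitted alone; in ``sequential`` mode
    factors are added in column order and each term's sum of squares is the
    increment over the preceding model (residual from the full model).
    p-values come from ``n_perm`` random permutations of sample identity,
    ``p = (1 + #{F_perm >= F_obs}) / (n_perm + 1)``, or from exhaustive
    enumeration of all distinct assignments when ``exhaustive`` is set
    (single categorical factor, small n only).
    """
    if isinstance(factors, pd.Series):
        factors = factors.to_frame()
    factors = factors.reindex(dist.index)
    if factors.isna().any().any():
        raise ValidationError("factors missing for some samples")
    for name in factors.columns:
        col = factors[name]
        if col.dtype.kind not in "fiu" and col.nunique() < 2:
            raise ValidationError(f"factor {name!r} has a single level")
    d = _check_distance(dist)
    g = _gower_center(d)
    n = d.shape[0]
    rng = np.random.default_rng(seed)

    if exhaustive:
        if factors.shape[1] != 1:
            raise ValidationError("exhaustive mode supports a single factor")
        name = factors.columns[0]
        labels = factors[name].astype(str).values
        x_obs = _model_matrix(factors)
        f_obs, r2, df_model = _pseudo_f(g, x_obs)
        values, counts = np.unique(labels, return_counts=True)
        count_ge = total = 0
        for perm in _multiset_permutations(labels):
            x = _model_matrix(pd.DataFrame({name: perm}, index=factors.index))
            f_p, _, _ = _pseudo_f(g, x)
            total += 1
            if f_p >= f_obs - 1e-9 * abs(f_obs) - 1e-12:
                count_ge += 1
        return [PermanovaResult(name, r2, f_obs, count_ge / total, df_model, total)]

    results = []
    if mode == "marginal":
        terms = [(name, factors[[name]]) for name in factors.columns]
        for name, fr in terms:
            x = _model_matrix(fr)
            h = _hat(x)
            rank = int(np.round(np.trace(h)))
            df_model, df_resid = rank - 1, n - rank
            ss_total = np.trace(g)
            ss_model = float((h * g).sum())  # tr(HG), both symmetric
            f_obs = (ss_model / df_model) / ((ss_total - ss_model) / df_resid)
            r2 = ss_model / ss_total
            count = 0
            for _ in range(n_perm):
                idx = rng.permutation(n)
                ss_p = float((h * g[np.ix_(idx, idx)]).sum())
                f_p = (ss_p / df_model) / ((ss_total - ss_p) / df_resid)
                if f_p >= f_obs:
                    count += 1
            results.append(
                PermanovaResult(name, r2, f_obs, (1 + count) / (n_perm + 1),
                                df_model, n_perm)
            )
    elif mode == "sequential":
        names = list(factors.columns)
        full_h = _hat(_model_matrix(factors))
        full_rank = int(np.round(np.trace(full_h)))
        ss_total = np.trace(g)
        df_resid = n - full_rank
        hats = [_hat(np.ones((n, 1)))]
        for k in range(len(names)):
            hats.append(_hat(_model_matrix(factors[names[: k + 1]])))
        dfs = [
            int(np.round(np.trace(hats[k + 1]))) - int(np.round(np.trace(hats[k])))
            for k in range(len(names))
        ]

        def term_stats(gm):
            ss_resid_full = np.trace(gm) - float((full_h * gm).sum())
            stats_out = []
            for k, name in enumerate(names):
                ss_term = float((hats[k + 1] * gm).sum()) - float(
                    (hats[k] * gm).sum()
                )
                f = (
                    (ss_term / dfs[k]) / (ss_resid_full / df_resid)
                    if dfs[k] >= 1 and ss_resid_full > 0 and df_resid >= 1
                    else np.nan
                )
                stats_out.append((name, ss_term, dfs[k], f))
            return stats_out

        obs = term_stats(g)
        counts = np.zeros(len(names))
        for _ in range(n_perm):
            idx = rng.permutation(n)
            perm = term_stats(g[np.ix_(idx, idx)])
            for k in range(len(names)):
                if perm[k][3] >= obs[k][3]:
                    counts[k] += 1
        for k, (name, ss_term, df_term, f) in enumerate(obs):
            results.append(
                PermanovaResult(
                    name, ss_term / ss_total, f,
                    (1 + counts[k]) / (n_perm + 1), df_term, n_perm,
                )
            )
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    return results


def _multiset_permutations(labels):
    values = sorted(set(labels))
    n = len(labels)
    positions = list(range(n))
    counts = {v: sum(1 for x in labels if x == v) for v in values}

    def rec(remaining_positions, remaining_values):
        if not remaining_values:
            yield {}
            return
        v = remaining_values[0]
        for combo in itertools.combinations(remaining_positions, counts[v]):
            rest = [p for p in remaining_positions if p not in combo]
            for tail in rec(rest, remaining_values[1:]):
                assignment = dict(tail)
                for p in combo:
                    assignment[p] = v
                yield assignment

    for assignment in rec(positions, values):
        yield [assignment[i] for i in range(n)]


# Tracy-Widom (GOE, beta=1) upper-tail quantiles, Patterson-style screening.
_TW1_QUANTILES = {0.10: 0.4501, 0.05: 0.9793, 0.025: 1.4536, 0.01: 2.0234,
                  0.001: 3.2724}


def tracy_widom_statistic(eigenvalues: np.ndarray, n_samples: int, k: int = 0):
    """Normalized Tracy-Widom statistic for the k-th (0-based) eigenvalue.

    The tested eigenvalue is scaled against the trailing spectrum; the
    effective sample size is moment-estimated from the eigenvalues below the
    tested one so that a dominant axis cannot distort its own null scale, and
    falls back to the true sample count when the estimate is degenerate or
    exceeds it.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    lam = lam[lam > 0][k:]
    m = lam.size
    if m < 2:
        return np.nan
    s1 = lam.sum()
    rest = lam[1:]
    r1, r2 = rest.sum(), (rest**2).sum()
    mr = rest.size
    n_eff = float(n_samples)
    if mr >= 2 and r1 > 0:
        denom = (mr - 1) * r2 / r1**2 - 1.0
        if denom > 0:
            n_eff = min((mr + 1) / denom, float(n_samples))
    if n_eff <= 1:
        return np.nan
    ell = m * lam[0] / s1
    a, b = np.sqrt(n_eff - 1), np.sqrt(m)
    mu = (a + b) ** 2 / n_eff
    sigma = (a + b) / n_eff * (1 / a + 1 / b) ** (1 / 3)
    return (ell - mu) / sigma


def pc_screen(
    eigenvalues: np.ndarray,
    n_samples: int,
    alpha: float = 0.05,
    min_contribution: float = 0.03,
) -> list:
    """Indices (1-based) of ordination axes that are both substantial and
    significant: variance contribution > ``min_contribution`` and
    Tracy-Widom statistic above the 1-alpha quantile."""
    if alpha not in _TW1_QUANTILES:
        raise ValidationError(
            f"alpha must be one of {sorted(_TW1_QUANTILES)} (tabulated quantiles)"
        )
    lam = np.asarray(eigenvalues, dtype=float)
    pos = lam[lam > 0]
    if pos.size < 2:
        return []
    contrib = pos / pos.sum()
    cutoff = _TW1_QUANTILES[alpha]
    kept = []
    for k in range(pos.size):
        if contrib[k] <= min_contribution:
            break  # eigenvalues are sorted; later axes contribute less
        tw = tracy_widom_statistic(pos, n_samples, k)
        if np.isnan(tw) or tw <= cutoff:
            break
        kept.append(k + 1)
    return kept


def pc_screen_permutation(
    table: pd.DataFrame,
    n_perm: int = 199,
    alpha: float = 0.05,
    min_contribution: float = 0.03,
    seed: int | None = None,
) -> list:
    """Permutation-based axis screening: species columns are shuffled
    independently across samples and the eigenvalue share of each axis is
    compared with its permutation distribution."""
    rng = np.random.default_rng(seed)
    obs = pcoa(bray_curtis(table))
    pos_obs = obs.eigenvalues[obs.eigenvalues > 0]
    n_axes = pos_obs.size
    if n_axes == 0:
        return []
    exceed = np.zeros(n_axes)
    x = table.values.copy()
    for _ in range(n_perm):
        xp = np.column_stack([rng.permutation(x[:, j]) for j in range(x.shape[1])])
        perm_tbl = pd.DataFrame(xp, index=table.index, columns=table.columns)
        lam = pcoa(bray_curtis(perm_tbl)).eigenvalues
        lam = lam[lam > 0]
        for k in range(n_axes):
            val = lam[k] if k < lam.size else 0.0
            if val >= pos_obs[k]:
                exceed[k] += 1
    pvals = (1 + exceed) / (n_perm + 1)
    contrib = pos_obs / pos_obs.sum()
    return [
        k + 1
        for k in range(n_axes)
        if contrib[k] > min_contribution and pvals[k] < alpha
    ]


def alpha_diversity(table: pd.DataFrame, detection: float = 0.0) -> pd.DataFrame:
    """Per-sample richness, Shannon index (natural log) and Pielou evenness.

    Metrics are computed on proportions renormalized over detected features,
    so they are invariant to uniform rescaling of a sample's counts.
    Evenness is undefined (NaN) when richness <= 1; all metrics are NaN for
    an empty sample.
    """
    rows = []
    for sid, row in table.iterrows():
        x = row.values.astype(float)
        x = x[x > detection]
        if x.size == 0:
            rows.append({"sample_id": sid, "richness": np.nan,
                         "shannon": np.nan, "evenness": np.nan})
            continue
        p = x / x.sum()
        h = float(-(p * np.log(p)).sum())
        richness = int(x.size)
        evenness = h / np.log(richness) if richness > 1 else np.nan
        rows.append({"sample_id": sid, "richness": richness,
                     "shannon": h, "evenness": evenness})
    return pd.DataFrame(rows).set_index("sample_id")


def mantel_test(
    dist1: pd.DataFrame,
    dist2: pd.DataFrame,
    n_perm: int = 9999,
    seed: int | None = None,
    exhaustive: bool = False,
):
    """Mantel correlation between two distance matrices.

    r is the Pearson correlation of the off-diagonal entries; significance
    comes from jointly permuting rows and columns of the second matrix:
    ``p = (1 + #{r_perm >= r_obs}) / (n_perm + 1)``.  ``exhaustive``
    enumerates all n! permutations (identity included) instead.
    """
    if list(dist1.index) != list(dist2.index):
        raise ValidationError("distance matrices must share sample ids in order")
    d1 = _check_distance(dist1)
    d2 = _check_distance(dist2)
    n = d1.shape[0]
    iu = np.triu_indices(n, k=1)
    v1 = d1[iu]

    def corr(mat):
        v2 = mat[iu]
        if v1.std() == 0 or v2.std() == 0:
            raise ValidationError("constant distance matrix; r undefined")
        return float(np.corrcoef(v1, v2)[0, 1])

    r_obs = corr(d2)
    if exhaustive:
        count = total = 0
        for perm in itertools.permutations(range(n)):
            idx = np.array(perm)
            if corr(d2[np.ix_(idx, idx)]) >= r_obs - 1e-12:
                count += 1
            total += 1
        return r_obs, count / total
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        idx = rng.permutation(n)
        if corr(d2[np.ix_(idx, idx)]) >= r_obs:
            count += 1
    return r_obs, (1 + count) / (n_perm + 1)
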