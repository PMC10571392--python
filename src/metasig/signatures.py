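"""Cross-cohort differential-abundance testing and signature calling.

Each feature (species, KO, or module abundance) is tested case vs control
within each cohort by the two-sided Wilcoxon rank-sum test, fold changes are
computed on pseudocounted group means, per-cohort p-values are FDR-adjusted,
the two cohorts' p-values are combined by Fisher's method, and a feature is
called a disease signature only when

1. q < 0.2 and fold change > 1.2 in each cohort, with coherent enrichment
   direction (case- or control-enriched in both), and
2. the FDR-adjusted combined p (combined q) is < 0.05.

The coherence requirement across two independent cohorts is the design's
guard against cohort-specific artifacts.  A rank-based linear model is
provided to verify that calls survive adjustment for sex, age and BMI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .catalog import ValidationError

CASE_ENRICHED = "case_enriched"
CONTROL_ENRICHED = "control_enriched"
NONE = "none"


@dataclass
class CohortTestResult:
    feature: str
    p: float
    fc: float
    direction: str
    q: float = np.nan


def pseudocount(table: pd.DataFrame) -> float:
    """Half the smallest nonzero abundance of the whole table (0 if all-zero)."""
    vals = table.values
    nz = vals[vals > 0]
    return float(nz.min() / 2.0) if nz.size else 0.0


def wilcoxon_rank_sum(case: np.ndarray, control: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact by enumeration when the smaller group has <= 8 samples and there
    are no ties across the pooled data; otherwise the normal approximation
    with tie and continuity corrections.
    """
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    if case.size < 2 or control.size < 2:
        raise ValidationError("each group needs >= 2 samples")
    pooled = np.concatenate([case, control])
    no_ties = np.unique(pooled).size == pooled.size
    if min(case.size, control.size) <= 8 and no_ties:
        method = "exact"
    else:
        method = "asymptotic"
    if np.all(pooled == pooled[0]):
        return 1.0
    return float(
        stats.mannwhitneyu(case, control, alternative="two-sided", method=method).pvalue
    )


def per_cohort_test(
    table: pd.DataFrame, is_case: pd.Series, delta: float | None = None
) -> pd.DataFrame:
    """Per-feature Wilcoxon p and pseudocounted fold change for one cohort.

    ``fc`` = (mean_case + delta) / (mean_control + delta) with delta half the
    table's smallest nonzero abundance.  Direction follows the sign of
    log(fc); fc == 1 leaves the direction undefined (never called).
    """
    is_case = is_case.reindex(table.index)
    if is_case.isna().any():
        raise ValidationError("labels missing for some samples")
    case_mask = is_case.astype(bool).values
    if case_mask.sum() < 2 or (~case_mask).sum() < 2:
        raise ValidationError("each group needs >= 2 samples")
    if delta is None:
        delta = pseudocount(table)
    rows = []
    case_tbl = table.values[case_mask]
    ctrl_tbl = table.values[~case_mask]
    for j, feature in enumerate(table.columns):
        cvals, kvals = case_tbl[:, j], ctrl_tbl[:, j]
        if np.all(cvals == 0) and np.all(kvals == 0):
            p, fc = 1.0, 1.0
        else:
            p = wilcoxon_rank_sum(cvals, kvals)
            fc = (cvals.mean() + delta) / (kvals.mean() + delta) if delta > 0 or (
                kvals.mean() > 0
            ) else np.nan
        if fc > 1:
            direction = CASE_ENRICHED
        elif fc < 1:
            direction = CONTROL_ENRICHED
        else:
            direction = NONE
        rows.append({"feature": feature, "p": p, "fc": fc, "direction": direction})
    out = pd.DataFrame(rows).set_index("feature")
    out["q"] = q_values(out["p"].values)
    return out


def combine_pvalues_fisher(p1, p2):
    """Fisher's method for two independent p-values.

    X = -2(ln p1 + ln p2) referred to the chi-square distribution with 4
    degrees of freedom.  Nonpositive p-values are clamped to the smallest
    positive float with a warning.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    tiny = np.finfo(float).tiny
    if np.any(p1 <= 0) or np.any(p2 <= 0):
        warnings.warn("nonpositive p-values clamped for Fisher combination")
    p1 = np.clip(p1, tiny, 1.0)
    p2 = np.clip(p2, tiny, 1.0)
    x = -2.0 * (np.log(p1) + np.log(p2))
    return stats.chi2.sf(x, df=4)


def q_values(p, method: str = "bh") -> np.ndarray:
    """FDR-adjusted values: Benjamini-Hochberg (``bh``) or empirical-null
    local-FDR-derived tail-area values (``local_fdr``).

    The local_fdr path probit-transforms the p-values, fits an Efron-style
    empirical null to the z-scores, and converts the local estimates to
    tail-area q-values by running means over the sorted significance order.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    if method == "local_fdr":
        from statsmodels.stats.multitest import local_fdr

        if p.size < 20:
            # empirical-null density estimation is meaningless at tiny m
            return multipletests(p, method="fdr_bh")[1]
        tiny = np.finfo(float).tiny
        z = stats.norm.isf(np.clip(p, tiny, 1 - 1e-15))
        try:
            lfdr = np.clip(local_fdr(z), 0.0, 1.0)
        except Exception:  # density fit can fail on degenerate inputs
            return multipletests(p, method="fdr_bh")[1]
        order = np.argsort(p, kind="mergesort")
        q = np.empty_like(p)
        q[order] = np.cumsum(lfdr[order]) / np.arange(1, p.size + 1)
        # enforce monotonicity in p like a step-up procedure
        q[order] = np.minimum.accumulate(q[order][::-1])[::-1]
        return np.clip(q, 0.0, 1.0)
    raise ValidationError(f"unknown FDR method {method!r}")


def call_signatures(
    cohort1: pd.DataFrame,
    cohort2: pd.DataFrame,
    fc_threshold: float = 1.2,
    q_threshold: float = 0.2,
    combined_q_threshold: float = 0.05,
    fdr_method: str = "bh",
) -> pd.DataFrame:
    """Apply the two-criterion signature rule to a pair of cohort results.

    The fold-change criterion is direction-symmetric: fc > 1.2 for a
    case-enriched call, fc < 1/1.2 for a control-enriched call.  Combined q
    is computed on the Fisher-combined p across the full feature universe.
    """
    if set(cohort1.index) != set(cohort2.index):
        raise ValidationError("cohorts must share the same feature universe")
    c2 = cohort2.reindex(cohort1.index)
    out = pd.DataFrame(index=cohort1.index)
    out["p_c1"], out["q_c1"], out["fc_c1"] = (
        cohort1["p"], cohort1["q"], cohort1["fc"],
    )
    out["p_c2"], out["q_c2"], out["fc_c2"] = c2["p"], c2["q"], c2["fc"]
    out["combined_p"] = combine_pvalues_fisher(out["p_c1"], out["p_c2"])
    out["combined_q"] = q_values(out["combined_p"].values, method=fdr_method)

    lo = 1.0 / fc_threshold
    calls = []
    for _, r in out.iterrows():
        up = (
            r["q_c1"] < q_threshold and r["q_c2"] < q_threshold
            and r["fc_c1"] > fc_threshold and r["fc_c2"] > fc_threshold
        )
        down = (
            r["q_c1"] < q_threshold and r["q_c2"] < q_threshold
            and r["fc_c1"] < lo and r["fc_c2"] < lo
        )
        if r["combined_q"] < combined_q_threshold and up:
            calls.append(CASE_ENRICHED)
        elif r["combined_q"] < combined_q_threshold and down:
            calls.append(CONTROL_ENRICHED)
        else:
            calls.append(NONE)
    out["call"] = calls
    return out


def discover_signatures(
    table: pd.DataFrame,
    metadata: pd.DataFrame,
    cohort_col: str = "cohort",
    case_col: str = "is_case",
    fdr_method: str = "bh",
    **thresholds,
) -> pd.DataFrame:
    """End-to-end two-cohort signature discovery on an abundance table."""
    meta = metadata.reindex(table.index)
    cohorts = sorted(meta[cohort_col].dropna().unique())
    if len(cohorts) != 2:
        raise ValidationError(
            f"exactly two cohorts required, found {len(cohorts)}: {cohorts}"
        )
    per_cohort = []
    for c in cohorts:
        mask = (meta[cohort_col] == c).values
        res = per_cohort_test(table.loc[mask], meta.loc[mask, case_col])
        res["q"] = q_values(res["p"].values, method=fdr_method)
        per_cohort.append(res)
    return call_signatures(*per_cohort, fdr_method=fdr_method, **thresholds)


def differential_functions(
    function_table: pd.DataFrame, metadata: pd.DataFrame, **kwargs
) -> pd.DataFrame:
    """Signature calling on a KO/module abundance table (same machinery)."""
    return discover_signatures(function_table, metadata, **kwargs)


def adjust_covariates(
    table: pd.DataFrame,
    is_case: pd.Series,
    covariates: pd.DataFrame,
) -> pd.Series:
    """Group p-values adjusted for covariates via a rank linear model.

    Per feature, abundances are rank-transformed and regressed on the group
    indicator plus the covariates; the two-sided p of the group coefficient
    is returned.  Zero-variance features and singular fits yield NaN.
    Categorical covariates (e.g. sex) are dummy-coded.
    """
    import statsmodels.api as sm

    keep = covariates.dropna().index.intersection(table.index)
    if len(keep) < len(table.index):
        warnings.warn(
            f"dropped {len(table.index) - len(keep)} samples with missing covariates"
        )
    tbl = table.loc[keep]
    grp = is_case.reindex(keep).astype(float).values
    cov = pd.get_dummies(covariates.loc[keep], drop_first=True).astype(float)
    X = np.column_stack([np.ones(len(keep)), grp, cov.values])
    out = {}
    for feature in tbl.columns:
        y = tbl[feature].values
        if np.unique(y).size == 1:
            out[feature] = np.nan
            continue
        ranks = stats.rankdata(y)
        try:
            fit = sm.OLS(ranks, X).fit()
            out[feature] = float(fit.pvalues[1])
        except Exception:
            out[feature] = np.nan
    return pd.Series(out, name="adjusted_p")
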