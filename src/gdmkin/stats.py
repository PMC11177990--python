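"""Group comparisons and clinical-score correlations.

Two-sample Student t-tests (pooled variance) with pooled-SD Cohen's d per
feature and contrast, Benjamini–Hochberg FDR across features within each
contrast, and Spearman rank correlations between subject-level GDM
features and ordinal clinical scores with all groups pooled so the full
health spectrum contributes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

DEFAULT_CONTRASTS = (("HD", "pHD"), ("HD", "CTR"), ("pHD", "CTR"))


@dataclass
class GroupStatsResult:
    feature: str
    contrast: str
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t_stat: float
    p_value: float
    cohens_d: float
    fdr_significant: bool = False


def two_sample_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Student t-test with pooled variance.

    Pooled (not Welch) variance: back-computing the published p-values from
    the printed effect sizes and group sizes matches the pooled-variance
    test.
    """
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        warnings.warn("zero pooled variance: p-value undefined", stacklevel=2)
        return float("nan"), float("nan")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def cohens_d_from_summary(
    mean_a: float, sd_a: float, n_a: int, mean_b: float, sd_b: float, n_b: int
) -> float:
    """Pooled-SD Cohen's d from group summary statistics.

    d = (mean_a − mean_b) / s_p with
    s_p = sqrt(((n_a−1) sd_a² + (n_b−1) sd_b²) / (n_a + n_b − 2)).
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs n >= 2")
    if sd_a < 0 or sd_b < 0:
        raise ValueError("standard deviations must be non-negative")
    pooled = np.sqrt(((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / (n_a + n_b - 2))
    if pooled == 0:
        warnings.warn("zero pooled SD: Cohen's d undefined", stacklevel=2)
        return float("nan")
    return float((mean_a - mean_b) / pooled)


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Pooled-SD Cohen's d from raw samples."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    return cohens_d_from_summary(
        a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b)
    )


def summary_t_p(
    mean_a: float, sd_a: float, n_a: int, mean_b: float, sd_b: float, n_b: int
) -> tuple[float, float]:
    """Pooled two-sample t statistic and two-sided p from summary statistics."""
    d = cohens_d_from_summary(mean_a, sd_a, n_a, mean_b, sd_b, n_b)
    t = d * np.sqrt(n_a * n_b / (n_a + n_b))
    df = n_a + n_b - 2
    p = 2 * sps.t.sf(abs(t), df)
    return float(t), float(p)


def fdr_adjust(p_values: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up adjusted p-values and significance mask."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, adjusted, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return adjusted, reject


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties; two-sided p."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant vector: Spearman rho undefined", stacklevel=2)
        return float("nan"), float("nan")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def group_stats_table(
    features: pd.DataFrame,
    feature_cols: list[str],
    group_col: str = "group",
    contrasts: tuple[tuple[str, str], ...] = DEFAULT_CONTRASTS,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-feature, per-contrast t/d/p with BH-FDR applied within contrast.

    The effect direction is always first-listed minus second-listed group.
    """
    rows: list[GroupStatsResult] = []
    for ga, gb in contrasts:
        sub_rows: list[GroupStatsResult] = []
        a_df = features[features[group_col] == ga]
        b_df = features[features[group_col] == gb]
        for col in feature_cols:
            a, b = a_df[col].to_numpy(float), b_df[col].to_numpy(float)
            t, p = two_sample_test(a, b)
            d = cohens_d(a, b)
            sub_rows.append(
                GroupStatsResult(
                    feature=col,
                    contrast=f"{ga}_vs_{gb}",
                    mean_a=a.mean(),
                    sd_a=a.std(ddof=1),
                    n_a=len(a),
                    mean_b=b.mean(),
                    sd_b=b.std(ddof=1),
                    n_b=len(b),
                    t_stat=t,
                    p_value=p,
                    cohens_d=d,
                )
            )
        pvals = np.array([r.p_value for r in sub_rows])
        ok = ~np.isnan(pvals)
        if ok.any():
            _, reject = fdr_adjust(pvals[ok], alpha)
            for r, rej in zip([r for r, o in zip(sub_rows, ok) if o], reject):
                r.fdr_significant = bool(rej)
        rows.extend(sub_rows)
    return pd.DataFrame([vars(r) for r in rows])


def correlation_table(
    features: pd.DataFrame,
    feature_cols: list[str],
    score_cols: list[str],
) -> pd.DataFrame:
    """Spearman rho and p for every (feature, clinical score) pair, groups pooled."""
    rows = []
    for feat in feature_cols:
        for score in score_cols:
            pair = features[[feat, score]].dropna()
            rho, p = spearman(pair[feat].to_numpy(), pair[score].to_numpy())
            rows.append({"feature": feat, "score": score, "spearman_rho": rho, "p_value": p})
    return pd.DataFrame(rows)
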