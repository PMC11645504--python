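"""Group-comparison statistics and the classifier's variable filter.

Normally distributed attributes are compared with the pooled-variance
independent-samples t test (df = n1 + n2 - 2); count data with Pearson's
chi-square (no continuity correction); non-normal biomarkers with the
Wilcoxon Mann-Whitney U test; multi-group comparisons with Kruskal-Wallis
followed by Bonferroni-adjusted pairwise tests.  The t test accepts
published summary statistics (mean, SD, n) as well as raw samples, so
printed group tables can be re-checked directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class TestResult:
    name: str
    statistic: float
    p_value: float
    df: float | None = None


def pooled_t_test_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> TestResult:
    """Two-sided pooled-variance t test from group summary statistics."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be nonnegative")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    if sp2 == 0:
        if mean1 == mean2:
            return TestResult("pooled t", 0.0, 1.0, df)
        return TestResult("pooled t", np.inf if mean1 > mean2 else -np.inf, 0.0, df)
    t = (mean1 - mean2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult("pooled t", float(t), float(p), df)


def pooled_t_test(x1: np.ndarray, x2: np.ndarray) -> TestResult:
    """Two-sided pooled-variance t test from raw samples."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    return pooled_t_test_from_summary(
        float(x1.mean()), float(x1.std(ddof=1)), x1.size,
        float(x2.mean()), float(x2.std(ddof=1)), x2.size,
    )


def chi_square_test(table: np.ndarray) -> TestResult:
    """Pearson chi-square on an r x c contingency table, no Yates correction."""
    table = np.asarray(table, dtype=float)
    if np.any(table < 0):
        raise ValueError("contingency counts must be nonnegative")
    if table.sum() <= 0:
        raise ValueError("empty contingency table")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero marginal")
    chi2, p, df, _ = sps.chi2_contingency(table, correction=False)
    return TestResult("chi-square", float(chi2), float(p), float(df))


def mann_whitney_u(
    x1: np.ndarray, x2: np.ndarray, method: str = "auto"
) -> TestResult:
    """Two-sided Mann-Whitney U.

    ``method='auto'`` uses exact enumeration for small tie-free samples
    (both n <= 20) and the tie-corrected normal approximation otherwise.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.size == 0 or x2.size == 0:
        raise ValueError("samples must be nonempty")
    pooled = np.concatenate([x1, x2])
    if np.all(pooled == pooled[0]):
        return TestResult("Mann-Whitney U", x1.size * x2.size / 2.0, 1.0)
    if method == "auto":
        ties = np.unique(pooled).size < pooled.size
        method = "exact" if (max(x1.size, x2.size) <= 20 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(x1, x2, alternative="two-sided", method=method)
    return TestResult("Mann-Whitney U", float(res.statistic), float(res.pvalue))


def kruskal_wallis(*groups: np.ndarray) -> TestResult:
    """Tie-corrected Kruskal-Wallis H across >=2 groups."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("groups must be nonempty")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return TestResult("Kruskal-Wallis", 0.0, 1.0, float(len(arrays) - 1))
    h, p = sps.kruskal(*arrays)
    return TestResult("Kruskal-Wallis", float(h), float(p), float(len(arrays) - 1))


def bonferroni(p_values: np.ndarray, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: multiply by m, cap at 1."""
    p = np.asarray(p_values, dtype=float)
    m = p.size if m is None else m
    return np.minimum(p * m, 1.0)


def mann_whitney_p_columns(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorized two-sided Mann-Whitney p per column of X (tie-corrected
    normal approximation).  Columns that are constant get p = 1."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(bool)
    x1, x2 = X[y], X[~y]
    with np.errstate(invalid="ignore"):
        res = sps.mannwhitneyu(
            x1, x2, alternative="two-sided", method="asymptotic", axis=0,
            nan_policy="omit",
        )
    p = np.asarray(res.pvalue, dtype=float)
    constant = np.nanmax(X, axis=0) == np.nanmin(X, axis=0)
    p[constant | ~np.isfinite(p)] = 1.0
    return p


def filter_variables(
    X, y: np.ndarray, alpha: float = 0.05
) -> list[str] | np.ndarray:
    """Retain columns whose groups differ at Mann-Whitney p < alpha.

    Falls back to all columns (with the caller expected to warn) when the
    filter would retain nothing.  Accepts a DataFrame (returns retained
    column names) or an array (returns a boolean mask).
    """
    import pandas as pd

    is_frame = isinstance(X, pd.DataFrame)
    arr = X.to_numpy(dtype=float) if is_frame else np.asarray(X, dtype=float)
    p = mann_whitney_p_columns(arr, y)
    mask = p < alpha
    if not mask.any():
        mask = np.ones_like(mask)
    if is_frame:
        return [c for c, keep in zip(X.columns, mask) if keep]
    return mask


def compare_feature_table(table, alpha: float = 0.05):
    """Per-variable ADHD-vs-TD comparison of a labeled feature table.

    Returns a DataFrame with the U statistic, raw p, and Bonferroni-adjusted
    p for every feature column.
    """
    import pandas as pd

    from .features import feature_matrix

    X, y = feature_matrix(table)
    rows = []
    for col in X.columns:
        vals = X[col].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        g1, g0 = vals[ok & (y == 1)], vals[ok & (y == 0)]
        if g1.size == 0 or g0.size == 0:
            rows.append({"variable": col, "U": np.nan, "p": np.nan})
            continue
        res = mann_whitney_u(g1, g0)
        rows.append({"variable": col, "U": res.statistic, "p": res.p_value})
    out = pd.DataFrame(rows)
    out["p_bonferroni"] = bonferroni(out["p"].to_numpy(), len(out))
    out["significant"] = out["p"] < alpha
    return out
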