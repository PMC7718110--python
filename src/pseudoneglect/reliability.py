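"""Test-retest reliability of bisection error.

Cronbach's alpha is the average-measures *consistency* intraclass
correlation ICC(3,k): it asks whether participants keep their rank and
spacing across repeated measurements and is therefore invariant to a
constant shift of any single measurement (a session- or task-level group
bias).  The absolute-agreement average-measures ICC(2,k) is provided for
contrast — it *is* reduced by such shifts.  Both come from the two-way
(participants x measurements) ANOVA decomposition; alpha is additionally
computed from the classical variance-of-sums formula and the two routes
are asserted equal.

Significance of alpha is assessed with the two-way ANOVA F test of
between-participant variance, F = MS_rows / MS_error on
(n-1, (n-1)(k-1)) degrees of freedom — the test reported alongside
ICCs by standard statistical software.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ReliabilityResult:
    """An average-measures ICC with its ANOVA F test.

    ``alpha`` may be negative (score reversals between measurements); it
    is reported as computed, never truncated at zero.
    """

    alpha: float
    icc_variant: str  # "consistency_avg" (ICC_c,k) or "agreement_avg" (ICC_a,k)
    k: int
    n: int
    f_stat: float
    df1: int
    df2: int
    p_value: float
    var_between_subject: float
    var_between_measurement: float
    var_residual: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


@dataclass
class CorrelationResult:
    """Pairwise Pearson correlations between measurement columns."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: int


def _validate(matrix: pd.DataFrame | np.ndarray) -> np.ndarray:
    arr = np.asarray(matrix, dtype=float)
    if arr.ndim != 2:
        raise ValueError("matrix must be 2-D (participants x measurements)")
    n, k = arr.shape
    if n < 3 or k < 2:
        raise ValueError("need n >= 3 participants and k >= 2 measurements")
    if np.isnan(arr).any():
        raise ValueError(
            "matrix has missing cells; complete-case the rows before "
            "computing reliability"
        )
    return arr


def _two_way_ms(arr: np.ndarray):
    """Mean squares of the two-way participants x measurements ANOVA."""
    n, k = arr.shape
    grand = arr.mean()
    row_means = arr.mean(axis=1)
    col_means = arr.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    resid = arr - row_means[:, None] - col_means[None, :] + grand
    ss_err = np.sum(resid**2)
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    return ms_rows, ms_cols, ms_err


def cronbach_alpha(matrix: pd.DataFrame | np.ndarray) -> ReliabilityResult:
    """Cronbach's alpha / ICC(3,k) of a participants x measurements matrix.

    Computed two ways — the variance-of-sums form
    ``k/(k-1) * (1 - sum(var_i) / var(total))`` and the ANOVA form
    ``(MS_rows - MS_err) / MS_rows`` — which agree algebraically and are
    asserted to agree numerically.  The F test of alpha > 0 uses
    ``MS_rows / MS_err`` on (n-1, (n-1)(k-1)) df.
    """
    arr = _validate(matrix)
    n, k = arr.shape
    item_vars = arr.var(axis=0, ddof=1)
    total_var = arr.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("total variance is zero; alpha undefined")
    alpha_classic = k / (k - 1) * (1.0 - item_vars.sum() / total_var)

    ms_rows, ms_cols, ms_err = _two_way_ms(arr)
    alpha_anova = (ms_rows - ms_err) / ms_rows
    assert np.isclose(alpha_classic, alpha_anova, rtol=1e-9, atol=1e-12), (
        alpha_classic, alpha_anova,
    )

    with np.errstate(divide="ignore"):
        f_stat = ms_rows / ms_err if ms_err > 0 else np.inf
    df1, df2 = n - 1, (n - 1) * (k - 1)
    p = float(stats.f.sf(f_stat, df1, df2))
    return ReliabilityResult(
        alpha=float(alpha_classic),
        icc_variant="consistency_avg",
        k=k,
        n=n,
        f_stat=float(f_stat),
        df1=df1,
        df2=df2,
        p_value=p,
        var_between_subject=float(max((ms_rows - ms_err) / k, 0.0)),
        var_between_measurement=float(max((ms_cols - ms_err) / n, 0.0)),
        var_residual=float(ms_err),
    )


def agreement_icc(matrix: pd.DataFrame | np.ndarray) -> ReliabilityResult:
    """Absolute-agreement average-measures ICC(2,k):
    ``(MS_rows - MS_err) / (MS_rows + (MS_cols - MS_err)/n)``.

    Unlike consistency, this is pulled down by measurement-level group
    offsets.  The F test reported is the same between-participant test as
    for alpha (the variant tag records which coefficient it accompanies).
    """
    arr = _validate(matrix)
    n, k = arr.shape
    ms_rows, ms_cols, ms_err = _two_way_ms(arr)
    icc = (ms_rows - ms_err) / (ms_rows + (ms_cols - ms_err) / n)
    f_stat = ms_rows / ms_err if ms_err > 0 else np.inf
    df1, df2 = n - 1, (n - 1) * (k - 1)
    return ReliabilityResult(
        alpha=float(icc),
        icc_variant="agreement_avg",
        k=k,
        n=n,
        f_stat=float(f_stat),
        df1=df1,
        df2=df2,
        p_value=float(stats.f.sf(f_stat, df1, df2)),
        var_between_subject=float(max((ms_rows - ms_err) / k, 0.0)),
        var_between_measurement=float(max((ms_cols - ms_err) / n, 0.0)),
        var_residual=float(ms_err),
    )


def pairwise_pearson(matrix: pd.DataFrame) -> CorrelationResult:
    """Pearson r (with two-sided t-based p) for every pair of columns.

    Used for cross-task correlations; a constant column makes r undefined
    for its pairs and raises.
    """
    arr = _validate(matrix)
    cols = list(matrix.columns) if isinstance(matrix, pd.DataFrame) else list(
        range(arr.shape[1])
    )
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    np.fill_diagonal(p.values, 0.0)
    for i, j in combinations(range(len(cols)), 2):
        xi, xj = arr[:, i], arr[:, j]
        if xi.std(ddof=1) == 0 or xj.std(ddof=1) == 0:
            raise ValueError(f"constant column makes r undefined: {cols[i]}/{cols[j]}")
        res = stats.pearsonr(xi, xj)
        r.iloc[i, j] = r.iloc[j, i] = res.statistic
        p.iloc[i, j] = p.iloc[j, i] = res.pvalue
    return CorrelationResult(r=r, p=p, n=arr.shape[0])
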