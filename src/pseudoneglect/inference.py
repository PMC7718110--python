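"""Group-level inference: one-sample t-tests with Bonferroni control and
the tasks x sessions within-subjects ANOVA.

The ANOVA is the classical fully-crossed two-way repeated-measures
decomposition: each within-subject effect (task, session, task x session)
is tested against its own effect-by-subject error stratum.  Partial
eta-squared is ``SS_effect / (SS_effect + SS_error_effect)``; plain
eta-squared (``SS_effect / SS_total``) is also emitted so both conventions
are auditable.  No sphericity correction is applied by default;
Greenhouse-Geisser-corrected p-values are available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class TTestResult:
    """One-sample t-test of a mean bisection error against ``mu0``.

    Satisfies ``t = (mean - mu0) / (sd / sqrt(n))`` and ``d = t / sqrt(n)``
    (Cohen's d for a one-sample design).
    """

    n: int
    mean: float
    sd: float
    mu0: float
    t: float
    df: int
    p_value: float
    cohens_d: float
    adjusted_alpha: float | None = None

    @property
    def significant(self) -> bool | None:
        if self.adjusted_alpha is None:
            return None
        return self.p_value <= self.adjusted_alpha


@dataclass
class BonferroniPlan:
    """Family-wise error control by alpha division."""

    family_alpha: float
    m: int
    adjusted_alpha: float

    @property
    def display(self) -> str:
        """The adjusted level rounded to 3 decimals as it would be quoted
        in a report (0.05/4 -> "0.013", 0.05/3 -> "0.017")."""
        return f"{round(self.adjusted_alpha, 3):.3f}"


@dataclass
class AnovaResult:
    """Two-way within-subjects ANOVA table plus the subject/error strata.

    ``table`` rows: task, session, task:session — each with SS, df, MS,
    F, p, partial and plain eta-squared, and its error stratum's SS/df.
    ``strata`` records every sum of squares in the decomposition; they add
    up to ``ss_total``.
    """

    table: pd.DataFrame
    strata: pd.DataFrame
    ss_total: float
    n_subjects: int
    n_tasks: int
    n_sessions: int
    gg_corrected: bool = False


def one_sample_t(
    values: np.ndarray | list[float],
    mu0: float = 0.0,
    adjusted_alpha: float | None = None,
) -> TTestResult:
    """Textbook one-sample t-test with Cohen's d = mean/sd."""
    arr = np.asarray(values, dtype=float)
    n = arr.size
    if n < 2:
        raise ValueError("need n >= 2")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    if sd == 0:
        raise ValueError("zero standard deviation; t undefined")
    return t_from_summary(mean, sd, n, mu0=mu0, adjusted_alpha=adjusted_alpha)


def t_from_summary(
    mean: float,
    sd: float,
    n: int,
    mu0: float = 0.0,
    adjusted_alpha: float | None = None,
) -> TTestResult:
    """One-sample t from summary statistics (mean, SD, n) — lets printed
    table cells be re-tested without the raw data."""
    if n < 2:
        raise ValueError("need n >= 2")
    if sd <= 0:
        raise ValueError("sd must be > 0")
    se = sd / np.sqrt(n)
    t = (mean - mu0) / se
    df = n - 1
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(
        n=n,
        mean=mean,
        sd=sd,
        mu0=mu0,
        t=float(t),
        df=df,
        p_value=float(p),
        cohens_d=float((mean - mu0) / sd),
        adjusted_alpha=adjusted_alpha,
    )


def bonferroni(family_alpha: float = 0.05, m: int = 1) -> BonferroniPlan:
    """Bonferroni-adjusted per-test alpha = family_alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 < family_alpha < 1:
        raise ValueError("family_alpha must be in (0, 1)")
    return BonferroniPlan(
        family_alpha=family_alpha, m=m, adjusted_alpha=family_alpha / m
    )


def _gg_epsilon(cov: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from a covariance matrix of the levels."""
    k = cov.shape[0]
    mean_diag = np.trace(cov) / k
    grand = cov.mean()
    row_means = cov.mean(axis=1)
    num = (k * (mean_diag - grand)) ** 2
    den = (k - 1) * (
        np.sum(cov**2) - 2 * k * np.sum(row_means**2) + k**2 * grand**2
    )
    return float(num / den)


def rm_anova(
    data: pd.DataFrame,
    subject: str = "participant_id",
    factors: tuple[str, str] = ("task", "session_index"),
    value: str = "error_mm",
    gg_correction: bool = False,
) -> AnovaResult:
    """Two-way fully-within ANOVA on a long table of cell means.

    Requires exactly one value per subject x factor-A x factor-B cell (no
    imputation of incomplete designs).  Sums of squares follow the
    complete orthogonal decomposition:

        total = subject + A + B + AxB + AxS + BxS + AxBxS

    and each effect's F uses its own effect-by-subject stratum.
    """
    fa, fb = factors
    pivot = data.pivot_table(
        index=subject, columns=[fa, fb], values=value, aggfunc="first"
    )
    counts = data.groupby([subject, fa, fb])[value].count()
    if (counts != 1).any():
        raise ValueError("need exactly one value per subject x cell")
    if pivot.isna().any().any():
        raise ValueError("incomplete design: every subject needs every cell")

    a_levels = sorted(data[fa].unique())
    b_levels = sorted(data[fb].unique())
    n, J, K = len(pivot), len(a_levels), len(b_levels)
    # cube[subject, a, b]
    cube = np.empty((n, J, K))
    for j, a in enumerate(a_levels):
        for k_, b in enumerate(b_levels):
            cube[:, j, k_] = pivot[(a, b)].to_numpy()

    grand = cube.mean()
    m_s = cube.mean(axis=(1, 2))
    m_a = cube.mean(axis=(0, 2))
    m_b = cube.mean(axis=(0, 1))
    m_sa = cube.mean(axis=2)
    m_sb = cube.mean(axis=1)
    m_ab = cube.mean(axis=0)

    ss_subj = J * K * np.sum((m_s - grand) ** 2)
    ss_a = n * K * np.sum((m_a - grand) ** 2)
    ss_b = n * J * np.sum((m_b - grand) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_as = K * np.sum(
        (m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2
    )
    ss_bs = J * np.sum(
        (m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2
    )
    ss_total = np.sum((cube - grand) ** 2)
    ss_abs = ss_total - (ss_subj + ss_a + ss_b + ss_ab + ss_as + ss_bs)
    ss_abs = max(ss_abs, 0.0)

    rows = []
    for name, ss_eff, df_eff, ss_err, df_err, eff_cube in (
        (fa, ss_a, J - 1, ss_as, (J - 1) * (n - 1), m_sa),
        (fb, ss_b, K - 1, ss_bs, (K - 1) * (n - 1), m_sb),
        (
            f"{fa}:{fb}",
            ss_ab,
            (J - 1) * (K - 1),
            ss_abs,
            (J - 1) * (K - 1) * (n - 1),
            None,
        ),
    ):
        ms_eff = ss_eff / df_eff
        ms_err = ss_err / df_err
        f_stat = ms_eff / ms_err if ms_err > 0 else np.inf
        p = float(stats.f.sf(f_stat, df_eff, df_err))
        eps = np.nan
        p_gg = np.nan
        if gg_correction and eff_cube is not None:
            cov = np.cov(eff_cube, rowvar=False, ddof=1)
            eps = _gg_epsilon(cov)
            p_gg = float(stats.f.sf(f_stat, df_eff * eps, df_err * eps))
        rows.append(
            {
                "effect": name,
                "ss": ss_eff,
                "df": df_eff,
                "ms": ms_eff,
                "ss_error": ss_err,
                "df_error": df_err,
                "ms_error": ms_err,
                "F": f_stat,
                "p": p,
                "partial_eta_sq": ss_eff / (ss_eff + ss_err)
                if (ss_eff + ss_err) > 0
                else np.nan,
                "eta_sq": ss_eff / ss_total if ss_total > 0 else np.nan,
                "gg_epsilon": eps,
                "p_gg": p_gg,
            }
        )
    table = pd.DataFrame(rows).set_index("effect")
    strata = pd.DataFrame(
        {
            "ss": [ss_subj, ss_a, ss_b, ss_ab, ss_as, ss_bs, ss_abs],
            "df": [
                n - 1,
                J - 1,
                K - 1,
                (J - 1) * (K - 1),
                (J - 1) * (n - 1),
                (K - 1) * (n - 1),
                (J - 1) * (K - 1) * (n - 1),
            ],
        },
        index=[
            "subject", fa, fb, f"{fa}:{fb}",
            f"{fa}:subject", f"{fb}:subject", f"{fa}:{fb}:subject",
        ],
    )
    assert np.isclose(strata["ss"].sum(), ss_total, rtol=1e-9, atol=1e-9)
    return AnovaResult(
        table=table,
        strata=strata,
        ss_total=float(ss_total),
        n_subjects=n,
        n_tasks=J,
        n_sessions=K,
        gg_corrected=gg_correction,
    )
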