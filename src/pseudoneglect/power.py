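"""Monte-Carlo power analysis for reliability studies.

Two questions a bisection-reliability study must budget for:

* can it detect that cross-session consistency (Cronbach's alpha) is
  above zero?  Simulated by drawing participants x sessions matrices from
  the variance-component model whose population consistency equals the
  hypothesised alpha, then running the two-way-ANOVA F test;
* can it detect a group-level pseudoneglect effect of size d with a
  one-sample t-test?  Simulated directly, and cross-checked against the
  noncentral-t closed form.

Both report the rejection proportion with its binomial Monte-Carlo
standard error, and are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .simulate import population_for_consistency


@dataclass
class PowerResult:
    """Estimated power of one scenario.

    ``mc_se`` is ``sqrt(p (1-p) / n_sims)``; ``analytic`` carries a
    closed-form cross-check where one exists (noncentral-t for the
    one-sample test), else ``None``.
    """

    test: str
    power: float
    mc_se: float
    n: int
    alpha_level: float
    n_sims: int
    seed: int
    params: dict = field(default_factory=dict)
    analytic: float | None = None


def power_cronbach(
    true_alpha: float,
    n: int,
    k: int,
    alpha_level: float = 0.05,
    n_sims: int = 1000,
    seed: int = 0,
) -> PowerResult:
    """Power of the Cronbach's-alpha F test when the population
    consistency is ``true_alpha``.

    Each replicate draws ``x_ij = b_i + e_ij`` with variance components
    set by ``alpha = sigma_b^2 / (sigma_b^2 + sigma_e^2 / k)``, then tests
    ``MS_rows / MS_err`` against F(n-1, (n-1)(k-1)) at ``alpha_level``.
    The detection question is interpreted as this significance test run
    when the hypothesised consistency truly holds.
    """
    if n < 4:
        raise ValueError("need n >= 4 participants")
    between_sd, noise_sd = population_for_consistency(true_alpha, k)
    rng = np.random.default_rng(seed)
    b = rng.normal(0.0, between_sd, size=(n_sims, n, 1))
    e = rng.normal(0.0, noise_sd, size=(n_sims, n, k))
    x = b + e
    # vectorised two-way mean squares per replicate
    grand = x.mean(axis=(1, 2), keepdims=True)
    rows = x.mean(axis=2, keepdims=True)
    cols = x.mean(axis=1, keepdims=True)
    ss_rows = k * ((rows - grand) ** 2).sum(axis=(1, 2))
    resid = x - rows - cols + grand
    ss_err = (resid**2).sum(axis=(1, 2))
    ms_rows = ss_rows / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    f = ms_rows / ms_err
    p = stats.f.sf(f, n - 1, (n - 1) * (k - 1))
    power = float((p < alpha_level).mean())
    return PowerResult(
        test="cronbach_f",
        power=power,
        mc_se=float(np.sqrt(power * (1 - power) / n_sims)),
        n=n,
        alpha_level=alpha_level,
        n_sims=n_sims,
        seed=seed,
        params={
            "true_alpha": true_alpha,
            "k": k,
            "between_sd": between_sd,
            "noise_sd": noise_sd,
            "interpretation": (
                "power of the two-way-ANOVA F test of alpha > 0 when the "
                "population consistency equals true_alpha"
            ),
        },
    )


def analytic_t_power(d: float, n: int, alpha_level: float = 0.05) -> float:
    """Closed-form two-sided one-sample t power via the noncentral t."""
    df = n - 1
    nc = d * np.sqrt(n)
    tcrit = stats.t.ppf(1 - alpha_level / 2, df)
    return float(
        stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc)
    )


def power_ttest(
    cohens_d: float,
    n: int,
    alpha_level: float = 0.05,
    n_sims: int = 1000,
    seed: int = 0,
) -> PowerResult:
    """Monte-Carlo power of the two-sided one-sample t-test at effect size
    ``cohens_d``, with the noncentral-t analytic power attached as a
    cross-check."""
    if n < 2:
        raise ValueError("need n >= 2")
    rng = np.random.default_rng(seed)
    x = rng.normal(cohens_d, 1.0, size=(n_sims, n))
    mean = x.mean(axis=1)
    sd = x.std(axis=1, ddof=1)
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), n - 1)
    power = float((p < alpha_level).mean())
    return PowerResult(
        test="one_sample_t",
        power=power,
        mc_se=float(np.sqrt(power * (1 - power) / n_sims)),
        n=n,
        alpha_level=alpha_level,
        n_sims=n_sims,
        seed=seed,
        params={"cohens_d": cohens_d},
        analytic=analytic_t_power(cohens_d, n, alpha_level),
    )
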