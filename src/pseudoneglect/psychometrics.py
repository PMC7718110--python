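"""Cumulative-normal psychometric fitting for the landmark task.

The landmark task asks, for a line pre-bisected at signed asymmetry ``x``
(mm, rightward positive), whether the right side looks longer.  The
proportion of "right longer" responses is modelled as

    p(x) = lam + (1 - 2*lam) * Phi((x - loc) / scale)

where ``loc`` is the threshold (the 50% crossing when the guess rate
equals the lapse rate), ``scale`` the slope SD of the underlying normal
CDF, and ``lam`` the lapse rate, with the guess rate fixed equal to the
lapse rate.  All three parameters are estimated jointly by maximising the
binomial likelihood over every stimulus level (the lapse rate is never
fixed in advance), from a deterministic multistart grid.  Uncertainty
comes from a non-parametric bootstrap that resamples the per-level
response counts.

The point of subjective equality (PSE) is the asymmetry at which
"right longer" responses reach 50%; with the symmetric lapse constraint it
coincides with the threshold.  Landmark bisection error is defined as the
negated PSE so that leftward perceptual biases are negative, matching the
manual tasks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import ndtr, xlogy
from scipy.stats import norm

from .design import Task
from .simulate import RIGHT_LONGER

logger = logging.getLogger(__name__)

# parameter bounds: loc within +/-50 mm, scale in [0.05, 100] mm
LOC_BOUND = 50.0
SCALE_MIN = 0.05
SCALE_MAX = 100.0

#: deterministic multistart grid: thresholds x slopes x lapse rates
START_GRID = [
    (loc, scale, lapse)
    for loc in (-6.0, 0.0, 6.0)
    for scale in (1.0, 3.0, 9.0)
    for lapse in (0.01, 0.05)
]


# -- proportion tables -------------------------------------------------------

def aggregate_responses(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-asymmetry response counts for landmark trials.

    Returns a DataFrame with columns ``asymmetry_mm``, ``n_trials``,
    ``n_right`` and ``prop_right``, sorted by asymmetry.  Levels with zero
    trials are omitted with a warning.  Pass the trials of one participant
    and one session (or pooled sessions) — the caller chooses the scope.
    """
    tasks = trials["task"].unique()
    if list(tasks) != [Task.LANDMARK.value]:
        raise ValueError(f"aggregate_responses expects landmark trials, got {tasks}")
    valid = trials.dropna(subset=["response"])
    if len(valid) < len(trials):
        logger.warning(
            "aggregate_responses: dropping %d trials with missing responses",
            len(trials) - len(valid),
        )
    grp = valid.groupby("asymmetry_mm")["response"]
    table = pd.DataFrame(
        {
            "n_trials": grp.size(),
            "n_right": grp.apply(lambda r: int((r == RIGHT_LONGER).sum())),
        }
    ).reset_index()
    table["prop_right"] = table["n_right"] / table["n_trials"]
    return table.sort_values("asymmetry_mm", ignore_index=True)


def read_proportions(path) -> pd.DataFrame:
    """Read a proportion table written by :func:`write_proportions`."""
    table = pd.read_csv(path, sep="\t")
    need = {"asymmetry_mm", "n_trials", "n_right"}
    if not need.issubset(table.columns):
        raise ValueError(f"proportion table lacks columns {need - set(table.columns)}")
    table["prop_right"] = table["n_right"] / table["n_trials"]
    return table.sort_values("asymmetry_mm", ignore_index=True)


def write_proportions(table: pd.DataFrame, path) -> None:
    table[["asymmetry_mm", "n_trials", "n_right"]].to_csv(path, sep="\t", index=False)


# -- model -------------------------------------------------------------------

def predicted_proportion(
    x: np.ndarray | float, loc: float, scale: float, lapse: float
) -> np.ndarray | float:
    """p(right longer) under the lapse-symmetric cumulative normal."""
    return lapse + (1.0 - 2.0 * lapse) * ndtr((np.asarray(x, float) - loc) / scale)


def _binom_loglik(p: np.ndarray, n: np.ndarray, k: np.ndarray) -> float:
    # binomial log-likelihood up to the constant choose(n, k) term
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return float(np.sum(xlogy(k, p) + xlogy(n - k, 1.0 - p)))


def _saturated_loglik(n: np.ndarray, k: np.ndarray) -> float:
    phat = k / n
    return float(np.sum(xlogy(k, phat) + xlogy(n - k, 1.0 - phat)))


def loglik(
    table: pd.DataFrame, loc: float, scale: float, lapse: float
) -> float:
    """Binomial log-likelihood of a parameter triple on a proportion table
    (up to the data-only combinatorial constant)."""
    x = table["asymmetry_mm"].to_numpy(float)
    n = table["n_trials"].to_numpy(float)
    k = table["n_right"].to_numpy(float)
    return _binom_loglik(predicted_proportion(x, loc, scale, lapse), n, k)


@dataclass
class PsychometricFit:
    """MLE of the lapse-symmetric cumulative-normal psychometric function.

    ``loc_mm`` is the threshold (= PSE under the guess-equals-lapse
    constraint), ``scale_mm`` the slope SD, ``lapse`` the shared
    guess/lapse rate.  ``deviance`` is against the saturated binomial
    model.  ``converged`` is honest: boundary-stuck or unidentifiable fits
    are flagged, never silently repaired.
    """

    loc_mm: float
    scale_mm: float
    lapse: float
    loglik: float
    deviance: float
    converged: bool
    n_levels: int
    n_trials: int
    lapse_max: float
    x: np.ndarray = field(repr=False)
    n: np.ndarray = field(repr=False)
    k: np.ndarray = field(repr=False)

    @property
    def guess(self) -> float:
        return self.lapse

    @property
    def pse_mm(self) -> float:
        return self.loc_mm


@dataclass
class BootstrapResult:
    """Non-parametric bootstrap of the psychometric fit.

    ``se_*`` are SDs over converged replicates; CIs are percentile.
    ``flagged`` if more than 20% of replicates failed to converge or the
    replicate distribution is degenerate.
    """

    n_boot: int
    n_dropped: int
    se_loc: float
    se_scale: float
    se_pse: float
    ci_pse: tuple[float, float]
    ci_loc: tuple[float, float]
    ci_scale: tuple[float, float]
    flagged: bool
    seed: int
    samples: pd.DataFrame = field(repr=False)


@dataclass
class PseResult:
    """Point of subjective equality and the derived bisection error
    (``-pse``, mm, leftward negative)."""

    pse_mm: float
    bisection_error_mm: float
    ci_mm: tuple[float, float] | None = None


@dataclass
class FitQuality:
    """Fit diagnostics: Monte-Carlo deviance p-value, bootstrap precision
    of the PSE, and convergence.  ``passed`` is False if any check fails;
    ``flags`` lists the failures."""

    passed: bool
    flags: list[str]
    deviance: float
    deviance_p: float | None
    se_pse: float | None


def _fit_once(
    x: np.ndarray,
    n: np.ndarray,
    k: np.ndarray,
    start: tuple[float, float, float],
    lapse_max: float,
):
    def nll(theta):
        loc, scale, lapse = theta
        return -_binom_loglik(predicted_proportion(x, loc, scale, lapse), n, k)

    return minimize(
        nll,
        x0=np.array(start),
        method="L-BFGS-B",
        bounds=[(-LOC_BOUND, LOC_BOUND), (SCALE_MIN, SCALE_MAX), (0.0, lapse_max)],
    )


def _moment_start(x, n, k) -> tuple[float, float, float]:
    # crude 50%-crossing interpolation for an extra, data-driven start
    p = k / n
    loc = float(np.interp(0.5, np.clip(p, 0.01, 0.99), x))
    span = (x.max() - x.min()) / 4 or 1.0
    return (loc, float(span), 0.02)


def fit_cumulative_normal(
    table: pd.DataFrame,
    lapse_max: float = 0.10,
    starts: list[tuple[float, float, float]] | None = None,
) -> PsychometricFit:
    """Joint MLE of (threshold, slope, lapse) on a proportion table.

    Requires at least 4 distinct asymmetry levels spanning both signs.
    The optimiser is run from every point of a deterministic start grid
    plus a moment-based start; the best converged solution wins.  Fits
    whose responses never vary, or that end stuck on the scale boundary,
    are returned with ``converged=False``.
    """
    x = table["asymmetry_mm"].to_numpy(float)
    n = table["n_trials"].to_numpy(float)
    k = table["n_right"].to_numpy(float)
    if len(np.unique(x)) < 4 or x.min() >= 0 or x.max() <= 0:
        raise ValueError(
            "need >= 4 distinct asymmetry levels spanning both signs"
        )
    if (k < 0).any() or (k > n).any():
        raise ValueError("counts must satisfy 0 <= n_right <= n_trials")

    total_k = k.sum()
    identifiable = 0 < total_k < n.sum()

    best = None
    all_starts = list(starts) if starts is not None else list(START_GRID)
    all_starts.append(_moment_start(x, n, k))
    for start in all_starts:
        res = _fit_once(x, n, k, start, lapse_max)
        if best is None or res.fun < best.fun:
            best = res
    loc, scale, lapse = best.x
    ll = -best.fun
    dev = 2.0 * (_saturated_loglik(n, k) - ll)
    on_scale_boundary = scale <= SCALE_MIN * 1.5 or scale >= SCALE_MAX * 0.99
    converged = bool(best.success) and identifiable and not on_scale_boundary
    if not converged:
        logger.warning(
            "psychometric fit flagged (success=%s identifiable=%s boundary=%s)",
            best.success, identifiable, on_scale_boundary,
        )
    return PsychometricFit(
        loc_mm=float(loc),
        scale_mm=float(scale),
        lapse=float(lapse),
        loglik=ll,
        deviance=float(max(dev, 0.0)),
        converged=converged,
        n_levels=len(x),
        n_trials=int(n.sum()),
        lapse_max=lapse_max,
        x=x,
        n=n,
        k=k,
    )


def _refit_warm(x, n, k, warm: PsychometricFit) -> PsychometricFit | None:
    """Single warm-started refit used inside bootstrap/Monte-Carlo loops."""
    res = _fit_once(
        x, n, k, (warm.loc_mm, warm.scale_mm, warm.lapse), warm.lapse_max
    )
    if not res.success:
        res2 = _fit_once(x, n, k, _moment_start(x, n, k), warm.lapse_max)
        if res2.fun < res.fun:
            res = res2
    loc, scale, lapse = res.x
    identifiable = 0 < k.sum() < n.sum()
    if not res.success or not identifiable or scale <= SCALE_MIN * 1.5:
        return None
    ll = -res.fun
    return PsychometricFit(
        loc_mm=float(loc), scale_mm=float(scale), lapse=float(lapse),
        loglik=ll,
        deviance=float(max(2.0 * (_saturated_loglik(n, k) - ll), 0.0)),
        converged=True, n_levels=len(x), n_trials=int(n.sum()),
        lapse_max=warm.lapse_max, x=x, n=n, k=k,
    )


def bootstrap_fit(
    table: pd.DataFrame,
    fit: PsychometricFit,
    n_boot: int = 400,
    seed: int = 0,
) -> BootstrapResult:
    """Non-parametric bootstrap: per replicate, resample each level's
    "right longer" count from Binomial(n, observed proportion), refit, and
    summarise the replicate spread.  Deterministic given ``seed``;
    non-converging replicates are dropped and counted, and the result is
    flagged when more than 20% drop.
    """
    if not fit.converged:
        raise ValueError("bootstrap_fit requires a converged fit")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    x, n = fit.x, fit.n
    phat = fit.k / n
    rows = []
    dropped = 0
    for _ in range(n_boot):
        k_star = rng.binomial(n.astype(int), phat).astype(float)
        refit = _refit_warm(x, n, k_star, fit)
        if refit is None:
            dropped += 1
            continue
        rows.append((refit.loc_mm, refit.scale_mm, refit.lapse, refit.pse_mm))
    samples = pd.DataFrame(rows, columns=["loc_mm", "scale_mm", "lapse", "pse_mm"])
    degenerate = len(samples) < 2 or float(samples["pse_mm"].std(ddof=1)) == 0.0
    flagged = dropped > 0.2 * n_boot or degenerate

    def ci(col):
        if len(samples) < 2:
            return (float("nan"), float("nan"))
        lo, hi = np.percentile(samples[col], [2.5, 97.5])
        return (float(lo), float(hi))

    def se(col):
        return float(samples[col].std(ddof=1)) if len(samples) > 1 else float("nan")

    return BootstrapResult(
        n_boot=n_boot,
        n_dropped=dropped,
        se_loc=se("loc_mm"),
        se_scale=se("scale_mm"),
        se_pse=se("pse_mm"),
        ci_pse=ci("pse_mm"),
        ci_loc=ci("loc_mm"),
        ci_scale=ci("scale_mm"),
        flagged=flagged,
        seed=seed,
        samples=samples,
    )


def pse(fit: PsychometricFit, bootstrap: BootstrapResult | None = None) -> PseResult:
    """PSE (the 50% crossing) and the landmark bisection error ``-PSE``.

    With the guess rate fixed equal to a lapse rate below 0.5 the crossing
    reduces analytically to the threshold.
    """
    if fit.lapse >= 0.5:
        raise ValueError("PSE undefined for lapse >= 0.5")
    p = fit.pse_mm
    ci = None
    if bootstrap is not None:
        ci = bootstrap.ci_pse
    return PseResult(pse_mm=p, bisection_error_mm=-p, ci_mm=ci)


def pse_numeric(fit: PsychometricFit) -> float:
    """The 50% crossing found by root-finding on the fitted curve (used to
    cross-check the closed form)."""
    from scipy.optimize import brentq

    f = lambda v: predicted_proportion(v, fit.loc_mm, fit.scale_mm, fit.lapse) - 0.5
    return float(brentq(f, -LOC_BOUND * 2, LOC_BOUND * 2, xtol=1e-12))


def fit_quality(
    fit: PsychometricFit,
    bootstrap: BootstrapResult | None = None,
    p_min: float = 0.01,
    se_max: float = 2.0,
    n_sims: int = 200,
    seed: int = 0,
) -> FitQuality:
    """Diagnose a psychometric fit.

    Flags, in order of precedence: non-convergence (fatal regardless of
    other checks); a Monte-Carlo deviance p-value below ``p_min`` (the
    observed deviance compared against deviances of datasets simulated
    from the fitted model, each refit); a bootstrap PSE standard error
    above ``se_max`` mm (only checked when a bootstrap is supplied).
    """
    flags: list[str] = []
    dev_p = None
    se_pse = bootstrap.se_pse if bootstrap is not None else None
    if not fit.converged:
        flags.append("non-convergence")
    else:
        rng = np.random.default_rng(seed)
        p_model = predicted_proportion(fit.x, fit.loc_mm, fit.scale_mm, fit.lapse)
        n_int = fit.n.astype(int)
        devs = []
        for _ in range(n_sims):
            k_sim = rng.binomial(n_int, p_model).astype(float)
            refit = _refit_warm(fit.x, fit.n, k_sim, fit)
            if refit is not None:
                devs.append(refit.deviance)
        devs = np.asarray(devs)
        # p: how extreme the observed deviance is under the fitted model
        dev_p = float((np.sum(devs >= fit.deviance) + 1) / (len(devs) + 1))
        if dev_p < p_min:
            flags.append("deviance")
        if bootstrap is not None and (bootstrap.flagged or se_pse > se_max):
            flags.append("pse-precision")
    return FitQuality(
        passed=not flags,
        flags=flags,
        deviance=fit.deviance,
        deviance_p=dev_p,
        se_pse=se_pse,
    )


# -- study-level convenience -------------------------------------------------

def landmark_session_errors(
    trials: pd.DataFrame,
    lapse_max: float = 0.10,
    n_boot: int = 0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[tuple[str, int], PsychometricFit],
           dict[tuple[str, int], BootstrapResult]]:
    """Fit each participant x session separately and return the
    participants x sessions matrix of landmark bisection errors (-PSE, mm)
    plus the underlying fits.  Cells whose fit does not converge are NaN.
    Set ``n_boot`` >= 100 to also bootstrap each cell.
    """
    landmark = trials[trials["task"] == Task.LANDMARK.value]
    fits: dict[tuple[str, int], PsychometricFit] = {}
    boots: dict[tuple[str, int], BootstrapResult] = {}
    cells: dict[str, dict[int, float]] = {}
    for (pid, sess), sub in landmark.groupby(["participant_id", "session_index"]):
        table = aggregate_responses(sub)
        fit = fit_cumulative_normal(table, lapse_max=lapse_max)
        fits[(pid, int(sess))] = fit
        value = -fit.pse_mm if fit.converged else np.nan
        cells.setdefault(pid, {})[int(sess)] = value
        if n_boot >= 100 and fit.converged:
            pid_key = int.from_bytes(str(pid).encode("utf8"), "little") % 2**31
            cell_seed = int(
                np.random.SeedSequence(
                    [seed, pid_key, int(sess)]
                ).generate_state(1)[0] % 2**31
            )
            boots[(pid, int(sess))] = bootstrap_fit(
                table, fit, n_boot=n_boot, seed=cell_seed
            )
    matrix = pd.DataFrame(cells).T.sort_index()
    matrix.index.name = "participant_id"
    matrix.columns.name = "session_index"
    return matrix, fits, boots


def pooled_fit(
    trials: pd.DataFrame, lapse_max: float = 0.10
) -> PsychometricFit:
    """Fit one curve to a participant's landmark trials pooled over all
    sessions (equal-trial pooling)."""
    return fit_cumulative_normal(aggregate_responses(trials), lapse_max=lapse_max)
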