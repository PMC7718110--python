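"""Bisection errors and participant x measurement summary matrices.

The bisection error of a manual trial is the perceived midpoint minus the
physical midpoint, in mm, with leftward errors negative.  For line
bisection the participant's scalar touchscreen calibration error is
subtracted; rod responses are recorded from the left end of the rod and
converted to signed error in exactly one place here.

Error matrices are plain :class:`pandas.DataFrame` objects — rows indexed
by participant, columns by session (one task) or by task (averaged over
sessions).  Missing cells stay ``NaN`` and propagate as exclusions, never
as imputations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import MANUAL_TASKS, Task
from .simulate import TRIAL_COLUMNS

logger = logging.getLogger(__name__)


# -- trial-table I/O ---------------------------------------------------------

def read_trials(path: str | Path) -> pd.DataFrame:
    """Read a delimited trial table, validating the header.

    Expects tab- or comma-separated text with the canonical columns
    (``participant_id``, ``session_index``, 1-based, ..., mm units).
    """
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table {path} lacks columns: {missing}")
    if (df["session_index"] < 1).any():
        raise ValueError("session_index must be 1-based")
    return df[TRIAL_COLUMNS]


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    trials.to_csv(path, sep="\t", index=False)


# -- per-trial errors --------------------------------------------------------

def manual_bisection_error(trials: pd.DataFrame) -> pd.Series:
    """Signed bisection error (mm, leftward negative) of manual trials.

    line bisection: ``(touch_x - line_centre) - calibration_offset`` where
    the line centre is at the trial's lateral offset (midline = 0);
    rod bisection: ``response_from_left_end - length/2``.

    Trials with a missing response (timeouts) get ``NaN`` — they are
    excluded downstream, never zero-filled.
    """
    tasks = trials["task"].astype(str)
    bad = ~tasks.isin([t.value for t in MANUAL_TASKS])
    if bad.any():
        raise ValueError(
            f"manual_bisection_error on non-manual tasks: {sorted(tasks[bad].unique())}"
        )
    response = pd.to_numeric(trials["response"], errors="coerce")
    midpoint = np.where(
        tasks == Task.ROD.value,
        trials["length_mm"] / 2.0,
        trials["offset_mm"],
    )
    calib = np.where(
        tasks == Task.LINE.value,
        trials["calibration_offset_mm"].fillna(0.0),
        0.0,
    )
    return (response - midpoint) - calib


def filter_trials(trials: pd.DataFrame, timeout_s: float) -> pd.DataFrame:
    """Drop trials that timed out or have no recorded response.

    Landmark responses are categorical strings; manual responses are
    numeric.  A trial is removed if its response time exceeds
    ``timeout_s`` or its response is missing.  The removal count is
    logged.
    """
    if timeout_s <= 0:
        raise ValueError("timeout_s must be > 0")
    is_manual = trials["task"].isin([t.value for t in MANUAL_TASKS])
    resp = trials["response"]
    missing = resp.isna()
    missing |= is_manual & pd.to_numeric(resp, errors="coerce").isna()
    timed_out = trials["response_time_s"] > timeout_s
    keep = ~(missing | timed_out)
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info(
            "filter_trials: removed %d of %d trials (timeout > %.3gs or missing)",
            n_removed, len(trials), timeout_s,
        )
    return trials.loc[keep]


# -- summary matrices --------------------------------------------------------

def session_means(trials: pd.DataFrame) -> pd.DataFrame:
    """Participants x sessions matrix of mean bisection error for one
    manual task, averaging over lengths, offsets and hands (unweighted
    trial mean).  Participant-sessions with zero trials yield ``NaN``.
    """
    tasks = trials["task"].unique()
    if len(tasks) != 1 or tasks[0] not in [t.value for t in MANUAL_TASKS]:
        raise ValueError(f"session_means expects a single manual task, got {tasks}")
    err = trials.assign(error_mm=manual_bisection_error(trials))
    mat = err.pivot_table(
        index="participant_id",
        columns="session_index",
        values="error_mm",
        aggfunc="mean",
    )
    mat.columns.name = "session_index"
    return mat


def task_means(
    session_matrices: dict[Task | str, pd.DataFrame],
) -> pd.DataFrame:
    """Participants x tasks matrix, each cell the mean of that task's
    session values.

    Landmark session values are the per-session negated PSEs produced by
    the psychometric module, entering on equal footing (mm) with manual
    errors.  Participants missing any session of a task get ``NaN`` for
    that task; participants absent from any task's matrix are excluded
    (logged), since cross-task reliability needs complete rows.
    """
    cols = {}
    for task, mat in session_matrices.items():
        name = task.value if isinstance(task, Task) else str(task)
        cols[name] = mat.mean(axis=1, skipna=False)
    out = pd.DataFrame(cols)
    out.index.name = "participant_id"
    incomplete = out.index[out.isna().any(axis=1)]
    if len(incomplete):
        logger.info(
            "task_means: %d participants with incomplete sessions: %s",
            len(incomplete), list(incomplete),
        )
    return out


# -- outlier screening -------------------------------------------------------

#: removal policies: flag in any task, in all tasks, or in listed tasks only
POLICIES = ("any-task", "all-tasks", "listed-tasks")


@dataclass
class ScreeningReport:
    """Outlier flags per participant x task and the removal decisions.

    ``flags`` is a boolean DataFrame (participants x tasks);
    ``removed`` lists participants the policy excludes; ``reasons`` maps
    each removed participant to the flagged tasks that triggered removal.
    """

    flags: pd.DataFrame
    z_scores: pd.DataFrame
    k_sd: float
    policy: str
    listed_tasks: tuple[str, ...] = ()
    removed: list[str] = field(default_factory=list)
    reasons: dict[str, list[str]] = field(default_factory=dict)

    def keep_index(self) -> pd.Index:
        return self.flags.index.difference(self.removed, sort=False)


def screen_outliers(
    task_matrix: pd.DataFrame,
    k_sd: float = 5.0,
    policy: str = "any-task",
    listed_tasks: tuple[str, ...] = (),
) -> ScreeningReport:
    """Flag participants whose task-level mean error lies more than
    ``k_sd`` group SDs from the group mean (SD computed including the
    candidate), and decide removals per policy:

    * ``any-task`` — removed if flagged in any task (default);
    * ``all-tasks`` — removed only if flagged in every task;
    * ``listed-tasks`` — removed if flagged in every task named in
      ``listed_tasks``.
    """
    if k_sd <= 0:
        raise ValueError("k_sd must be > 0")
    if policy not in POLICIES:
        raise ValueError(f"policy must be one of {POLICIES}")
    if policy == "listed-tasks" and not listed_tasks:
        raise ValueError("listed-tasks policy requires listed_tasks")
    if len(task_matrix) < 3:
        raise ValueError("need at least 3 participants for a stable group SD")
    z = (task_matrix - task_matrix.mean()) / task_matrix.std(ddof=1)
    flags = z.abs() > k_sd
    report = ScreeningReport(
        flags=flags, z_scores=z, k_sd=k_sd, policy=policy,
        listed_tasks=tuple(listed_tasks),
    )
    for pid, row in flags.iterrows():
        if policy == "any-task":
            hit = row.any()
        elif policy == "all-tasks":
            hit = row.all()
        else:
            hit = all(row.get(t, False) for t in listed_tasks)
        if hit:
            report.removed.append(pid)
            report.reasons[pid] = list(row.index[row])
    if report.removed:
        logger.info(
            "screen_outliers (policy=%s, k=%g): removed %s",
            policy, k_sd, report.removed,
        )
    return report


# -- Table-1-style writer ----------------------------------------------------

def summary_grid(session_matrices: dict[Task | str, pd.DataFrame]) -> pd.DataFrame:
    """Group mean and SD of bisection error per task x session, with
    all-session and all-task marginals (marginals are taken over the
    participant-level averaged values, matching how a summary table is
    normally reported).
    """
    names = [
        t.value if isinstance(t, Task) else str(t) for t in session_matrices
    ]
    mats = {n: m for n, m in zip(names, session_matrices.values())}
    sessions = sorted({c for m in mats.values() for c in m.columns})
    rows = {}
    for name, mat in mats.items():
        row = {}
        for s in sessions:
            row[("mean", s)] = mat[s].mean()
            row[("sd", s)] = mat[s].std(ddof=1)
        all_sess = mat.mean(axis=1)
        row[("mean", "all_sessions")] = all_sess.mean()
        row[("sd", "all_sessions")] = all_sess.std(ddof=1)
        rows[name] = row
    # all-task marginal: average each participant over tasks first
    per_task = {n: m for n, m in mats.items()}
    row = {}
    for s in sessions:
        stacked = pd.concat([m[s] for m in per_task.values()], axis=1)
        avg = stacked.mean(axis=1)
        row[("mean", s)] = avg.mean()
        row[("sd", s)] = avg.std(ddof=1)
    grand = pd.concat(
        [m.mean(axis=1) for m in per_task.values()], axis=1
    ).mean(axis=1)
    row[("mean", "all_sessions")] = grand.mean()
    row[("sd", "all_sessions")] = grand.std(ddof=1)
    rows["all_tasks"] = row
    grid = pd.DataFrame(rows).T
    grid.columns = pd.MultiIndex.from_tuples(grid.columns)
    return grid
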