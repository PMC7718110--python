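"""End-to-end pipeline: trials in, reliability report out.

Stages, in order: timeout filtering; per-session psychometric fits for
the landmark task and trial averaging for the manual tasks; outlier and
fit-quality screening; participants x sessions and participants x tasks
error matrices; reliability (consistency alpha per task across sessions,
and across tasks); one-sample t-tests with Bonferroni-adjusted levels
(family of 4 session tests, family of 3 task tests); the tasks x sessions
within-subjects ANOVA.  Everything is deterministic given the master
seed, from which all sub-seeds are derived.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import errors as err_mod
from . import inference, psychometrics, reliability
from .design import Task, StudyDesign, default_design
from .simulate import PopulationParams, default_population, simulate_study

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; seeds are recorded in all outputs.

    Provide either ``trial_path`` (a delimited trial table) or leave it
    None to simulate a study from ``design``/``population`` with ``seed``.
    """

    seed: int = 0
    design: StudyDesign = field(default_factory=default_design)
    population: PopulationParams = field(default_factory=default_population)
    trial_path: str | None = None
    outlier_k_sd: float = 5.0
    outlier_policy: str = "any-task"
    listed_tasks: tuple[str, ...] = ()
    lapse_max: float = 0.10
    n_boot: int = 0  # bootstrap replicates per landmark cell (0 = off)
    n_quality_sims: int = 0  # deviance Monte-Carlo sims per cell (0 = off)
    quality_p_min: float = 0.01
    quality_se_max: float = 2.0
    family_alpha: float = 0.05
    output_dir: str | None = None

    def digest(self) -> str:
        # output_dir is excluded: where a run is written must not change
        # its identity
        payload = {
            k: (repr(v) if not isinstance(v, (int, float, str, type(None))) else v)
            for k, v in self.__dict__.items()
            if k != "output_dir"
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class StudyReport:
    """All result surfaces of one pipeline run."""

    summary_grid: pd.DataFrame  # task x session mean/SD with marginals
    session_matrices: dict[str, pd.DataFrame]
    task_matrix: pd.DataFrame
    reliability_by_task: pd.DataFrame
    cross_task_reliability: pd.DataFrame
    cross_task_correlations: reliability.CorrelationResult
    ttests: pd.DataFrame
    anova: inference.AnovaResult
    screening: err_mod.ScreeningReport
    poor_fit_participants: list[str]
    n_analysed: int
    manifest: dict

    def write(self, directory: str | Path) -> None:
        """Write every table as delimited text plus a run manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.summary_grid.to_csv(directory / "summary_grid.tsv", sep="\t")
        for task, mat in self.session_matrices.items():
            mat.to_csv(directory / f"session_errors_{task}.tsv", sep="\t")
        self.task_matrix.to_csv(directory / "task_errors.tsv", sep="\t")
        self.reliability_by_task.to_csv(
            directory / "reliability_by_task.tsv", sep="\t"
        )
        self.cross_task_reliability.to_csv(
            directory / "reliability_cross_task.tsv", sep="\t"
        )
        self.cross_task_correlations.r.to_csv(
            directory / "cross_task_pearson_r.tsv", sep="\t"
        )
        self.cross_task_correlations.p.to_csv(
            directory / "cross_task_pearson_p.tsv", sep="\t"
        )
        self.ttests.to_csv(directory / "ttests.tsv", sep="\t", index=False)
        self.anova.table.to_csv(directory / "anova.tsv", sep="\t")
        self.anova.strata.to_csv(directory / "anova_strata.tsv", sep="\t")
        self.screening.flags.to_csv(directory / "screening_flags.tsv", sep="\t")
        (directory / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2, sort_keys=True)
        )


def _sub_seed(master: int, label: str) -> int:
    key = int.from_bytes(label.encode("utf8"), "little") % 2**31
    return int(
        np.random.SeedSequence([master, key]).generate_state(1)[0] % 2**31
    )


def run_pipeline(config: PipelineConfig) -> StudyReport:
    """Execute the full analysis and return the report (also written to
    ``config.output_dir`` when set)."""
    # -- input ---------------------------------------------------------------
    if config.trial_path is not None:
        trials = err_mod.read_trials(config.trial_path)
        source = {"trial_path": str(config.trial_path)}
    else:
        study = simulate_study(
            config.design, config.population, seed=_sub_seed(config.seed, "simulate")
        )
        trials = study.trials
        source = {"simulated": True, "seed": config.seed}

    design = config.design
    trials = err_mod.filter_trials(trials, design.response_timeout_s)

    # -- per-task session matrices -------------------------------------------
    session_matrices: dict[str, pd.DataFrame] = {}
    poor_fit: list[str] = []
    if Task.LANDMARK in design.tasks:
        lm_matrix, fits, boots = psychometrics.landmark_session_errors(
            trials,
            lapse_max=config.lapse_max,
            n_boot=config.n_boot,
            seed=_sub_seed(config.seed, "bootstrap"),
        )
        for (pid, sess), fit in fits.items():
            quality = psychometrics.fit_quality(
                fit,
                bootstrap=boots.get((pid, sess)),
                p_min=config.quality_p_min,
                se_max=config.quality_se_max,
                n_sims=config.n_quality_sims,
                seed=_sub_seed(config.seed, f"quality-{pid}-{sess}"),
            ) if config.n_quality_sims > 0 or not fit.converged else None
            if (quality is not None and not quality.passed) or not fit.converged:
                if pid not in poor_fit:
                    poor_fit.append(pid)
        session_matrices[Task.LANDMARK.value] = lm_matrix
    for task in (Task.LINE, Task.ROD):
        if task in design.tasks:
            sub = trials[trials["task"] == task.value]
            session_matrices[task.value] = err_mod.session_means(sub)
    if poor_fit:
        logger.info("removing participants with poor psychometric fits: %s", poor_fit)

    # -- screening -----------------------------------------------------------
    task_matrix = err_mod.task_means(session_matrices)
    complete = task_matrix.dropna()
    complete = complete.loc[~complete.index.isin(poor_fit)]
    screening = err_mod.screen_outliers(
        complete,
        k_sd=config.outlier_k_sd,
        policy=config.outlier_policy,
        listed_tasks=config.listed_tasks,
    )
    keep = screening.keep_index()
    session_matrices = {
        t: m.loc[m.index.intersection(keep)] for t, m in session_matrices.items()
    }
    task_matrix = complete.loc[keep]

    # -- reliability -----------------------------------------------------------
    rel_rows = []
    for task, mat in session_matrices.items():
        res = reliability.cronbach_alpha(mat.dropna())
        agr = reliability.agreement_icc(mat.dropna())
        row = res.__dict__ | {"task": task, "agreement_icc": agr.alpha}
        rel_rows.append(row)
    reliability_by_task = pd.DataFrame(rel_rows).set_index("task")
    cross = reliability.cronbach_alpha(task_matrix)
    cross_agr = reliability.agreement_icc(task_matrix)
    cross_task_reliability = pd.DataFrame(
        [cross.__dict__ | {"agreement_icc": cross_agr.alpha}]
    )
    correlations = reliability.pairwise_pearson(task_matrix)

    # -- t-tests ---------------------------------------------------------------
    sessions = sorted(
        {int(c) for m in session_matrices.values() for c in m.columns}
    )
    session_plan = inference.bonferroni(config.family_alpha, len(sessions))
    task_plan = inference.bonferroni(config.family_alpha, len(session_matrices))
    trows = []
    aligned = {t: m.loc[task_matrix.index] for t, m in session_matrices.items()}
    for s in sessions:
        vals = pd.concat([m[s] for m in aligned.values()], axis=1).mean(axis=1)
        res = inference.one_sample_t(vals, adjusted_alpha=session_plan.adjusted_alpha)
        trows.append(
            {"family": "session", "level": s, "adjusted_alpha_display":
             session_plan.display, **res.__dict__, "significant": res.significant}
        )
    for task in task_matrix.columns:
        res = inference.one_sample_t(
            task_matrix[task], adjusted_alpha=task_plan.adjusted_alpha
        )
        trows.append(
            {"family": "task", "level": task, "adjusted_alpha_display":
             task_plan.display, **res.__dict__, "significant": res.significant}
        )
    grand = task_matrix.mean(axis=1)
    res = inference.one_sample_t(grand)
    trows.append(
        {"family": "overall", "level": "all", "adjusted_alpha_display": "",
         **res.__dict__, "significant": res.p_value <= config.family_alpha}
    )
    ttests = pd.DataFrame(trows)

    # -- ANOVA -----------------------------------------------------------------
    long = (
        pd.concat(
            {t: m.stack() for t, m in aligned.items()}, names=["task"]
        )
        .rename("error_mm")
        .reset_index()
    )
    anova = inference.rm_anova(long)

    # -- assemble --------------------------------------------------------------
    grid = err_mod.summary_grid(aligned)
    report = StudyReport(
        summary_grid=grid,
        session_matrices=aligned,
        task_matrix=task_matrix,
        reliability_by_task=reliability_by_task,
        cross_task_reliability=cross_task_reliability,
        cross_task_correlations=correlations,
        ttests=ttests,
        anova=anova,
        screening=screening,
        poor_fit_participants=poor_fit,
        n_analysed=len(task_matrix),
        manifest={
            "seed": config.seed,
            "config_digest": config.digest(),
            "source": source,
            "n_analysed": len(task_matrix),
            "removed_outliers": screening.removed,
            "removed_poor_fits": poor_fit,
            "adjusted_alpha_sessions": session_plan.display,
            "adjusted_alpha_tasks": task_plan.display,
        },
    )
    if config.output_dir is not None:
        report.write(config.output_dir)
    return report


def config_from_file(path: str | Path) -> PipelineConfig:
    """Load a plain-text key/value (YAML subset) pipeline config."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    simple = {
        "seed", "trial_path", "outlier_k_sd", "outlier_policy", "lapse_max",
        "n_boot", "n_quality_sims", "quality_p_min", "quality_se_max",
        "family_alpha", "output_dir",
    }
    for key, val in raw.items():
        if key in simple:
            kwargs[key] = val
        elif key == "listed_tasks":
            kwargs[key] = tuple(val)
        elif key == "design":
            kwargs[key] = StudyDesign.from_config(val)
        else:
            raise ValueError(f"unknown config key: {key}")
    return PipelineConfig(**kwargs)
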