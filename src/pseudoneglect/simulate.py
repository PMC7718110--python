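"""Generative observer model for bisection studies.

Every downstream stage (psychometric fitting, error matrices, reliability,
power) is exercised against data from this module, so the generator encodes
exactly the statistical structure the analysis assumes:

* each observer carries a latent per-task bias ``b`` (mm, leftward
  negative);
* each session adds a shared jitter drawn once per participant x task x
  session — this is the mechanism that degrades cross-session reliability;
* manual (line/rod) trials add independent Gaussian trial noise to the
  perceived midpoint;
* landmark trials are Bernoulli draws from a cumulative-normal psychometric
  function with equal guess and lapse rates, so the generative model is the
  exact inverse of the fitted one:

      P(right longer | x) = lam + (1 - 2*lam) * Phi((x - pse) / sigma),

  with ``pse = -(b + session_jitter)`` (the bisection-error sign
  convention negates the PSE).

Population defaults are calibrated so that session-level and
across-session error SDs, and the implied cross-session consistency, sit
in the range reported for healthy young adults on these tasks (landmark
consistency about 0.8, tactile rod moderate, visuomotor line bisection
near zero).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .design import MANUAL_TASKS, StudyDesign, Task, default_design, enumerate_trials

#: canonical trial-table schema, one row per observed trial
TRIAL_COLUMNS = [
    "participant_id",
    "session_index",
    "task",
    "length_mm",
    "offset_mm",
    "asymmetry_mm",
    "hand",
    "start_side",
    "response",
    "response_time_s",
    "calibration_offset_mm",
]

RIGHT_LONGER = "right_longer"
LEFT_LONGER = "left_longer"


@dataclass(frozen=True)
class TaskPopulation:
    """Population distribution of latent bias for one task.

    mean_mm
        population mean bisection error (mm, leftward negative).
    between_sd
        SD of the stable participant-level bias (mm); this is the signal
        that reliability measures try to detect.
    session_sd
        SD of the session-level jitter shared by all trials of a session
        (mm); this is the noise that consistency is measured against.
    trial_sd
        SD of trial-level response noise for manual tasks (mm).  For the
        landmark task trial noise is binomial, governed by ``sigma_psy``.
    """

    mean_mm: float
    between_sd: float
    session_sd: float
    trial_sd: float = 0.0

    def __post_init__(self) -> None:
        for name in ("between_sd", "session_sd", "trial_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class PopulationParams:
    """Hierarchical population from which a simulated study is drawn."""

    tasks: dict[Task, TaskPopulation] = field(
        default_factory=lambda: {
            Task.LANDMARK: TaskPopulation(-0.20, between_sd=1.2, session_sd=1.2),
            Task.LINE: TaskPopulation(
                -1.92, between_sd=0.5, session_sd=5.2, trial_sd=10.0
            ),
            Task.ROD: TaskPopulation(
                -0.84, between_sd=2.6, session_sd=3.9, trial_sd=8.0
            ),
        }
    )
    sigma_psy: float = 2.5  # psychometric slope SD, mm
    lapse_rate: float = 0.02
    timeout_rate: float = 0.02  # fraction of line trials exceeding the timeout
    calibration_sd: float = 0.5  # per-participant stylus calibration offset SD, mm

    def __post_init__(self) -> None:
        if self.sigma_psy <= 0:
            raise ValueError("sigma_psy must be > 0")
        if not 0 <= self.lapse_rate < 0.5:
            raise ValueError("lapse_rate must be in [0, 0.5)")
        if not 0 <= self.timeout_rate < 1:
            raise ValueError("timeout_rate must be in [0, 1)")
        if self.calibration_sd < 0:
            raise ValueError("calibration_sd must be >= 0")


@dataclass(frozen=True)
class ObserverProfile:
    """One simulated observer's latent parameters (per-task bias in mm,
    leftward negative; for the landmark task the bias is the negated PSE)."""

    participant_id: str
    bias_mm: dict[Task, float]
    sigma_psy: float
    lapse_rate: float
    session_sd: dict[Task, float]
    trial_sd: dict[Task, float]
    calibration_offset_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_psy <= 0:
            raise ValueError("sigma_psy must be > 0")
        if not 0 <= self.lapse_rate < 0.5:
            raise ValueError("lapse_rate must be in [0, 0.5)")


@dataclass
class SimulatedStudy:
    design: StudyDesign
    population: PopulationParams
    observers: list[ObserverProfile]
    session_bias: dict[tuple[str, Task, int], float]
    trials: pd.DataFrame
    seed: int

    def write(self, directory: str | Path) -> None:
        """Write the trial table plus a manifest recording seed and
        population parameters."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.trials.to_csv(directory / "trials.tsv", sep="\t", index=False)
        manifest = {
            "seed": self.seed,
            "n_participants": self.design.n_participants,
            "n_sessions": self.design.n_sessions,
            "population": {
                t.value: asdict(p) for t, p in self.population.tasks.items()
            },
            "sigma_psy": self.population.sigma_psy,
            "lapse_rate": self.population.lapse_rate,
            "timeout_rate": self.population.timeout_rate,
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def default_population() -> PopulationParams:
    return PopulationParams()


def p_right_longer(
    asymmetry_mm: np.ndarray | float,
    pse_mm: float,
    sigma_psy: float,
    lapse_rate: float,
) -> np.ndarray | float:
    """Probability of a "right side longer" response at a given asymmetry.

    Equal guess and lapse rates give the symmetric form
    ``lam + (1 - 2 lam) Phi((x - pse) / sigma)``.
    """
    return lapse_rate + (1.0 - 2.0 * lapse_rate) * norm.cdf(
        (np.asarray(asymmetry_mm, dtype=float) - pse_mm) / sigma_psy
    )


def simulate_landmark_trial(
    observer: ObserverProfile,
    session_bias_mm: float,
    asymmetry_mm: float,
    rng: np.random.Generator,
) -> str:
    """Draw one 2AFC landmark response.

    The effective PSE is the negated total bias for this session,
    ``pse = -(b + session_bias)``, so a leftward (negative) bias puts the
    50% crossing at a positive asymmetry.
    """
    pse = -(observer.bias_mm[Task.LANDMARK] + session_bias_mm)
    p = p_right_longer(asymmetry_mm, pse, observer.sigma_psy, observer.lapse_rate)
    return RIGHT_LONGER if rng.random() < p else LEFT_LONGER


def simulate_manual_trial(
    observer: ObserverProfile,
    session_bias_mm: float,
    length_mm: float,
    offset_mm: float,
    task: Task,
    rng: np.random.Generator,
) -> float:
    """Draw one manual bisection response (the recorded coordinate).

    Rod responses are measured from the participant's left end of the rod
    (a 100 mm rod bisected 5 mm left of centre is recorded as 45 mm).
    Line responses are screen x-coordinates with the body midline at 0, so
    the line's physical midpoint sits at ``offset_mm``; the participant's
    stylus calibration offset is added to the touch, mirroring what the
    touchscreen records before calibration correction.
    """
    if task not in MANUAL_TASKS:
        raise ValueError(f"manual trial for non-manual task {task}")
    err = (
        observer.bias_mm[task]
        + session_bias_mm
        + rng.normal(0.0, observer.trial_sd[task])
    )
    if task is Task.ROD:
        return length_mm / 2.0 + err
    return offset_mm + err + observer.calibration_offset_mm


def draw_observers(
    design: StudyDesign, population: PopulationParams, rng: np.random.Generator
) -> list[ObserverProfile]:
    observers = []
    width = len(str(design.n_participants))
    for i in range(design.n_participants):
        pid = f"P{i + 1:0{width}d}"
        bias = {
            t: float(rng.normal(p.mean_mm, p.between_sd))
            for t, p in population.tasks.items()
            if t in design.tasks
        }
        observers.append(
            ObserverProfile(
                participant_id=pid,
                bias_mm=bias,
                sigma_psy=population.sigma_psy,
                lapse_rate=population.lapse_rate,
                session_sd={
                    t: population.tasks[t].session_sd for t in design.tasks
                },
                trial_sd={t: population.tasks[t].trial_sd for t in design.tasks},
                calibration_offset_mm=float(
                    rng.normal(0.0, population.calibration_sd)
                ),
            )
        )
    return observers


def simulate_study(
    design: StudyDesign | None = None,
    population: PopulationParams | None = None,
    seed: int = 0,
) -> SimulatedStudy:
    """Simulate a complete multi-session study.

    Hierarchy: participant bias ~ Normal(mean, between_sd) per task;
    session jitter ~ Normal(0, session_sd) per participant x task x
    session; every enumerated trial receives a response.  A
    ``timeout_rate`` fraction of line-bisection trials exceed the response
    timeout (missing response, to exercise filtering).  Deterministic
    given ``seed``.
    """
    design = design if design is not None else default_design()
    population = population if population is not None else default_population()
    missing = [t for t in design.tasks if t not in population.tasks]
    if missing:
        raise ValueError(f"population lacks parameters for tasks: {missing}")

    root = np.random.SeedSequence(seed)
    ss_obs, ss_sess, ss_trials, ss_order = root.spawn(4)
    observers = draw_observers(design, population, np.random.default_rng(ss_obs))

    rng_sess = np.random.default_rng(ss_sess)
    session_bias: dict[tuple[str, Task, int], float] = {}
    for obs in observers:
        for task in design.tasks:
            for s in range(1, design.n_sessions + 1):
                session_bias[(obs.participant_id, task, s)] = float(
                    rng_sess.normal(0.0, obs.session_sd[task])
                )

    rng = np.random.default_rng(ss_trials)
    order_seed = int(
        np.random.default_rng(ss_order).integers(0, 2**31 - 1)
    )
    rows = []
    for obs in observers:
        for s in range(1, design.n_sessions + 1):
            for spec in enumerate_trials(design, obs.participant_id, s, order_seed):
                sb = session_bias[(obs.participant_id, spec.task, s)]
                timeout = False
                if spec.task is Task.LANDMARK:
                    response: str | float = simulate_landmark_trial(
                        obs, sb, spec.asymmetry_mm, rng
                    )
                    rt = min(float(rng.lognormal(-0.3, 0.4)), 4.5)
                else:
                    response = simulate_manual_trial(
                        obs, sb, spec.length_mm, spec.offset_mm, spec.task, rng
                    )
                    rt = min(float(rng.lognormal(0.2, 0.4)), 4.5)
                    if (
                        spec.task is Task.LINE
                        and rng.random() < population.timeout_rate
                    ):
                        timeout = True
                rows.append(
                    {
                        "participant_id": obs.participant_id,
                        "session_index": s,
                        "task": spec.task.value,
                        "length_mm": spec.length_mm,
                        "offset_mm": spec.offset_mm,
                        "asymmetry_mm": spec.asymmetry_mm,
                        "hand": spec.hand,
                        "start_side": spec.start_side,
                        "response": np.nan if timeout else response,
                        "response_time_s": (
                            design.response_timeout_s
                            + float(rng.exponential(0.5))
                            if timeout
                            else rt
                        ),
                        "calibration_offset_mm": (
                            obs.calibration_offset_mm
                            if spec.task is Task.LINE
                            else 0.0
                        ),
                    }
                )
    trials = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    return SimulatedStudy(
        design=design,
        population=population,
        observers=observers,
        session_bias=session_bias,
        trials=trials,
        seed=seed,
    )


def population_for_consistency(
    consistency: float,
    k: int,
    mean_mm: float = 0.0,
    noise_sd: float = 1.0,
) -> tuple[float, float]:
    """Between- and within-subject SDs whose population consistency
    (average-measures, k measurements) equals ``consistency``.

    Inverts ``alpha = sigma_b^2 / (sigma_b^2 + sigma_e^2 / k)`` at
    ``sigma_e = noise_sd``; returns ``(between_sd, noise_sd)``.
    """
    if not 0 < consistency < 1:
        raise ValueError("consistency must be in (0, 1)")
    if k < 2:
        raise ValueError("k must be >= 2")
    sigma_b2 = consistency / (1.0 - consistency) * noise_sd**2 / k
    return float(np.sqrt(sigma_b2)), float(noise_sd)
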