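"""Factorial study design for spatial bisection experiments.

Three tasks probe the same latent spatial bias through different effectors:

* ``landmark`` — a two-alternative forced choice ("which side of a
  pre-bisected line is longer?") driven by a signed stimulus asymmetry;
* ``line_bisection`` — manual transection of a visual line with a stylus;
* ``rod_bisection`` — tactile transection of a physical rod while
  blindfolded.

A :class:`StudyDesign` records the factor levels (stimulus lengths, lateral
position offsets, landmark asymmetries) and per-session trial counts, and
:func:`enumerate_trials` expands it into the concrete, counterbalanced trial
list for one participant-session.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np


class Task(str, enum.Enum):
    """The three bisection task modalities."""

    LANDMARK = "landmark"
    LINE = "line_bisection"
    ROD = "rod_bisection"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


MANUAL_TASKS = (Task.LINE, Task.ROD)


@dataclass(frozen=True)
class TrialSpec:
    """One planned trial (stimulus geometry only, no response).

    ``asymmetry_mm`` is present only for landmark trials (signed, rightward
    positive).  ``hand`` applies to the manual tasks, ``start_side`` only to
    rod bisection (which end the participant starts scanning from).
    """

    participant_id: str
    session_index: int
    task: Task
    length_mm: float
    offset_mm: float
    asymmetry_mm: float | None = None
    hand: str | None = None
    start_side: str | None = None

    def __post_init__(self) -> None:
        if (self.task is Task.LANDMARK) != (self.asymmetry_mm is not None):
            raise ValueError("asymmetry_mm must be present iff task is landmark")
        if (self.task in MANUAL_TASKS) != (self.hand is not None):
            raise ValueError("hand must be present iff task is manual")
        if (self.task is Task.ROD) != (self.start_side is not None):
            raise ValueError("start_side must be present iff task is rod bisection")


@dataclass(frozen=True)
class StudyDesign:
    """Factor levels and per-session trial counts of a bisection study.

    Units are mm throughout; signed quantities are leftward-negative.
    """

    n_participants: int = 24
    n_sessions: int = 4
    tasks: tuple[Task, ...] = (Task.LANDMARK, Task.LINE, Task.ROD)
    lengths_mm: tuple[float, ...] = (100.0, 200.0, 300.0)
    offsets_mm: tuple[float, ...] = (-20.0, 0.0, 20.0)
    asymmetries_mm: tuple[float, ...] = (
        -10.0, -8.0, -6.0, -4.0, -2.0, 0.0, 2.0, 4.0, 6.0, 8.0, 10.0,
    )
    trials_per_asymmetry: int = 15
    trials_at_zero_asymmetry: int = 30
    line_trials_per_session: int = 90
    rod_trials_per_session: int = 54
    response_timeout_s: float = 5.0

    def __post_init__(self) -> None:
        if not self.lengths_mm or not self.offsets_mm:
            raise ValueError("lengths_mm and offsets_mm must be nonempty")
        for name in (
            "n_participants",
            "n_sessions",
            "trials_per_asymmetry",
            "trials_at_zero_asymmetry",
            "line_trials_per_session",
            "rod_trials_per_session",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.response_timeout_s <= 0:
            raise ValueError("response_timeout_s must be > 0")
        asyms = sorted(self.asymmetries_mm)
        if Task.LANDMARK in self.tasks:
            if sorted(-a for a in asyms) != asyms:
                raise ValueError("asymmetries_mm must be symmetric about 0")

    @property
    def nonzero_asymmetries(self) -> tuple[float, ...]:
        return tuple(a for a in self.asymmetries_mm if a != 0.0)

    @property
    def landmark_trials_per_session(self) -> int:
        return (
            self.trials_per_asymmetry * len(self.nonzero_asymmetries)
            + self.trials_at_zero_asymmetry
        )

    def trials_per_session(self, task: Task) -> int:
        if task is Task.LANDMARK:
            return self.landmark_trials_per_session
        if task is Task.LINE:
            return self.line_trials_per_session
        if task is Task.ROD:
            return self.rod_trials_per_session
        raise ValueError(f"unknown task: {task}")

    def total_trials(self, task: Task) -> int:
        return self.trials_per_session(task) * self.n_sessions

    # -- plain-text (key: value) serialization -------------------------------

    def to_config(self, path: str | Path) -> None:
        lines = []
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = ", ".join(str(x.value if isinstance(x, Task) else x) for x in v)
            lines.append(f"{f.name}: {v}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_config(cls, path: str | Path) -> "StudyDesign":
        kv: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition(":")
            kv[key.strip()] = val.strip()
        kwargs: dict = {}
        for f in fields(cls):
            if f.name not in kv:
                continue
            raw = kv[f.name]
            if f.name == "tasks":
                kwargs[f.name] = tuple(Task(t.strip()) for t in raw.split(","))
            elif f.name in ("lengths_mm", "offsets_mm", "asymmetries_mm"):
                kwargs[f.name] = tuple(float(x) for x in raw.split(","))
            elif f.name == "response_timeout_s":
                kwargs[f.name] = float(raw)
            else:
                kwargs[f.name] = int(raw)
        return cls(**kwargs)


def default_design() -> StudyDesign:
    """The reference design: 4 sessions; lines/rods of 100/200/300 mm at
    lateral offsets 0/±20 mm; landmark asymmetries 0, ±2..±10 mm with 15
    trials per nonzero level and 30 at zero (180/session); 90 line and 54
    rod trials per session; 5 s response timeout.
    """
    return StudyDesign()


def _balanced(levels: Sequence, n: int, rng: np.random.Generator) -> np.ndarray:
    """n labels drawn from ``levels`` with counts as equal as possible.

    Exact when n divides evenly; the remainder is assigned by seeded draw
    without replacement.  Order is shuffled.
    """
    levels = list(levels)
    q, r = divmod(n, len(levels))
    out = np.array(levels * q + list(rng.choice(levels, size=r, replace=False)))
    rng.shuffle(out)
    return out


def enumerate_trials(
    design: StudyDesign,
    participant_id: str,
    session_index: int,
    seed: int,
    tasks: Iterable[Task] | None = None,
) -> list[TrialSpec]:
    """Expand a design into the counterbalanced trial list for one session.

    Counts are exact on every factor margin the design states (per length,
    per offset, per asymmetry level, per hand, per start side); joint
    assignments beyond those margins are balanced random draws from ``seed``.
    Rod trials are blocked by rod length (the length changes only between
    blocks).  Deterministic given (design, ids, seed).
    """
    if not 1 <= session_index <= design.n_sessions:
        raise ValueError(
            f"session_index {session_index} outside [1, {design.n_sessions}]"
        )
    rng = np.random.default_rng(
        np.random.SeedSequence([seed, session_index, _stable_id(participant_id)])
    )
    trials: list[TrialSpec] = []
    for task in tasks if tasks is not None else design.tasks:
        if task is Task.LANDMARK:
            trials.extend(_landmark_trials(design, participant_id, session_index, rng))
        elif task is Task.LINE:
            trials.extend(_line_trials(design, participant_id, session_index, rng))
        elif task is Task.ROD:
            trials.extend(_rod_trials(design, participant_id, session_index, rng))
        else:
            raise ValueError(f"unknown task: {task}")
    return trials


def _stable_id(participant_id: str) -> int:
    # deterministic across processes (hash() is salted)
    return int.from_bytes(participant_id.encode("utf8"), "little") % (2**32)


def _landmark_trials(design, pid, session, rng) -> list[TrialSpec]:
    specs = []
    for asym in design.asymmetries_mm:
        n = (
            design.trials_at_zero_asymmetry
            if asym == 0.0
            else design.trials_per_asymmetry
        )
        lengths = _balanced(design.lengths_mm, n, rng)
        offsets = _balanced(design.offsets_mm, n, rng)
        specs.extend(
            TrialSpec(pid, session, Task.LANDMARK, float(L), float(o), float(asym))
            for L, o in zip(lengths, offsets)
        )
    order = rng.permutation(len(specs))
    return [specs[i] for i in order]


def _line_trials(design, pid, session, rng) -> list[TrialSpec]:
    n = design.line_trials_per_session
    n_cells = len(design.lengths_mm) * len(design.offsets_mm)
    per_cell, rem = divmod(n, n_cells)
    if rem:
        raise ValueError(
            f"line_trials_per_session={n} not divisible over "
            f"{n_cells} length x offset cells"
        )
    specs = []
    for L in design.lengths_mm:
        for o in design.offsets_mm:
            hands = _balanced(["left", "right"], per_cell, rng)
            specs.extend(
                TrialSpec(pid, session, Task.LINE, float(L), float(o), hand=str(h))
                for h in hands
            )
    order = rng.permutation(len(specs))
    return [specs[i] for i in order]


def _rod_trials(design, pid, session, rng) -> list[TrialSpec]:
    n = design.rod_trials_per_session
    n_cells = len(design.lengths_mm) * len(design.offsets_mm)
    per_cell, rem = divmod(n, n_cells)
    if rem:
        raise ValueError(
            f"rod_trials_per_session={n} not divisible over "
            f"{n_cells} length x offset cells"
        )
    by_length: dict[float, list[TrialSpec]] = {L: [] for L in design.lengths_mm}
    for L in design.lengths_mm:
        for o in design.offsets_mm:
            hands = _balanced(["left", "right"], per_cell, rng)
            starts = _balanced(["left", "right"], per_cell, rng)
            by_length[L].extend(
                TrialSpec(
                    pid, session, Task.ROD, float(L), float(o),
                    hand=str(h), start_side=str(s),
                )
                for h, s in zip(hands, starts)
            )
    # rod length is blocked: shuffle within each length, then order blocks
    specs = []
    block_order = rng.permutation(len(design.lengths_mm))
    lengths = list(design.lengths_mm)
    for bi in block_order:
        block = by_length[lengths[bi]]
        order = rng.permutation(len(block))
        specs.extend(block[i] for i in order)
    return specs
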