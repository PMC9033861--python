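"""Synthetic social-evaluation task: schedules and forward-simulated participants.

The task emulated here presents a sequence of raters drawn from a small
number of groups that differ in how likely they are to approve of the
participant.  On every trial the participant sees the rater's group cue,
predicts approval or disapproval, and (on feedback trials) receives the
outcome.  Every 2-3 trials a probe collects a momentary self-esteem rating
on a visual-analogue scale, mapped here to the open unit interval.

Feedback is computer-generated: each group delivers a fixed share of
approvals (defaults 15/30/70/85% across four groups), arranged so that
approvals and disapprovals are balanced 50/50 overall.  Because the real
participant data are not public, cohorts for model development, parameter
recovery and model recovery are forward-simulated from any registered model
with known parameters.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import yaml

from . import config
from .errors import ConfigError
from .registry import get_model

__all__ = [
    "GroupDesign",
    "TaskSchedule",
    "ParticipantRecord",
    "make_schedule",
    "simulate_participant",
    "generate_cohort",
    "cohort_to_csv",
    "cohort_from_csv",
    "design_from_yaml",
    "design_to_yaml",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupDesign:
    """Design constants for one task session.

    ``raters_per_group`` may be a single int (same size for every group) or
    one count per group.  ``n_no_feedback`` adds trials that cue a group and
    collect a prediction but deliver no outcome (scanner sessions include
    24 of these).
    """

    n_groups: int = 4
    approval_rates: tuple[float, ...] = config.DEFAULT_APPROVAL_RATES
    raters_per_group: tuple[int, ...] | int = config.DISCOVERY_RATERS_PER_GROUP
    n_no_feedback: int = 0
    first_probe_after: int = config.FIRST_PROBE_AFTER
    probe_gaps: tuple[int, ...] = config.PROBE_GAPS
    seed: int = 0

    def __post_init__(self):
        if self.n_groups < 1:
            raise ConfigError("n_groups must be >= 1")
        if len(self.approval_rates) != self.n_groups:
            raise ConfigError(
                f"{len(self.approval_rates)} approval rates for {self.n_groups} groups")
        if isinstance(self.raters_per_group, int):
            object.__setattr__(
                self, "raters_per_group", (self.raters_per_group,) * self.n_groups)
        else:
            object.__setattr__(self, "raters_per_group", tuple(self.raters_per_group))
        if len(self.raters_per_group) != self.n_groups:
            raise ConfigError("raters_per_group length must match n_groups")
        for g, (rate, n) in enumerate(zip(self.approval_rates, self.raters_per_group), 1):
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"group {g}: approval rate {rate} outside [0, 1]")
            if n < 1:
                raise ConfigError(f"group {g}: raters_per_group must be >= 1")
        if self.n_no_feedback < 0:
            raise ConfigError("n_no_feedback must be >= 0")

    @property
    def n_feedback_trials(self) -> int:
        return sum(self.raters_per_group)

    @property
    def n_trials(self) -> int:
        return self.n_feedback_trials + self.n_no_feedback

    def approval_counts(self) -> tuple[int, ...]:
        """Integer approvals per group, preserving the overall approval total.

        Each group's count is rate x raters rounded half-up; if the rounded
        counts miss the rounded overall total, the largest group absorbs a
        +-1 correction.  A larger discrepancy, or a correction that would
        push a count outside [0, raters], is a configuration error.
        """
        exact = [r * n for r, n in zip(self.approval_rates, self.raters_per_group)]
        counts = [int(np.floor(x + 0.5)) for x in exact]
        target = int(np.floor(sum(exact) + 0.5))
        diff = target - sum(counts)
        if diff != 0:
            if abs(diff) > 1:
                bad = [g + 1 for g, x in enumerate(exact) if x != round(x)]
                raise ConfigError(
                    f"approval counts not realisable as integers for groups {bad}: "
                    f"rounded counts miss the overall total by {diff}")
            g = int(np.argmax(self.raters_per_group))
            counts[g] += diff
            if not 0 <= counts[g] <= self.raters_per_group[g]:
                raise ConfigError(
                    f"group {g + 1}: adjusted approval count {counts[g]} "
                    f"outside [0, {self.raters_per_group[g]}]")
        return tuple(counts)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["approval_rates"] = list(self.approval_rates)
        d["raters_per_group"] = list(self.raters_per_group)
        d["probe_gaps"] = list(self.probe_gaps)
        return d


@dataclass
class TaskSchedule:
    """One session: group cue, outcome and probe flag per trial.

    ``group`` is 1-based; ``outcome`` is 1 (approve), 0 (disapprove) or
    None (no-feedback trial); ``probe_after[t]`` flags a self-esteem probe
    immediately after trial t+1 (0-based storage, 1-based trial indices).
    """

    group: list[int]
    outcome: list[int | None]
    probe_after: list[bool]
    n_groups: int

    def __post_init__(self):
        n = len(self.group)
        if not (len(self.outcome) == len(self.probe_after) == n):
            raise ConfigError("schedule columns must have equal length")

    @property
    def n_trials(self) -> int:
        return len(self.group)

    @property
    def probe_trials(self) -> list[int]:
        """0-based indices of trials followed by a probe."""
        return [t for t, p in enumerate(self.probe_after) if p]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "trial": np.arange(1, self.n_trials + 1),
            "group": self.group,
            "outcome": [o if o is not None else pd.NA for o in self.outcome],
            "probe_after": self.probe_after,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, n_groups: int | None = None) -> "TaskSchedule":
        group = [int(g) for g in df["group"]]
        outcome = [None if pd.isna(o) else int(o) for o in df["outcome"]]
        probe = [bool(p) for p in df["probe_after"]]
        return cls(group, outcome, probe, n_groups or max(group))

    @classmethod
    def from_csv(cls, path, n_groups: int | None = None) -> "TaskSchedule":
        return cls.from_frame(pd.read_csv(path, float_precision="round_trip"), n_groups)


@dataclass
class ParticipantRecord:
    """One participant's predictions and self-esteem ratings on a schedule.

    ``predictions`` is aligned to trials (1 = predicted approval);
    ``se_rating`` is aligned to trials and holds a value exactly on probe
    trials, None elsewhere.
    """

    schedule: TaskSchedule
    predictions: list[int]
    se_rating: list[float | None]
    meta: dict = field(default_factory=dict)
    participant_id: str | int = 0

    def __post_init__(self):
        n = self.schedule.n_trials
        if len(self.predictions) != n or len(self.se_rating) != n:
            raise ConfigError("predictions/se_rating must align to the schedule")
        for t, (r, p) in enumerate(zip(self.se_rating, self.schedule.probe_after)):
            if (r is None) == p:
                raise ConfigError(f"trial {t + 1}: se_rating present iff probe_after")

    @property
    def n_predictions(self) -> int:
        return len(self.predictions)

    @property
    def n_ratings(self) -> int:
        return sum(r is not None for r in self.se_rating)

    @property
    def ratings(self) -> list[float]:
        """Probe ratings in trial order."""
        return [r for r in self.se_rating if r is not None]

    def to_frame(self) -> pd.DataFrame:
        df = self.schedule.to_frame()
        df.insert(0, "participant_id", self.participant_id)
        df["prediction"] = self.predictions
        df["se_rating"] = [r if r is not None else pd.NA for r in self.se_rating]
        return df


# ---------------------------------------------------------------------------
# Schedule construction
# ---------------------------------------------------------------------------

def make_schedule(design: GroupDesign) -> TaskSchedule:
    """Build a task schedule realising the design exactly.

    Deterministic given ``design.seed``: group order is a seeded shuffle of
    all rater trials, outcomes are seeded shuffles within group (hitting
    each group's approval count exactly), no-feedback trials are seeded
    insertions with a random group cue, and probe gaps are seeded draws
    from ``design.probe_gaps``.
    """
    rng = np.random.default_rng(design.seed)
    counts = design.approval_counts()

    # per-group outcome sequences with the exact approval count
    outcomes_by_group: list[list[int]] = []
    for napp, nrat in zip(counts, design.raters_per_group):
        seq = [1] * napp + [0] * (nrat - napp)
        rng.shuffle(seq)
        outcomes_by_group.append(seq)

    # interleave group cues across the session
    labels = np.repeat(np.arange(design.n_groups), design.raters_per_group)
    rng.shuffle(labels)
    group = [int(g) + 1 for g in labels]
    taken = [0] * design.n_groups
    outcome: list[int | None] = []
    for g in labels:
        outcome.append(outcomes_by_group[g][taken[g]])
        taken[g] += 1

    # insert no-feedback trials at random positions with random group cues
    for _ in range(design.n_no_feedback):
        pos = int(rng.integers(0, len(group) + 1))
        group.insert(pos, int(rng.integers(1, design.n_groups + 1)))
        outcome.insert(pos, None)

    n = len(group)
    probe = [False] * n
    t = design.first_probe_after
    while t <= n:
        probe[t - 1] = True
        t += int(rng.choice(design.probe_gaps))

    return TaskSchedule(group, outcome, probe, design.n_groups)


# ---------------------------------------------------------------------------
# Forward simulation
# ---------------------------------------------------------------------------

def simulate_participant(model: str, params, schedule: TaskSchedule,
                         seed: int, participant_id: str | int = 0,
                         ) -> ParticipantRecord:
    """Simulate one participant under a registered model with known parameters.

    Predictions are drawn from the model's per-trial choice probability and
    ratings from its rating distribution at each probe, with latent states
    evolved exactly as in the model's likelihood.  Reproducible given seed.
    """
    mod = get_model(model)
    mod.validate_params(params)
    rng = np.random.default_rng(seed)
    predictions, ratings = mod.simulate(params, schedule, rng)
    meta = {
        "generating_model": model,
        "generating_params": mod.params_to_dict(params),
        "seed": int(seed),
    }
    return ParticipantRecord(schedule, predictions, ratings, meta, participant_id)


def generate_cohort(model: str,
                    param_sampler: dict | Callable | None,
                    n_participants: int,
                    design: GroupDesign,
                    seed: int) -> list[ParticipantRecord]:
    """Simulate a cohort with independently sampled parameters and seeds.

    ``param_sampler`` is a dict of per-parameter uniform ranges in the
    model's fit coordinates (None selects the model's default generation
    ranges from :mod:`sociometer.config`) or a callable ``sampler(rng) ->
    params``.  Each participant gets an independent schedule and simulation
    seed derived from ``seed``; generating parameters are stored in
    ``meta`` for recovery scoring.
    """
    if n_participants < 1:
        raise ConfigError("n_participants must be >= 1")
    mod = get_model(model)
    if param_sampler is None:
        try:
            param_sampler = config.GENERATION_RANGES[model]
        except KeyError:
            raise ConfigError(
                f"no default generation ranges for model {model!r}; "
                "pass a param_sampler") from None

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_participants)
    records = []
    for i, child in enumerate(children):
        s_sched, s_params, s_sim = (int(x) for x in child.generate_state(3) % (2 ** 31))
        schedule = make_schedule(dataclasses.replace(design, seed=s_sched))
        rng = np.random.default_rng(s_params)
        if callable(param_sampler):
            params = param_sampler(rng)
        else:
            accept = config.GENERATION_CONSTRAINTS.get(model)
            for _ in range(10_000):
                draw = {k: float(rng.uniform(lo, hi))
                        for k, (lo, hi) in param_sampler.items()}
                if accept is None or accept(draw):
                    break
            else:  # pragma: no cover - constraint/range mismatch
                raise ConfigError(
                    f"could not draw parameters satisfying the {model!r} "
                    "generation constraint")
            params = mod.params_from_fit_dict(draw)
        rec = simulate_participant(model, params, schedule, s_sim, participant_id=i)
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# Serialisation
# ---------------------------------------------------------------------------

def cohort_to_csv(records: Sequence[ParticipantRecord], path) -> None:
    """Write a cohort as tidy CSV, one row per (participant, trial).

    Missing ratings and missing outcomes are empty fields, never 0.
    """
    pd.concat([r.to_frame() for r in records], ignore_index=True).to_csv(
        path, index=False)


def cohort_from_csv(path) -> list[ParticipantRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"participant_id", "trial", "group", "outcome", "prediction", "se_rating"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigError(f"trial table missing columns: {sorted(missing)}")
    records = []
    for pid, sub in df.groupby("participant_id", sort=True):
        sub = sub.sort_values("trial")
        probe = [not pd.isna(r) for r in sub["se_rating"]]
        schedule = TaskSchedule(
            [int(g) for g in sub["group"]],
            [None if pd.isna(o) else int(o) for o in sub["outcome"]],
            probe,
            int(df["group"].max()),
        )
        ratings = [None if pd.isna(r) else float(r) for r in sub["se_rating"]]
        preds = [int(p) for p in sub["prediction"]]
        records.append(ParticipantRecord(schedule, preds, ratings,
                                         {"generating_model": "empirical"}, pid))
    return records


def design_from_yaml(path) -> GroupDesign:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: design YAML must be a mapping")
    try:
        return GroupDesign(**{k: tuple(v) if isinstance(v, list) else v
                              for k, v in raw.items()})
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def design_to_yaml(design: GroupDesign, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(design.to_dict(), fh, sort_keys=False)
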