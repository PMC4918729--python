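"""Probabilistic instrumental learning task: configuration and trial schedules.

The task presents pairs of abstract stimuli drawn from three conditions —
*gain* (win £1 / nothing), *loss* (lose £1 / nothing) and *neutral*
(look £1 / nothing, no monetary consequence).  Within each pair the two
stimuli carry reciprocal outcome probabilities ``(p, 1 - p)`` (default
``p = 0.8``).  A session comprises several runs, each introducing fresh
stimulus pairs, so learned values do not carry over between runs.

Schedules are *pre-realized*: the Bernoulli outcome draw of **both** options
is fixed at schedule time.  This makes simulated behaviour, likelihood
refitting and counterfactual analyses exactly reproducible from the seed.

By convention option ``A`` of every pair is the high-probability option
(probability ``p_high`` of producing its outcome); option ``B`` has
``1 - p_high``.  "Correct" choice therefore means ``A`` in the gain
condition and ``B`` (avoidance) in the loss condition.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONDITIONS = ("gain", "loss", "neutral")

#: canonical column order of a schedule frame
SCHEDULE_COLUMNS = [
    "run", "order", "pair_id", "condition", "trial",
    "side_A", "draw_A", "draw_B",
]


class ConfigError(ValueError):
    """Raised for an invalid task configuration."""


@dataclass(frozen=True)
class TaskConfig:
    """Structural parameters of the learning task.

    Parameters
    ----------
    n_runs : int
        Runs per session; each run uses new stimulus pairs (default 3).
    trials_per_pair : int
        Presentations of each pair within a run (default 30).
    p_high : float
        Outcome probability of the high-probability option; its partner
        gets ``1 - p_high``.  Must satisfy ``0.5 < p_high <= 1``.
    conditions : tuple of str
        Conditions run in each session, one pair per condition per run.
    outcome_magnitude : float
        Objective outcome size in currency units (default 1 = £1).
    """

    n_runs: int = 3
    trials_per_pair: int = 30
    p_high: float = 0.8
    conditions: tuple = CONDITIONS
    outcome_magnitude: float = 1.0

    def __post_init__(self):
        if not (0.5 < self.p_high <= 1.0):
            raise ConfigError(f"p_high must be in (0.5, 1], got {self.p_high}")
        if self.trials_per_pair < 1:
            raise ConfigError("trials_per_pair must be >= 1")
        if self.n_runs < 1:
            raise ConfigError("n_runs must be >= 1")
        conds = tuple(self.conditions)
        if len(conds) == 0 or any(c not in CONDITIONS for c in conds):
            raise ConfigError(
                f"conditions must be a nonempty subset of {CONDITIONS}, got {conds}"
            )
        if len(set(conds)) != len(conds):
            raise ConfigError("conditions must not repeat")
        object.__setattr__(self, "conditions", conds)

    @property
    def n_pairs_per_run(self) -> int:
        """One pair per condition per run."""
        return len(self.conditions)

    def to_dict(self) -> dict:
        return {
            "n_runs": self.n_runs,
            "trials_per_pair": self.trials_per_pair,
            "p_high": self.p_high,
            "conditions": list(self.conditions),
            "outcome_magnitude": self.outcome_magnitude,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TaskConfig":
        d = dict(d)
        if "conditions" in d:
            d["conditions"] = tuple(d["conditions"])
        return cls(**d)


@dataclass(frozen=True)
class StimulusPair:
    """One stimulus pair: two options with reciprocal outcome probabilities."""

    pair_id: str
    condition: str
    p_outcome_A: float

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ConfigError(f"unknown condition {self.condition!r}")
        if not (0.0 <= self.p_outcome_A <= 1.0):
            raise ConfigError("p_outcome_A must be a probability")

    @property
    def p_outcome_B(self) -> float:
        return 1.0 - self.p_outcome_A


def pairs_for_run(config: TaskConfig, run: int) -> list[StimulusPair]:
    """Stimulus pairs used in ``run`` (new identities each run)."""
    return [
        StimulusPair(pair_id=f"r{run}_{c}", condition=c, p_outcome_A=config.p_high)
        for c in config.conditions
    ]


def make_schedule(config: TaskConfig, seed: int) -> pd.DataFrame:
    """Generate a deterministic trial schedule for one session.

    Returns a frame with one row per trial in presentation order, columns
    :data:`SCHEDULE_COLUMNS`.  Per pair: exactly ``trials_per_pair`` rows,
    left/right placement of option A balanced to within one trial, and both
    options' outcome draws pre-realized as Bernoulli samples.
    """
    if not isinstance(config, TaskConfig):
        raise ConfigError("config must be a TaskConfig")
    rng = np.random.default_rng(seed)
    frames = []
    T = config.trials_per_pair
    for run in range(1, config.n_runs + 1):
        pairs = pairs_for_run(config, run)
        # randomized interleaving of pair presentations within the run
        deck = np.repeat(np.arange(len(pairs)), T)
        rng.shuffle(deck)
        counters = np.zeros(len(pairs), dtype=int)
        per_pair = {}
        for p in pairs:
            sides = np.array(["left", "right"]).repeat([T // 2, T - T // 2])
            rng.shuffle(sides)
            per_pair[p.pair_id] = {
                "sides": sides,
                "draw_A": (rng.random(T) < p.p_outcome_A).astype(int),
                "draw_B": (rng.random(T) < p.p_outcome_B).astype(int),
            }
        rows = {c: [] for c in SCHEDULE_COLUMNS}
        for order, k in enumerate(deck, start=1):
            p = pairs[k]
            i = counters[k]
            counters[k] += 1
            info = per_pair[p.pair_id]
            rows["run"].append(run)
            rows["order"].append(order)
            rows["pair_id"].append(p.pair_id)
            rows["condition"].append(p.condition)
            rows["trial"].append(i + 1)
            rows["side_A"].append(info["sides"][i])
            rows["draw_A"].append(info["draw_A"][i])
            rows["draw_B"].append(info["draw_B"][i])
        frames.append(pd.DataFrame(rows))
    return pd.concat(frames, ignore_index=True)


def outcome_value(condition: str, drew: int | bool, magnitude: float = 1.0) -> float:
    """Objective outcome of a choice whose option draw was ``drew``.

    Gain: ``+magnitude`` or 0; loss: ``-magnitude`` or 0; neutral: always 0
    (the "look" outcome has no monetary consequence).
    """
    if condition == "gain":
        return magnitude if drew else 0.0
    if condition == "loss":
        return -magnitude if drew else 0.0
    if condition == "neutral":
        return 0.0
    raise ConfigError(f"unknown condition {condition!r}")


def pair_outcome(pair: StimulusPair, chosen: str, schedule_row) -> float:
    """Objective outcome for choosing option ``chosen`` on a schedule row."""
    if chosen not in ("A", "B"):
        raise ValueError(f"chosen must be 'A' or 'B', got {chosen!r}")
    drew = schedule_row["draw_A"] if chosen == "A" else schedule_row["draw_B"]
    return outcome_value(pair.condition, drew)


def correct_choice(condition: str) -> str | None:
    """The objectively correct option: approach A in gain, avoid (B) in loss."""
    if condition == "gain":
        return "A"
    if condition == "loss":
        return "B"
    if condition == "neutral":
        return None
    raise ConfigError(f"unknown condition {condition!r}")
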