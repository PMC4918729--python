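"""Generative Rescorla-Wagner + softmax agent.

The agent learns action values for the two options of a stimulus pair by the
delta rule.  Expected values start at zero; after choosing option ``A`` and
receiving subjective outcome ``R(t)`` the chosen value is updated as

    Q_A(t+1) = Q_A(t) + alpha * delta(t),      delta(t) = R(t) - Q_A(t)

and choices follow the softmax (temperature convention: divide by beta)

    P_A = exp(Q_A / beta) / (exp(Q_A / beta) + exp(Q_B / beta)).

Subjective reinforcement on a trial is ``R`` when the chosen option's outcome
was drawn and 0 for a nil outcome; the behavioural log stores the objective
±1/0 outcome separately.  Larger ``beta`` means more random choice.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .task import TaskConfig, outcome_value

#: lower guard on the softmax temperature during simulation
BETA_FLOOR = 1e-3


class ParameterError(ValueError):
    """Raised for out-of-domain agent parameters."""


@dataclass(frozen=True)
class AgentParams:
    """Free parameters (alpha, beta, R) of one subject x treatment x valence cell.

    alpha : learning rate in [0, 1]
    beta  : softmax temperature, > 0 (divide-by-beta convention)
    r     : subjective outcome value, signed (positive for gain, negative
            for loss cells when the sign convention is active)
    """

    alpha: float
    beta: float
    r: float

    def __post_init__(self):
        if not (0.0 <= self.alpha <= 1.0):
            raise ParameterError(f"alpha must be in [0, 1], got {self.alpha}")
        if not (self.beta > 0.0):
            raise ParameterError(f"beta must be > 0, got {self.beta}")


@dataclass(frozen=True)
class ValueState:
    """Expected values of the two options; initialized at zero."""

    q_a: float = 0.0
    q_b: float = 0.0


def prediction_error(outcome_value: float, q_chosen: float) -> float:
    """delta = actual minus expected outcome."""
    return outcome_value - q_chosen


def update_value(state: ValueState, chosen: str, delta: float, alpha: float) -> ValueState:
    """Delta-rule update of the chosen option only."""
    if not (0.0 <= alpha <= 1.0):
        raise ParameterError(f"alpha must be in [0, 1], got {alpha}")
    if chosen == "A":
        return replace(state, q_a=state.q_a + alpha * delta)
    if chosen == "B":
        return replace(state, q_b=state.q_b + alpha * delta)
    raise ValueError(f"chosen must be 'A' or 'B', got {chosen!r}")


def choice_probability(state: ValueState, beta: float) -> float:
    """Softmax probability of choosing option A; numerically stable."""
    if not (beta > 0.0):
        raise ParameterError(f"beta must be > 0, got {beta}")
    d = (state.q_a - state.q_b) / beta
    # logistic of d without overflow for |d| up to ~1e4 and beyond
    if d >= 0:
        return 1.0 / (1.0 + math.exp(-d))
    e = math.exp(d)
    return e / (1.0 + e)


def simulate_pair(
    params: AgentParams,
    pair_rows: pd.DataFrame,
    rng: np.random.Generator,
    magnitude: float = 1.0,
) -> pd.DataFrame:
    """Forward-simulate one agent on one stimulus pair.

    ``pair_rows`` are the schedule rows of a single pair in presentation
    order.  Returns the rows augmented with ``choice``, ``go_flag``,
    ``outcome`` (objective), ``q_chosen`` (pre-choice value of the chosen
    option) and ``delta`` (subjective prediction error).
    """
    beta = max(params.beta, BETA_FLOOR)
    cond = pair_rows["condition"].iloc[0]
    n = len(pair_rows)
    side_a = pair_rows["side_A"].to_numpy()
    draw_a = pair_rows["draw_A"].to_numpy()
    draw_b = pair_rows["draw_B"].to_numpy()
    u = rng.random(n)

    choice = np.empty(n, dtype=object)
    go = np.zeros(n, dtype=int)
    outc = np.zeros(n)
    q_chosen = np.zeros(n)
    delta = np.zeros(n)

    qa = qb = 0.0
    for i in range(n):
        d = (qa - qb) / beta
        p_a = 1.0 / (1.0 + math.exp(-d)) if d >= 0 else math.exp(d) / (1.0 + math.exp(d))
        pick_a = u[i] < p_a
        drew = draw_a[i] if pick_a else draw_b[i]
        side = side_a[i] if pick_a else ("right" if side_a[i] == "left" else "left")
        choice[i] = "A" if pick_a else "B"
        go[i] = 1 if side == "right" else 0
        outc[i] = outcome_value(cond, drew, magnitude)
        # neutral outcomes carry no subjective reinforcement
        reinf = params.r * drew if cond != "neutral" else 0.0
        q = qa if pick_a else qb
        q_chosen[i] = q
        delta[i] = reinf - q
        if pick_a:
            qa += params.alpha * delta[i]
        else:
            qb += params.alpha * delta[i]

    out = pair_rows.copy()
    out["choice"] = choice
    out["go_flag"] = go
    out["outcome"] = outc
    out["q_chosen"] = q_chosen
    out["delta"] = delta
    return out


def simulate_session(
    params_by_condition: dict[str, AgentParams],
    schedule: pd.DataFrame,
    rng: np.random.Generator,
    magnitude: float = 1.0,
) -> pd.DataFrame:
    """Simulate a full session (all runs, all pairs) of one agent.

    ``params_by_condition`` maps condition name to the cell parameters; the
    neutral condition, if present and unparameterized, behaves as ``r = 0``
    (no learning signal, hence chance-level choice).
    """
    chunks = []
    for pair_id, rows in schedule.groupby("pair_id", sort=False):
        rows = rows.sort_values("order")
        cond = rows["condition"].iloc[0]
        params = params_by_condition.get(cond)
        if params is None:
            if cond != "neutral":
                raise ParameterError(f"no parameters supplied for condition {cond!r}")
            base = next(iter(params_by_condition.values()))
            params = AgentParams(alpha=base.alpha, beta=base.beta, r=0.0)
        chunks.append(simulate_pair(params, rows, rng, magnitude))
    out = pd.concat(chunks, ignore_index=True)
    return out.sort_values(["run", "order"], ignore_index=True)
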