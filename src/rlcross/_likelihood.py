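"""Hot inner loops of the choice likelihood (JIT-compiled when numba is present)."""
from __future__ import annotations

import math

import numpy as np

PROB_FLOOR = 1e-12

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


@njit(cache=True)
def nll_core(alpha, beta, r, choices, nonnil, pair_start):
    """-sum(log P(choice_t)) under the delta rule + softmax.

    choices: int8, 0 = option A, 1 = option B.
    nonnil: float64, 1.0 when the chosen option's outcome was drawn.
    pair_start: bool, True where Q values reset to zero (new pair).
    """
    nll = 0.0
    qa = 0.0
    qb = 0.0
    for i in range(choices.size):
        if pair_start[i]:
            qa = 0.0
            qb = 0.0
        # evaluate the chosen option's probability directly (no cancellation)
        if choices[i] == 0:
            d = (qa - qb) / beta
        else:
            d = (qb - qa) / beta
        if d >= 0.0:
            p = 1.0 / (1.0 + math.exp(-d))
        else:
            e = math.exp(d)
            p = e / (1.0 + e)
        if p < PROB_FLOOR:
            p = PROB_FLOOR
        nll -= math.log(p)
        out = r * nonnil[i]
        if choices[i] == 0:
            qa += alpha * (out - qa)
        else:
            qb += alpha * (out - qb)
    return nll


@njit(cache=True)
def series_core(alpha, beta, r, choices, nonnil, pair_start):
    """Per-trial (Q_chosen pre-update, delta) along an observed sequence."""
    n = choices.size
    q_chosen = np.empty(n)
    delta = np.empty(n)
    qa = 0.0
    qb = 0.0
    for i in range(n):
        if pair_start[i]:
            qa = 0.0
            qb = 0.0
        q = qa if choices[i] == 0 else qb
        out = r * nonnil[i]
        q_chosen[i] = q
        delta[i] = out - q
        if choices[i] == 0:
            qa += alpha * delta[i]
        else:
            qb += alpha * delta[i]
    return q_chosen, delta
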