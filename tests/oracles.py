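"""Independent reference implementations used only as test oracles.

Deliberately naive and written directly from the model definitions: pure
Python floats, no shared code with the package internals.
"""
from __future__ import annotations

import math


def bruteforce_nll(alpha, beta, r, choices, nonnil, pair_starts=None):
    """-log likelihood of a choice sequence by direct recursion.

    choices: sequence of 'A'/'B'; nonnil: 1 when the chosen option's outcome
    was drawn, 0 for nil.  Values start at zero; chosen value updates by
    alpha * (R * nonnil - Q); choice probability is the softmax with
    temperature beta evaluated at the pre-update values.
    """
    q = {"A": 0.0, "B": 0.0}
    total = 0.0
    for i, (c, nn) in enumerate(zip(choices, nonnil)):
        if pair_starts is not None and pair_starts[i]:
            q = {"A": 0.0, "B": 0.0}
        ea = math.exp(q["A"] / beta)
        eb = math.exp(q["B"] / beta)
        p = ea / (ea + eb) if c == "A" else eb / (ea + eb)
        total -= math.log(max(p, 1e-12))
        delta = r * nn - q[c]
        q[c] = q[c] + alpha * delta
    return total


def textbook_paired_t(x, y):
    """Paired t statistic and two-sided p from the textbook formulas."""
    import scipy.stats

    d = [a - b for a, b in zip(x, y)]
    n = len(d)
    mean = sum(d) / n
    var = sum((v - mean) ** 2 for v in d) / (n - 1)
    t = mean / math.sqrt(var / n)
    p = 2 * scipy.stats.t.sf(abs(t), n - 1)
    return t, p


def all_sequences(length):
    """Every (choices, nonnil) pair of a given trial count: 4^length items."""
    seqs = [([], [])]
    for _ in range(length):
        nxt = []
        for ch, nn in seqs:
            for c in ("A", "B"):
                for o in (0, 1):
                    nxt.append((ch + [c], nn + [o]))
        seqs = nxt
    return seqs
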