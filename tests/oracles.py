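"""Independent reference implementations used only by the tests.

These deliberately avoid the package's own code paths: the fight oracle is a
literal step-by-step trace of the rules, and the linearity oracle goes
through cyclic-triad counting rather than the variance-of-wins formula.
"""

import itertools
import math

import numpy as np


def zero_noise_fight(s_i, s_j, t_i, t_j, f_i=1e9, f_j=1e9,
                     max_rounds=100_000):
    """Deterministic (sigma = 0) fight trace.

    Returns (gives_up_i, gives_up_j, length).  Costs are paid every round;
    each decision variable moves by the true strength difference; giving up
    happens when d exceeds the threshold or fitness drops below zero, with
    both checked simultaneously at the end of the round.
    """
    c_i = math.exp(s_j - s_i)
    c_j = math.exp(s_i - s_j)
    d_i = d_j = 0.0
    for r in range(1, max_rounds + 1):
        f_i -= c_i
        f_j -= c_j
        d_i -= s_i - s_j
        d_j -= s_j - s_i
        give_i = f_i < 0 or d_i > t_i
        give_j = f_j < 0 or d_j > t_j
        if give_i or give_j:
            return give_i, give_j, r
    raise AssertionError("oracle fight did not terminate")


def landau_h_via_triads(dominates: np.ndarray) -> float:
    """Landau's index computed from the number of cyclic triads:
    h = 1 - 24 d / (N^3 - N)."""
    n = dominates.shape[0]
    d = 0
    for a, b, c in itertools.combinations(range(n), 3):
        if (dominates[a, b] and dominates[b, c] and dominates[c, a]) or \
                (dominates[b, a] and dominates[c, b] and dominates[a, c]):
            d += 1
    return 1.0 - 24.0 * d / (n**3 - n)


def all_tournaments(n: int):
    """Yield every complete dominance matrix on n individuals."""
    pairs = list(itertools.combinations(range(n), 2))
    for bits in itertools.product((0, 1), repeat=len(pairs)):
        dom = np.zeros((n, n), dtype=np.int64)
        for (a, b), bit in zip(pairs, bits):
            if bit:
                dom[a, b] = 1
            else:
                dom[b, a] = 1
        yield dom
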