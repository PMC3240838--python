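"""Array-based hot loop for the conflict phase of one generation.

The object layer (``conflicts``/``fights``) defines the behavioural rules in
readable form; this module repeats them over flat arrays so that the
generation loop runs at compiled speed.  Group state is struct-of-arrays:

    s, F, U, T : (n_groups, group_size) float64
    w          : (n_groups, group_size, group_size) float64, w[g, i, j] being
                 the willingness of i to escalate against j (diagonal unused)
    disabled   : (n_groups, group_size) bool

``conflict_phase`` mutates F, w and disabled in place and returns aggregate
fight statistics plus (optionally) the directed win tally over conflicts in
which at least one individual escalated.

Reproducibility: the caller passes one 32-bit seed per group; each group's
conflict phase reseeds numba's global Mersenne-Twister state, so per-group
streams are independent of group execution order.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["conflict_phase", "dyad_indices"]


def dyad_indices(group_size: int) -> tuple[np.ndarray, np.ndarray]:
    """Index arrays (i, j) with i < j for every unordered dyad."""
    i_idx, j_idx = np.triu_indices(group_size, k=1)
    return i_idx.astype(np.int64), j_idx.astype(np.int64)


@njit(cache=True, inline="always")
def _updated_w(w_cur: float, u: float, won: bool) -> float:
    if u == 0.0:
        return w_cur
    if won:
        w_new = w_cur + u * (1.0 - w_cur) if u > 0.0 else w_cur + u * w_cur
    else:
        w_new = w_cur - u * w_cur if u > 0.0 else w_cur - u * (1.0 - w_cur)
    return min(1.0, max(0.0, w_new))


@njit(cache=True)
def conflict_phase(s, F, U, T, w, disabled, benefit, sigma_eps,
                   n_conflict_rounds, max_fight_rounds, group_seeds,
                   dyad_i, dyad_j, collect_wins):
    n_groups, group_size = s.shape
    n_dyads = dyad_i.shape[0]

    wins = np.zeros((n_groups, group_size, group_size), dtype=np.int64)
    n_fights = 0
    fight_rounds_total = 0
    longest_fight = 0
    cap_breaches = 0

    for g in range(n_groups):
        np.random.seed(group_seeds[g])
        for _ in range(n_conflict_rounds):
            order = np.random.permutation(n_dyads)
            for k in order:
                i = dyad_i[k]
                j = dyad_j[k]
                esc_i = (not disabled[g, i]) and \
                    (np.random.random() < w[g, i, j])
                esc_j = (not disabled[g, j]) and \
                    (np.random.random() < w[g, j, i])

                if not esc_i and not esc_j:
                    # undecided: random holder, no costs, no learning
                    if np.random.random() < 0.5:
                        F[g, i] += benefit
                    else:
                        F[g, j] += benefit
                    continue

                if esc_i and esc_j:
                    # escalated fight: sequential assessment
                    c_i = math.exp(s[g, j] - s[g, i])
                    c_j = 1.0 / c_i
                    ds = s[g, i] - s[g, j]
                    d_i = 0.0
                    d_j = 0.0
                    give_i = False
                    give_j = False
                    forced_i = False
                    forced_j = False
                    length = 0
                    for _r in range(max_fight_rounds):
                        length += 1
                        F[g, i] -= c_i
                        F[g, j] -= c_j
                        d_i -= ds + sigma_eps * np.random.standard_normal()
                        d_j -= -ds + sigma_eps * np.random.standard_normal()
                        forced_i = F[g, i] < 0.0
                        forced_j = F[g, j] < 0.0
                        give_i = forced_i or d_i > T[g, i]
                        give_j = forced_j or d_j > T[g, j]
                        if give_i or give_j:
                            break
                    if not (give_i or give_j):
                        cap_breaches += 1
                        give_i = True
                        give_j = True
                    if give_i and give_j:
                        i_wins = np.random.random() < 0.5
                    else:
                        i_wins = give_j
                    if forced_i:
                        disabled[g, i] = True
                        for m in range(group_size):
                            w[g, i, m] = 0.0
                    if forced_j:
                        disabled[g, j] = True
                        for m in range(group_size):
                            w[g, j, m] = 0.0
                    n_fights += 1
                    fight_rounds_total += length
                    if length > longest_fight:
                        longest_fight = length
                else:
                    i_wins = esc_i

                if i_wins:
                    win, lose = i, j
                else:
                    win, lose = j, i
                F[g, win] += benefit
                # simultaneous update from pre-conflict w; disabled stay at 0
                if not disabled[g, win]:
                    w[g, win, lose] = _updated_w(w[g, win, lose], U[g, win],
                                                 True)
                if not disabled[g, lose]:
                    w[g, lose, win] = _updated_w(w[g, lose, win], U[g, lose],
                                                 False)
                if collect_wins:
                    wins[g, win, lose] += 1

    return n_fights, fight_rounds_total, longest_fight, cap_breaches, wins
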