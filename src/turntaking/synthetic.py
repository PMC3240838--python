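"""Synthetic dyadic interaction sequences with known structure.

Used to exercise the dominance metrics against patterns whose expected
statistics are known in closed form: strict alternation (turn-taking-like),
despotic fixed dominance along a transitive order, and unstructured random
outcomes.
"""

from __future__ import annotations

import numpy as np

from .metrics import DyadInteractionTally

__all__ = ["interaction_sequence", "group_tally"]

PATTERNS = ("alternating", "despotic", "random")


def interaction_sequence(pattern: str, n_interactions: int,
                         rng: np.random.Generator,
                         ids: tuple[int, int] = (0, 1)
                         ) -> list[tuple[int, int]]:
    """A (winner, loser) sequence for one dyad.

    ``alternating``: the winner strictly alternates, random first winner.
    ``despotic``: one randomly chosen individual wins every interaction.
    ``random``: every interaction is a fair coin flip.
    """
    a, b = ids
    if pattern == "alternating":
        first = a if rng.random() < 0.5 else b
        second = b if first == a else a
        seq = [(first, second), (second, first)] * (n_interactions // 2 + 1)
        return seq[:n_interactions]
    if pattern == "despotic":
        dom, sub = (a, b) if rng.random() < 0.5 else (b, a)
        return [(dom, sub)] * n_interactions
    if pattern == "random":
        return [((a, b) if rng.random() < 0.5 else (b, a))
                for _ in range(n_interactions)]
    raise ValueError(f"unknown pattern {pattern!r}; choose from {PATTERNS}")


def group_tally(pattern: str, n_individuals: int, interactions_per_dyad: int,
                rng: np.random.Generator) -> DyadInteractionTally:
    """A full-group tally in which every dyad follows the given pattern.

    For ``despotic`` the dominance directions follow one global transitive
    order (a random permutation of the group), so the resulting hierarchy is
    perfectly linear.
    """
    tally = DyadInteractionTally(range(n_individuals))
    order = rng.permutation(n_individuals)
    rank = {int(ident): r for r, ident in enumerate(order)}
    for i in range(n_individuals):
        for j in range(i + 1, n_individuals):
            if pattern == "despotic":
                dom, sub = (i, j) if rank[i] < rank[j] else (j, i)
                tally.record(dom, sub, count=interactions_per_dyad)
            else:
                for winner, loser in interaction_sequence(
                        pattern, interactions_per_dyad, rng, ids=(i, j)):
                    tally.record(winner, loser)
    return tally
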