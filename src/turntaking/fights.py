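"""Single escalated fight: sequential assessment with noisy perception.

A fight proceeds in discrete rounds.  Each round, every fighter (1) pays a
cost that depends on relative strength, (2) draws a noisy estimate of the
strength difference, which is subtracted from its personal decision variable
``d`` (evidence of being weaker, reset to zero at the start of every fight),
and (3) decides simultaneously with its opponent whether to give up.  An
individual concedes once ``d`` exceeds its giving-up threshold ``T``, or is
forced to concede in the round its fitness drops below zero — in which case
it also stops escalating for the rest of its life.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .core import Individual

__all__ = [
    "FightResult",
    "round_cost",
    "perceive_relative_strength",
    "run_fight",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FightResult:
    """Outcome of one escalated fight between individuals *i* and *j*."""

    winner: int
    loser: int
    length: int
    cost_i: float
    cost_j: float
    forced_giveup_i: bool = False
    forced_giveup_j: bool = False
    double_giveup: bool = False


def round_cost(s_i: float, s_j: float) -> float:
    """Per-round fitness cost to an individual of strength ``s_i`` fighting
    an opponent of strength ``s_j``: ``exp(s_j - s_i)``.

    The weaker individual pays more than 1 per round, the stronger less than
    1, and equally matched opponents both pay exactly 1.
    """
    return math.exp(s_j - s_i)


def perceive_relative_strength(s_i: float, s_j: float, sigma_eps: float,
                               rng: np.random.Generator) -> float:
    """One noisy estimate of the strength difference ``s_i - s_j``.

    The observation error is drawn fresh for each individual in each fighting
    round from Normal(0, sigma_eps).
    """
    return s_i - s_j + rng.normal(0.0, sigma_eps)


def run_fight(ind_i: Individual, ind_j: Individual, sigma_eps: float,
              rng: np.random.Generator,
              max_fight_rounds: int = 10_000,
              trace: list | None = None) -> FightResult:
    """Fight until at least one side gives up; mutates both fitness values.

    Each round both fighters pay :func:`round_cost` (including the final
    round), subtract their own perceived strength difference from their
    decision variable, and then decide simultaneously.  Giving up happens
    when ``d > T`` or when fitness has dropped below zero (forced give-up,
    which additionally disables all future escalation for that individual).
    A simultaneous double give-up is resolved by a fair coin.

    If ``trace`` is a list, a ``(round, d_i, d_j, F_i, F_j)`` tuple is
    appended per round for diagnostics.
    """
    d_i = 0.0
    d_j = 0.0
    c_i = round_cost(ind_i.strength, ind_j.strength)
    c_j = round_cost(ind_j.strength, ind_i.strength)
    forced_i = forced_j = False
    length = 0
    give_i = give_j = False

    for r in range(1, max_fight_rounds + 1):
        length = r
        ind_i.fitness -= c_i
        ind_j.fitness -= c_j
        d_i -= perceive_relative_strength(ind_i.strength, ind_j.strength,
                                          sigma_eps, rng)
        d_j -= perceive_relative_strength(ind_j.strength, ind_i.strength,
                                          sigma_eps, rng)
        if trace is not None:
            trace.append((r, d_i, d_j, ind_i.fitness, ind_j.fitness))
        forced_i = ind_i.fitness < 0.0
        forced_j = ind_j.fitness < 0.0
        give_i = forced_i or d_i > ind_i.giving_up_threshold
        give_j = forced_j or d_j > ind_j.giving_up_threshold
        if give_i or give_j:
            break
    else:  # pragma: no cover - unreachable under realistic parameters
        pass

    if not (give_i or give_j):
        logger.warning(
            "fight hit max_fight_rounds=%d (s_i=%.3f s_j=%.3f sigma=%.3f); "
            "choosing winner at random", max_fight_rounds, ind_i.strength,
            ind_j.strength, sigma_eps)
        give_i = give_j = True

    double = give_i and give_j
    if double:
        i_wins = rng.random() < 0.5
    else:
        i_wins = give_j

    if forced_i:
        ind_i.disable_escalation()
    if forced_j:
        ind_j.disable_escalation()

    return FightResult(
        winner=ind_i.id if i_wins else ind_j.id,
        loser=ind_j.id if i_wins else ind_i.id,
        length=length,
        cost_i=length * c_i,
        cost_j=length * c_j,
        forced_giveup_i=forced_i,
        forced_giveup_j=forced_j,
        double_giveup=double,
    )
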