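"""One dyadic conflict: escalation decisions, outcome resolution and the
experience-driven update of the willingness to escalate.

Both individuals decide simultaneously (each with its dyad-specific
probability ``w``) whether to escalate.  Neither willing: a random individual
takes the resource and nothing is learned.  Exactly one willing: it takes the
resource uncontested.  Both willing: an escalated fight decides the winner.
Whenever at least one individual was willing to escalate, both update their
willingness toward the opponent from the win/lose outcome, using their own
heritable update factor ``U``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Individual
from .fights import FightResult, run_fight

__all__ = [
    "ConflictOutcome",
    "decide_escalation",
    "update_willingness",
    "run_conflict",
    "outcomes_to_records",
]


@dataclass(frozen=True)
class ConflictOutcome:
    """What happened in one conflict of the dyad (id_i, id_j)."""

    id_i: int
    id_j: int
    escalated_i: bool
    escalated_j: bool
    winner: int
    fight_result: FightResult | None = None
    update_applied: bool = False

    @property
    def fought(self) -> bool:
        return self.fight_result is not None


def outcomes_to_records(outcomes, group: int = 0) -> list[dict]:
    """Flatten conflict outcomes into event-log rows (the schema consumed by
    the ``metrics`` CLI command): group, winner, loser, escalated flag and
    fight length where a fight occurred."""
    records = []
    for o in outcomes:
        records.append({
            "group": group,
            "id_i": o.id_i,
            "id_j": o.id_j,
            "winner": o.winner,
            "loser": o.id_j if o.winner == o.id_i else o.id_i,
            "escalated": int(o.update_applied),
            "fight_length": (o.fight_result.length
                             if o.fight_result is not None else None),
        })
    return records


def decide_escalation(w_value: float, escalation_disabled: bool,
                      rng: np.random.Generator) -> bool:
    """Bernoulli(w) escalation decision; always False once disabled."""
    if escalation_disabled:
        return False
    return rng.random() < w_value


def update_willingness(w_cur: float, update_factor: float, *,
                       won: bool) -> float:
    """Move the willingness to escalate after a decided conflict.

    Winners with positive U move toward 1 (``w + U(1-w)``), with negative U
    toward 0 (``w + U*w``); losers move the opposite way (``w - U*w`` and
    ``w - U(1-w)`` respectively).  U = 0 leaves w unchanged.  The result
    always stays in [0, 1].
    """
    u = update_factor
    if u == 0.0:
        return w_cur
    if won:
        w_new = w_cur + u * (1.0 - w_cur) if u > 0.0 else w_cur + u * w_cur
    else:
        w_new = w_cur - u * w_cur if u > 0.0 else w_cur - u * (1.0 - w_cur)
    # clip against floating-point drift only; algebraically already in range
    return min(1.0, max(0.0, w_new))


def _apply_updates(winner: Individual, loser: Individual) -> None:
    # both updates read the pre-conflict w values (simultaneous update);
    # disabled individuals keep w pinned at zero
    if not winner.escalation_disabled:
        winner.willingness[loser.id] = update_willingness(
            winner.willingness[loser.id], winner.update_factor, won=True)
    if not loser.escalation_disabled:
        loser.willingness[winner.id] = update_willingness(
            loser.willingness[winner.id], loser.update_factor, won=False)


def run_conflict(ind_i: Individual, ind_j: Individual, benefit: float,
                 sigma_eps: float, rng: np.random.Generator,
                 max_fight_rounds: int = 10_000) -> ConflictOutcome:
    """Run one conflict over a resource of value ``benefit``.

    Mutates fitness (benefit to the resource holder, fight costs to both
    fighters) and, when at least one individual escalated, the willingness
    values of both individuals.
    """
    esc_i = decide_escalation(ind_i.willingness[ind_j.id],
                              ind_i.escalation_disabled, rng)
    esc_j = decide_escalation(ind_j.willingness[ind_i.id],
                              ind_j.escalation_disabled, rng)

    fight_result = None
    if not esc_i and not esc_j:
        # undecided conflict: random resource holder, nothing is learned
        holder = ind_i if rng.random() < 0.5 else ind_j
        holder.fitness += benefit
        return ConflictOutcome(ind_i.id, ind_j.id, esc_i, esc_j,
                               winner=holder.id)
    if esc_i and esc_j:
        fight_result = run_fight(ind_i, ind_j, sigma_eps, rng,
                                 max_fight_rounds)
        winner = ind_i if fight_result.winner == ind_i.id else ind_j
    else:
        winner = ind_i if esc_i else ind_j
    loser = ind_j if winner is ind_i else ind_i
    winner.fitness += benefit
    _apply_updates(winner, loser)
    return ConflictOutcome(ind_i.id, ind_j.id, esc_i, esc_j,
                           winner=winner.id, fight_result=fight_result,
                           update_applied=True)
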