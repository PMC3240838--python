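"""Relationship and hierarchy statistics computed from conflict outcomes.

All dominance statistics are computed from the directed win tally over
*qualifying* conflicts — those in which at least one individual was willing
to escalate.  Undecided conflicts (random resource allocation with no
escalation) carry no relationship information and are excluded.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DyadInteractionTally",
    "directional_consistency",
    "linearity",
    "fight_length_stats",
    "classify_strategy",
    "landau_h",
]


class DyadInteractionTally:
    """Directed win counts per ordered pair over qualifying conflicts.

    ``matrix[a, b]`` counts conflicts in which individual ``ids[a]`` obtained
    the resource against ``ids[b]`` while at least one of the two had
    escalated.
    """

    def __init__(self, ids: Sequence[int]):
        self.ids = list(ids)
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate individual ids")
        self._index = {ident: k for k, ident in enumerate(self.ids)}
        self.matrix = np.zeros((len(self.ids), len(self.ids)), dtype=np.int64)

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def total(self) -> int:
        return int(self.matrix.sum())

    def record(self, winner: int, loser: int, count: int = 1) -> None:
        self.matrix[self._index[winner], self._index[loser]] += count

    @classmethod
    def from_matrix(cls, matrix: np.ndarray,
                    ids: Sequence[int] | None = None
                    ) -> "DyadInteractionTally":
        matrix = np.asarray(matrix)
        if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
            raise ValueError("tally matrix must be square")
        tally = cls(ids if ids is not None else range(matrix.shape[0]))
        tally.matrix = matrix.astype(np.int64).copy()
        return tally

    @classmethod
    def from_outcomes(cls, outcomes: Iterable,
                      ids: Sequence[int] | None = None
                      ) -> "DyadInteractionTally":
        """Build a tally from :class:`~turntaking.conflicts.ConflictOutcome`
        records, keeping only conflicts where an update was applied (i.e. at
        least one individual escalated)."""
        outcomes = list(outcomes)
        if ids is None:
            seen: dict[int, None] = {}
            for o in outcomes:
                seen.setdefault(o.id_i)
                seen.setdefault(o.id_j)
            ids = list(seen)
        tally = cls(ids)
        for o in outcomes:
            if o.update_applied:
                loser = o.id_j if o.winner == o.id_i else o.id_i
                tally.record(o.winner, loser)
        return tally

    def dyad_splits(self) -> list[tuple[int, int]]:
        """(high, low) win counts per unordered dyad with >=1 interaction."""
        m = self.matrix
        splits = []
        for a in range(self.n):
            for b in range(a + 1, self.n):
                hi, lo = max(m[a, b], m[b, a]), min(m[a, b], m[b, a])
                if hi + lo > 0:
                    splits.append((int(hi), int(lo)))
        return splits


def directional_consistency(tally: DyadInteractionTally,
                            pooled: bool = True) -> float:
    """Directional consistency index of a group's dyadic relationships.

    Per dyad, with H interactions won in the more frequent direction and L in
    the other, the dyadic index is (H - L) / (H + L).  The group value pools
    counts across dyads, sum(H - L) / sum(H + L); ``pooled=False`` returns
    the unweighted mean of the dyadic indices instead.  Dyads without any
    qualifying interaction are excluded; with no qualifying dyad at all the
    index is undefined and NaN is returned.
    """
    splits = tally.dyad_splits()
    if not splits:
        return float("nan")
    if pooled:
        hi = sum(h for h, _ in splits)
        lo = sum(l for _, l in splits)
        return (hi - lo) / (hi + lo)
    return float(np.mean([(h - l) / (h + l) for h, l in splits]))


def landau_h(dominates: np.ndarray) -> float:
    """Landau's linearity index of a complete dominance tournament.

    ``dominates[a, b]`` is 1 if a dominates b.  With V_a the number of
    group-mates a dominates, h = 12 / (N^3 - N) * sum_a (V_a - (N-1)/2)^2;
    h = 1 for a transitive order, 0 for maximally circular relations.
    """
    dominates = np.asarray(dominates)
    n = dominates.shape[0]
    v = dominates.sum(axis=1)
    return float(12.0 / (n**3 - n) * np.sum((v - (n - 1) / 2.0) ** 2))


def linearity(tally: DyadInteractionTally, n_randomizations: int = 2000,
              rng: np.random.Generator | None = None) -> float:
    """Linearity of the dominance hierarchy implied by a win tally.

    The dominance relation of each dyad is the majority win direction.
    Dyads that are tied or unobserved are resolved uniformly at random, the
    Landau index is computed on each completed tournament, and the mean over
    ``n_randomizations`` repeats is returned (randomization treatment of
    unknown relationships).  Undefined (NaN) for groups of fewer than three.
    """
    n = tally.n
    if n < 3:
        return float("nan")
    m = tally.matrix
    a_idx, b_idx = np.triu_indices(n, k=1)
    wins_ab = m[a_idx, b_idx]
    wins_ba = m[b_idx, a_idx]

    dominates = np.zeros((n, n), dtype=np.int64)
    dominates[a_idx[wins_ab > wins_ba], b_idx[wins_ab > wins_ba]] = 1
    dominates[b_idx[wins_ba > wins_ab], a_idx[wins_ba > wins_ab]] = 1
    unknown = wins_ab == wins_ba

    if not unknown.any():
        return landau_h(dominates)

    if rng is None:
        rng = np.random.default_rng()
    v_base = dominates.sum(axis=1).astype(np.float64)
    ua, ub = a_idx[unknown], b_idx[unknown]
    coins = rng.random((n_randomizations, ua.size)) < 0.5
    # each unknown dyad adds one dominance either to a or to b
    onehot_a = np.zeros((ua.size, n))
    onehot_a[np.arange(ua.size), ua] = 1.0
    onehot_b = np.zeros((ub.size, n))
    onehot_b[np.arange(ub.size), ub] = 1.0
    v = v_base + coins @ onehot_a + (~coins) @ onehot_b
    h = 12.0 / (n**3 - n) * np.sum((v - (n - 1) / 2.0) ** 2, axis=1)
    return float(h.mean())


def fight_length_stats(source: Iterable) -> dict[str, float]:
    """Summary statistics (count, mean, median, max) of fight lengths.

    ``source`` is either an iterable of conflict outcomes (fights extracted
    from records with a fight result) or an iterable of lengths.  Returns an
    empty dict when no fights occurred.
    """
    lengths = []
    for item in source:
        if hasattr(item, "fight_result"):
            if item.fight_result is not None:
                lengths.append(item.fight_result.length)
        else:
            lengths.append(int(item))
    if not lengths:
        return {}
    arr = np.asarray(lengths, dtype=np.float64)
    return {
        "count": int(arr.size),
        "mean": float(arr.mean()),
        "median": float(np.median(arr)),
        "max": float(arr.max()),
    }


def classify_strategy(u_values: Iterable[float],
                      turn_taking_max: float = -0.5,
                      contest_min: float = 0.1) -> str:
    """Label an evolved population by its mean update factor.

    Strongly negative mean U is the turn-taking regime, positive mean U the
    contest regime; anything between the (configurable) thresholds is
    ``ambiguous``.
    """
    u = np.asarray(list(u_values), dtype=np.float64)
    if u.size == 0:
        raise ValueError("cannot classify an empty set of update factors")
    mean_u = float(u.mean())
    if mean_u <= turn_taking_max:
        return "turn_taking"
    if mean_u >= contest_min:
        return "contest"
    return "ambiguous"
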