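"""Generational loop: conflict rounds, fitness-proportional reproduction with
mutation, death of parents and migration of offspring.

Two interchangeable engines drive :func:`run_simulation`:

``"array"`` (default)
    Struct-of-arrays state advanced by the compiled kernel in
    :mod:`turntaking._kernel`; fast enough for the evolutionary experiments.

``"object"``
    Direct composition of the per-individual operations in
    :mod:`turntaking.conflicts` / :mod:`turntaking.fights`; transparent and
    convenient for small-scale inspection and cross-validation.

Each engine is deterministic given the config (including the seed); the two
engines consume randomness differently and therefore agree statistically,
not bitwise.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .conflicts import ConflictOutcome, run_conflict
from .core import Individual, Population, SimulationConfig, init_population, \
    validate_config
from .metrics import DyadInteractionTally, classify_strategy, \
    directional_consistency, linearity

__all__ = [
    "GenerationSummary",
    "SimulationResult",
    "run_conflict_round",
    "select_parent",
    "make_offspring",
    "reproduce_and_migrate",
    "run_simulation",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GenerationSummary:
    """Population-level aggregates for one generation (conflict phase)."""

    generation: int
    mean_update_factor: float
    mean_giving_up_threshold: float
    mean_fitness: float
    n_fights: int
    mean_fight_length: float
    max_fight_length: int
    dci: float = float("nan")
    linearity: float = float("nan")
    strategy: str = ""


@dataclass
class SimulationResult:
    """End state of a run: per-generation summaries plus the final
    generation's individuals and dominance tallies."""

    config: SimulationConfig
    summaries: list[GenerationSummary]
    strength: np.ndarray          # (n_groups, group_size)
    fitness: np.ndarray
    update_factor: np.ndarray
    giving_up_threshold: np.ndarray
    win_tally: np.ndarray         # (n_groups, group_size, group_size)
    group_dci: np.ndarray = field(default=None)        # type: ignore
    group_linearity: np.ndarray = field(default=None)  # type: ignore

    @property
    def strategy(self) -> str:
        return classify_strategy(self.update_factor.ravel())

    def summaries_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.summaries])

    def individuals_frame(self) -> pd.DataFrame:
        g, n = self.strength.shape
        return pd.DataFrame({
            "group": np.repeat(np.arange(g), n),
            "id": np.tile(np.arange(n), g),
            "strength": self.strength.ravel(),
            "fitness": self.fitness.ravel(),
            "update_factor": self.update_factor.ravel(),
            "giving_up_threshold": self.giving_up_threshold.ravel(),
        })


# ---------------------------------------------------------------------------
# object-level operations
# ---------------------------------------------------------------------------

def run_conflict_round(group: list[Individual], benefit: float,
                       sigma_eps: float, rng: np.random.Generator,
                       max_fight_rounds: int = 10_000
                       ) -> list[ConflictOutcome]:
    """One conflict round: every unordered dyad enters exactly one conflict,
    in an order randomized anew each round."""
    dyads = list(itertools.combinations(range(len(group)), 2))
    outcomes = []
    for k in rng.permutation(len(dyads)):
        i, j = dyads[k]
        outcomes.append(run_conflict(group[i], group[j], benefit, sigma_eps,
                                     rng, max_fight_rounds))
    return outcomes


def select_parent(group: list[Individual],
                  rng: np.random.Generator) -> Individual:
    """Sample one parent with probability proportional to fitness, negative
    fitness values clamped to zero first.  All-zero fitness falls back to a
    uniform draw."""
    weights = np.array([max(ind.fitness, 0.0) for ind in group])
    total = weights.sum()
    if total <= 0.0:
        logger.warning("all clamped fitness zero; selecting parent uniformly")
        return group[rng.integers(len(group))]
    return group[rng.choice(len(group), p=weights / total)]


def make_offspring(parent: Individual, config: SimulationConfig,
                   rng: np.random.Generator, ident: int = 0) -> Individual:
    """One offspring: inherits (U, T) subject to joint mutation; fresh
    strength ~ Uniform(0, 1), fitness F0, willingness filled in at group
    placement."""
    u, t = parent.update_factor, parent.giving_up_threshold
    if rng.random() < config.mutation_prob:
        u = float(rng.uniform(*config.u_mut_range))
        t = float(rng.uniform(*config.t_mut_range))
    return Individual(
        id=ident,
        strength=float(rng.uniform(0.0, 1.0)),
        fitness=config.initial_fitness,
        update_factor=u,
        giving_up_threshold=t,
    )


def reproduce_and_migrate(population: Population, config: SimulationConfig,
                          rng: np.random.Generator) -> Population:
    """Produce the next generation: per group, ``group_size`` reproduction
    events with selection inside the natal group; parents die; offspring are
    pooled and randomly permuted into equal-size groups."""
    offspring: list[Individual] = []
    for group in population.groups:
        for _ in range(len(group)):
            offspring.append(make_offspring(select_parent(group, rng),
                                            config, rng))
    order = rng.permutation(len(offspring))
    size = config.group_size
    groups = []
    for start in range(0, len(offspring), size):
        members = [offspring[k] for k in order[start:start + size]]
        for ident, ind in enumerate(members):
            ind.id = ident
            ind.willingness = {j: 1.0 for j in range(size) if j != ident}
        groups.append(members)
    return Population(groups=groups, generation=population.generation + 1)


# ---------------------------------------------------------------------------
# engines
# ---------------------------------------------------------------------------

def _group_metrics(win_tally: np.ndarray, n_randomizations: int,
                   rng: np.random.Generator
                   ) -> tuple[np.ndarray, np.ndarray]:
    n_groups = win_tally.shape[0]
    dci = np.full(n_groups, np.nan)
    lin = np.full(n_groups, np.nan)
    for g in range(n_groups):
        tally = DyadInteractionTally.from_matrix(win_tally[g])
        dci[g] = directional_consistency(tally)
        lin[g] = linearity(tally, n_randomizations, rng)
    return dci, lin


def _summary(generation, u, t, f, n_fights, rounds_total, longest,
             dci=float("nan"), lin=float("nan"), strategy=""):
    return GenerationSummary(
        generation=generation,
        mean_update_factor=float(np.mean(u)),
        mean_giving_up_threshold=float(np.mean(t)),
        mean_fitness=float(np.mean(f)),
        n_fights=int(n_fights),
        mean_fight_length=(rounds_total / n_fights if n_fights else
                           float("nan")),
        max_fight_length=int(longest),
        dci=dci,
        linearity=lin,
        strategy=strategy,
    )


def _run_array(config: SimulationConfig) -> SimulationResult:
    from ._kernel import conflict_phase, dyad_indices

    g_n, n = config.n_groups, config.group_size
    ss = np.random.SeedSequence(config.seed)
    rng_init, rng_seeds, rng_repro, rng_metrics = (
        np.random.default_rng(c) for c in ss.spawn(4))

    s = rng_init.random((g_n, n))
    fit = np.full((g_n, n), config.initial_fitness)
    u = np.full((g_n, n), config.u_init)
    t = np.full((g_n, n), config.t_init)
    w = np.ones((g_n, n, n))
    disabled = np.zeros((g_n, n), dtype=np.bool_)
    di, dj = dyad_indices(n)

    summaries: list[GenerationSummary] = []
    win_tally = np.zeros((g_n, n, n), dtype=np.int64)
    group_dci = np.full(g_n, np.nan)
    group_lin = np.full(g_n, np.nan)

    for gen in range(config.n_generations):
        final = gen == config.n_generations - 1
        seeds = rng_seeds.integers(0, 2**31, size=g_n)
        n_fights, rounds_total, longest, breaches, wins = conflict_phase(
            s, fit, u, t, w, disabled, config.benefit, config.sigma_eps,
            config.n_conflict_rounds, config.max_fight_rounds, seeds,
            di, dj, final)
        if breaches:
            logger.warning("generation %d: %d fights hit max_fight_rounds=%d",
                           gen, breaches, config.max_fight_rounds)
        if final:
            win_tally = wins
            group_dci, group_lin = _group_metrics(
                wins, config.n_linearity_randomizations, rng_metrics)
            summaries.append(_summary(
                gen, u, t, fit, n_fights, rounds_total, longest,
                dci=float(np.nanmean(group_dci)),
                lin=float(np.nanmean(group_lin)),
                strategy=classify_strategy(u.ravel())))
            break
        summaries.append(_summary(gen, u, t, fit, n_fights, rounds_total,
                                  longest))

        # reproduction: fitness-proportional selection within the natal
        # group, joint mutation of (U, T), then global migration
        f_clamped = np.clip(fit, 0.0, None)
        totals = f_clamped.sum(axis=1, keepdims=True)
        probs = np.where(totals > 0, f_clamped / np.where(totals == 0, 1.0,
                                                          totals), 1.0 / n)
        cum = np.cumsum(probs, axis=1)
        draws = rng_repro.random((g_n, n))
        parent = (cum[:, None, :] < draws[:, :, None]).sum(axis=2)
        rows = np.arange(g_n)[:, None]
        u_next = u[rows, parent]
        t_next = t[rows, parent]
        mutate = rng_repro.random((g_n, n)) < config.mutation_prob
        n_mut = int(mutate.sum())
        if n_mut:
            u_next[mutate] = rng_repro.uniform(*config.u_mut_range, n_mut)
            t_next[mutate] = rng_repro.uniform(*config.t_mut_range, n_mut)
        perm = rng_repro.permutation(g_n * n)
        u = u_next.ravel()[perm].reshape(g_n, n)
        t = t_next.ravel()[perm].reshape(g_n, n)
        s = rng_repro.random((g_n, n))
        fit = np.full((g_n, n), config.initial_fitness)
        w = np.ones((g_n, n, n))
        disabled = np.zeros((g_n, n), dtype=np.bool_)

    return SimulationResult(config=config, summaries=summaries, strength=s,
                            fitness=fit, update_factor=u,
                            giving_up_threshold=t, win_tally=win_tally,
                            group_dci=group_dci, group_linearity=group_lin)


def _run_object(config: SimulationConfig) -> SimulationResult:
    ss = np.random.SeedSequence(config.seed)
    rng_init, rng_conflict, rng_repro, rng_metrics = (
        np.random.default_rng(c) for c in ss.spawn(4))
    pop = init_population(config, rng_init)

    summaries: list[GenerationSummary] = []
    g_n, n = config.n_groups, config.group_size
    win_tally = np.zeros((g_n, n, n), dtype=np.int64)
    group_dci = np.full(g_n, np.nan)
    group_lin = np.full(g_n, np.nan)

    for gen in range(config.n_generations):
        final = gen == config.n_generations - 1
        lengths: list[int] = []
        for g, group in enumerate(pop.groups):
            for _ in range(config.n_conflict_rounds):
                outcomes = run_conflict_round(group, config.benefit,
                                              config.sigma_eps, rng_conflict,
                                              config.max_fight_rounds)
                for o in outcomes:
                    if o.fight_result is not None:
                        lengths.append(o.fight_result.length)
                    if final and o.update_applied:
                        loser = o.id_j if o.winner == o.id_i else o.id_i
                        win_tally[g, o.winner, loser] += 1
        u = [ind.update_factor for ind in pop.individuals()]
        t = [ind.giving_up_threshold for ind in pop.individuals()]
        f = [ind.fitness for ind in pop.individuals()]
        if final:
            group_dci, group_lin = _group_metrics(
                win_tally, config.n_linearity_randomizations, rng_metrics)
            summaries.append(_summary(
                gen, u, t, f, len(lengths), sum(lengths),
                max(lengths, default=0),
                dci=float(np.nanmean(group_dci)),
                lin=float(np.nanmean(group_lin)),
                strategy=classify_strategy(u)))
            break
        summaries.append(_summary(gen, u, t, f, len(lengths), sum(lengths),
                                  max(lengths, default=0)))
        pop = reproduce_and_migrate(pop, config, rng_repro)

    shape = (g_n, n)
    result = SimulationResult(
        config=config, summaries=summaries,
        strength=np.reshape([i.strength for i in pop.individuals()], shape),
        fitness=np.reshape([i.fitness for i in pop.individuals()], shape),
        update_factor=np.reshape(
            [i.update_factor for i in pop.individuals()], shape),
        giving_up_threshold=np.reshape(
            [i.giving_up_threshold for i in pop.individuals()], shape),
        win_tally=win_tally, group_dci=group_dci, group_linearity=group_lin)
    return result


def run_simulation(config: SimulationConfig,
                   engine: str = "array") -> SimulationResult:
    """Run the full nested dynamics for ``config.n_generations``.

    Each generation: ``n_conflict_rounds`` conflict rounds in every group,
    then (except after the final generation, whose population is recorded)
    reproduction, death of parents and migration of offspring.  Dominance
    metrics (DCI, linearity) are computed from the final generation's
    qualifying conflicts.
    """
    validate_config(config)
    if config.n_generations == 0:
        ss = np.random.SeedSequence(config.seed)
        rng_init = np.random.default_rng(ss.spawn(4)[0])
        g_n, n = config.n_groups, config.group_size
        return SimulationResult(
            config=config, summaries=[],
            strength=rng_init.random((g_n, n)),
            fitness=np.full((g_n, n), config.initial_fitness),
            update_factor=np.full((g_n, n), config.u_init),
            giving_up_threshold=np.full((g_n, n), config.t_init),
            win_tally=np.zeros((g_n, n, n), dtype=np.int64),
            group_dci=np.full(g_n, np.nan),
            group_linearity=np.full(g_n, np.nan))
    if engine == "array":
        return _run_array(config)
    if engine == "object":
        return _run_object(config)
    raise ValueError(f"unknown engine {engine!r}; use 'array' or 'object'")
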