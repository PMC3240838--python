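"""Experiment designs: the benefit x initial-U sweep, strategy-competition
experiments at fixed strategy frequencies, and the sensitivity sweeps over
perception noise, conflict rounds and group size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import SimulationConfig
from .evolution import SimulationResult, run_simulation

__all__ = [
    "StrategyProfile",
    "CompetitionResult",
    "main_sweep",
    "competition_experiment",
    "competition_curve",
    "sensitivity_sweep",
    "derive_strategy_profiles",
    "max_turn_taking_benefit",
]

SENSITIVITY_AXES = ("sigma_eps", "n_conflict_rounds", "group_size")


@dataclass(frozen=True)
class StrategyProfile:
    """A fixed (U, T) strategy used to seed competition experiments."""

    label: str
    update_factor: float
    giving_up_threshold: float

    def __post_init__(self):
        if not -1.0 <= self.update_factor <= 1.0:
            raise ValueError(f"update_factor out of [-1, 1]: "
                             f"{self.update_factor}")
        if not 0.0 <= self.giving_up_threshold <= 5.0:
            raise ValueError(f"giving_up_threshold out of [0, 5]: "
                             f"{self.giving_up_threshold}")


@dataclass(frozen=True)
class CompetitionResult:
    """Mean fitness per strategy after one generation of conflicts in groups
    seeded with ``k_a`` strategy-A and ``group_size - k_a`` strategy-B
    individuals."""

    label_a: str
    label_b: str
    benefit: float
    group_size: int
    k_a_per_group: int
    mean_fitness_a: float
    mean_fitness_b: float
    n_groups: int


def _run_seeds(root_seed: int, n: int) -> list[int]:
    return [int(x) for x in
            np.random.SeedSequence(root_seed).generate_state(n)]


def _sweep_row(result: SimulationResult, **extra) -> dict:
    final = result.summaries[-1]
    return dict(
        **extra,
        mean_update_factor=float(result.update_factor.mean()),
        mean_giving_up_threshold=float(result.giving_up_threshold.mean()),
        mean_fitness=float(result.fitness.mean()),
        dci=final.dci,
        linearity=final.linearity,
        n_fights=final.n_fights,
        mean_fight_length=final.mean_fight_length,
        strategy=result.strategy,
    )


def main_sweep(config_template: SimulationConfig,
               benefits=range(1, 11), u_inits=(-1.0, 1.0),
               n_replicates: int = 10, seed: int = 0,
               engine: str = "array",
               progress: bool = False) -> pd.DataFrame:
    """One simulation per (benefit, u_init, replicate) with derived seeds.

    Returns one row per run with the final-generation aggregates and the
    strategy label.  The default design (benefits 1..10, U_init in {-1, +1},
    ten replicates) is the 200-run main analysis.
    """
    benefits = list(benefits)
    u_inits = list(u_inits)
    cells = [(b, u, r) for b in benefits for u in u_inits
             for r in range(n_replicates)]
    seeds = _run_seeds(seed, len(cells))
    rows = []
    iterator = zip(cells, seeds)
    if progress:
        from tqdm import tqdm  # soft dependency, exercised only by the CLI

        iterator = tqdm(list(iterator), desc="sweep")
    for (benefit, u_init, rep), run_seed in iterator:
        config = config_template.replace(benefit=float(benefit),
                                         u_init=float(u_init), seed=run_seed)
        result = run_simulation(config, engine=engine)
        rows.append(_sweep_row(result, benefit=float(benefit),
                               u_init=float(u_init), replicate=rep,
                               seed=run_seed))
    return pd.DataFrame(rows)


def competition_experiment(strategy_a: StrategyProfile,
                           strategy_b: StrategyProfile,
                           group_size: int, n_groups: int,
                           k_a_per_group: int, benefit: float,
                           sigma_eps: float = 1.0,
                           n_conflict_rounds: int = 10,
                           seed: int = 0,
                           initial_fitness: float = 100.0,
                           max_fight_rounds: int = 10_000
                           ) -> CompetitionResult:
    """One generation of conflicts between two fixed strategies.

    Every group holds ``k_a_per_group`` strategy-A individuals and the rest
    strategy-B; strengths are drawn fresh, all willingness values start at
    one, and no reproduction or mutation takes place.  Returns the mean
    final fitness of each strategy.
    """
    if not 0 <= k_a_per_group <= group_size:
        raise ValueError(f"k_a_per_group must be in [0, {group_size}], "
                         f"got {k_a_per_group}")
    from ._kernel import conflict_phase, dyad_indices

    ss = np.random.SeedSequence(seed)
    rng_init, rng_seeds = (np.random.default_rng(c) for c in ss.spawn(2))
    g_n, n = n_groups, group_size
    is_a = np.zeros((g_n, n), dtype=bool)
    is_a[:, :k_a_per_group] = True

    s = rng_init.random((g_n, n))
    fit = np.full((g_n, n), initial_fitness)
    u = np.where(is_a, strategy_a.update_factor, strategy_b.update_factor)
    t = np.where(is_a, strategy_a.giving_up_threshold,
                 strategy_b.giving_up_threshold)
    w = np.ones((g_n, n, n))
    disabled = np.zeros((g_n, n), dtype=np.bool_)
    di, dj = dyad_indices(n)
    seeds = rng_seeds.integers(0, 2**31, size=g_n)
    conflict_phase(s, fit, u, t, w, disabled, float(benefit),
                   float(sigma_eps), n_conflict_rounds, max_fight_rounds,
                   seeds, di, dj, False)

    return CompetitionResult(
        label_a=strategy_a.label, label_b=strategy_b.label,
        benefit=float(benefit), group_size=group_size,
        k_a_per_group=k_a_per_group,
        mean_fitness_a=float(fit[is_a].mean()) if k_a_per_group else
        float("nan"),
        mean_fitness_b=float(fit[~is_a].mean())
        if k_a_per_group < group_size else float("nan"),
        n_groups=n_groups)


def competition_curve(strategy_a: StrategyProfile,
                      strategy_b: StrategyProfile, group_size: int,
                      n_groups: int, benefit: float, seed: int = 0,
                      ks=None, **kwargs) -> pd.DataFrame:
    """Competition experiments over all within-group frequencies of A."""
    if ks is None:
        ks = range(group_size + 1)
    ks = list(ks)
    seeds = _run_seeds(seed, len(ks))
    rows = []
    for k, run_seed in zip(ks, seeds):
        res = competition_experiment(strategy_a, strategy_b, group_size,
                                     n_groups, k, benefit, seed=run_seed,
                                     **kwargs)
        rows.append(vars(res))
    return pd.DataFrame(rows)


def sensitivity_sweep(axis: str, values, config_template: SimulationConfig,
                      benefits=range(1, 11), u_inits=(-1.0, 1.0),
                      n_replicates: int = 10, seed: int = 0,
                      engine: str = "array") -> pd.DataFrame:
    """Repeat :func:`main_sweep` for each value of one varied parameter
    (``sigma_eps``, ``n_conflict_rounds`` or ``group_size``)."""
    if axis not in SENSITIVITY_AXES:
        raise ValueError(f"axis must be one of {SENSITIVITY_AXES}, "
                         f"got {axis!r}")
    values = list(values)
    seeds = _run_seeds(seed, len(values))
    frames = []
    for value, sub_seed in zip(values, seeds):
        template = config_template.replace(**{axis: value})
        df = main_sweep(template, benefits, u_inits, n_replicates,
                        seed=sub_seed, engine=engine)
        df.insert(0, "axis", axis)
        df.insert(1, "axis_value", value)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def derive_strategy_profiles(sweep_results: pd.DataFrame, benefit: float
                             ) -> tuple[StrategyProfile, StrategyProfile]:
    """Mean evolved (U, T) per strategy at one benefit of a sweep table.

    Returns the (turn_taking, contest) profiles; raises if either label is
    absent at that benefit (e.g. turn-taking does not evolve for large
    benefits).
    """
    at_benefit = sweep_results[sweep_results["benefit"] == benefit]
    profiles = []
    for label in ("turn_taking", "contest"):
        rows = at_benefit[at_benefit["strategy"] == label]
        if rows.empty:
            raise ValueError(
                f"no runs labelled {label!r} at benefit {benefit}; "
                "cannot derive its strategy profile")
        profiles.append(StrategyProfile(
            label=label,
            update_factor=float(rows["mean_update_factor"].mean()),
            giving_up_threshold=float(
                rows["mean_giving_up_threshold"].mean())))
    return profiles[0], profiles[1]


def max_turn_taking_benefit(sweep_results: pd.DataFrame) -> float:
    """Largest benefit at which any run evolved turn-taking (NaN if none)."""
    tt = sweep_results[sweep_results["strategy"] == "turn_taking"]
    if tt.empty:
        return float("nan")
    return float(tt["benefit"].max())
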