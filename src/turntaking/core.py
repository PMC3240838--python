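"""Domain types, run configuration and population initialization.

All randomness flows through :class:`numpy.random.Generator` instances that
are derived from a single root seed via ``numpy.random.SeedSequence``, so a
run is fully determined by its :class:`SimulationConfig`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

__all__ = [
    "Individual",
    "SimulationConfig",
    "Population",
    "PRESETS",
    "validate_config",
    "init_population",
    "load_config",
]


@dataclass
class Individual:
    """One agent: strength, fitness, heritable strategy parameters and the
    per-opponent willingness to escalate.

    Attributes
    ----------
    id : int
        Identity within the group (stable over the individual's lifetime).
    strength : float
        Fighting ability ``s`` in [0, 1]; drawn once at birth.
    fitness : float
        Accumulated payoff ``F``; benefits add to it, fight costs subtract.
    update_factor : float
        Heritable ``U`` in [-1, 1] controlling how win/loss experience moves
        the willingness to escalate.
    giving_up_threshold : float
        Heritable ``T`` in [0, 5]; evidence level at which a fighter concedes.
    willingness : dict[int, float]
        Map from opponent id to escalation probability ``w`` in [0, 1].
    escalation_disabled : bool
        Set permanently (for this lifetime) once fitness drops below zero;
        implies all willingness values are zero.
    """

    id: int
    strength: float
    fitness: float
    update_factor: float
    giving_up_threshold: float
    willingness: dict[int, float] = field(default_factory=dict)
    escalation_disabled: bool = False

    def disable_escalation(self) -> None:
        """Zero every willingness value and block future escalation."""
        self.escalation_disabled = True
        for opponent in self.willingness:
            self.willingness[opponent] = 0.0

    def check_invariants(self) -> None:
        assert 0.0 <= self.strength <= 1.0
        assert -1.0 <= self.update_factor <= 1.0
        assert 0.0 <= self.giving_up_threshold <= 5.0
        for w in self.willingness.values():
            assert 0.0 <= w <= 1.0
        if self.escalation_disabled:
            assert all(w == 0.0 for w in self.willingness.values())


#: Named parameter presets.  ``paper`` is the full-scale main analysis;
#: ``desk`` is a scaled-down variant that preserves the qualitative outcomes
#: while fitting in an interactive compute budget.
PRESETS: dict[str, dict] = {
    "paper": dict(n_groups=1000, group_size=10, n_conflict_rounds=10,
                  n_generations=5000),
    "desk": dict(n_groups=200, group_size=10, n_conflict_rounds=10,
                 n_generations=1500),
}


@dataclass(frozen=True)
class SimulationConfig:
    """All parameters of one simulation run; the single source of truth.

    Defaults reproduce the main analysis: 1000 groups of 10 individuals,
    10 conflict rounds per generation, initial fitness 100, perception-noise
    SD 1, mutation probability 0.001, T initialized at 0, 5000 generations.
    """

    n_groups: int = 1000
    group_size: int = 10
    n_conflict_rounds: int = 10
    benefit: float = 1.0
    initial_fitness: float = 100.0
    sigma_eps: float = 1.0
    mutation_prob: float = 0.001
    u_init: float = -1.0
    t_init: float = 0.0
    u_mut_range: tuple[float, float] = (-1.0, 1.0)
    t_mut_range: tuple[float, float] = (0.0, 5.0)
    n_generations: int = 5000
    seed: int = 0
    max_fight_rounds: int = 10_000
    n_linearity_randomizations: int = 200

    def replace(self, **changes) -> "SimulationConfig":
        return dataclasses.replace(self, **changes)

    @classmethod
    def from_mapping(cls, mapping: Mapping, preset: str | None = None,
                     **overrides) -> "SimulationConfig":
        base: dict = {}
        if preset is not None:
            if preset not in PRESETS:
                raise ValueError(f"unknown preset {preset!r}; "
                                 f"choose from {sorted(PRESETS)}")
            base.update(PRESETS[preset])
        unknown = set(mapping) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        base.update(mapping)
        base.update(overrides)
        for key in ("u_mut_range", "t_mut_range"):
            if key in base:
                base[key] = tuple(base[key])
        return validate_config(cls(**base))


def validate_config(config: SimulationConfig) -> SimulationConfig:
    """Validate every field; raise ``ValueError`` naming the offender."""

    def check(cond: bool, msg: str) -> None:
        if not cond:
            raise ValueError(f"invalid SimulationConfig: {msg}")

    c = config
    check(c.n_groups >= 1, f"n_groups must be >= 1, got {c.n_groups}")
    check(c.group_size >= 2,
          f"group_size must be >= 2 (no dyads otherwise), got {c.group_size}")
    check(c.n_conflict_rounds >= 1,
          f"n_conflict_rounds must be >= 1, got {c.n_conflict_rounds}")
    check(c.benefit > 0, f"benefit must be positive, got {c.benefit}")
    check(c.initial_fitness > 0,
          f"initial_fitness must be positive, got {c.initial_fitness}")
    check(c.sigma_eps >= 0, f"sigma_eps must be >= 0, got {c.sigma_eps}")
    check(0.0 <= c.mutation_prob <= 1.0,
          f"mutation_prob must be in [0, 1], got {c.mutation_prob}")
    check(-1.0 <= c.u_init <= 1.0,
          f"u_init must be in [-1, 1], got {c.u_init}")
    check(0.0 <= c.t_init <= 5.0, f"t_init must be in [0, 5], got {c.t_init}")
    check(c.u_mut_range[0] <= c.u_mut_range[1],
          f"u_mut_range low > high: {c.u_mut_range}")
    check(c.t_mut_range[0] <= c.t_mut_range[1],
          f"t_mut_range low > high: {c.t_mut_range}")
    check(c.n_generations >= 0,
          f"n_generations must be >= 0, got {c.n_generations}")
    check(c.max_fight_rounds >= 1,
          f"max_fight_rounds must be >= 1, got {c.max_fight_rounds}")
    check(c.n_linearity_randomizations >= 1,
          "n_linearity_randomizations must be >= 1, "
          f"got {c.n_linearity_randomizations}")
    return config


def load_config(path: str | Path, preset: str | None = None,
                **overrides) -> SimulationConfig:
    """Read a YAML or TOML config file mirroring SimulationConfig fields."""
    path = Path(path)
    if path.suffix in {".toml", ".tml"}:
        import tomllib

        with open(path, "rb") as fh:
            mapping = tomllib.load(fh)
    else:
        import yaml

        with open(path) as fh:
            mapping = yaml.safe_load(fh) or {}
    return SimulationConfig.from_mapping(mapping, preset=preset, **overrides)


@dataclass
class Population:
    """Groups of individuals plus the generation counter."""

    groups: list[list[Individual]]
    generation: int = 0

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def group_size(self) -> int:
        return len(self.groups[0])

    def individuals(self):
        for group in self.groups:
            yield from group

    def check_invariants(self) -> None:
        sizes = {len(g) for g in self.groups}
        assert len(sizes) == 1, f"unequal group sizes: {sizes}"
        for ind in self.individuals():
            ind.check_invariants()


def _new_individual(ident: int, opponents: range, u: float, t: float,
                    f0: float, rng: np.random.Generator) -> Individual:
    return Individual(
        id=ident,
        strength=float(rng.uniform(0.0, 1.0)),
        fitness=f0,
        update_factor=u,
        giving_up_threshold=t,
        willingness={j: 1.0 for j in opponents if j != ident},
    )


def init_population(config: SimulationConfig,
                    rng: np.random.Generator) -> Population:
    """Found the population: strengths ~ Uniform(0, 1), fitness = F0,
    every willingness value 1, and (U, T) = (u_init, t_init) for everyone.
    """
    validate_config(config)
    groups = []
    for _ in range(config.n_groups):
        members = range(config.group_size)
        groups.append([
            _new_individual(i, members, config.u_init, config.t_init,
                            config.initial_fitness, rng)
            for i in members
        ])
    return Population(groups=groups, generation=0)
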