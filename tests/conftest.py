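import numpy as np
import pandas as pd
import pytest

from turntaking import Individual, SimulationConfig, main_sweep

#: Scaled-down variant of the main analysis used by the stochastic
#: reproduction tests: same group size, rounds, noise and mutation rate, but
#: 200 groups and 1500 generations instead of 1000 x 5000.
DESK_CONFIG = SimulationConfig(
    n_groups=200, group_size=10, n_conflict_rounds=10, initial_fitness=100.0,
    sigma_eps=1.0, mutation_prob=0.001, t_init=0.0, n_generations=1500,
    n_linearity_randomizations=100,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_individual(ident=0, strength=0.5, fitness=100.0, update_factor=0.0,
                    giving_up_threshold=0.0, opponents=(1,), willingness=1.0):
    return Individual(
        id=ident, strength=strength, fitness=fitness,
        update_factor=update_factor,
        giving_up_threshold=giving_up_threshold,
        willingness={j: willingness for j in opponents},
    )


def make_dyad(s_i=0.5, s_j=0.5, u=0.0, t=0.0, fitness=100.0, willingness=1.0):
    a = make_individual(0, s_i, fitness, u, t, opponents=(1,),
                        willingness=willingness)
    b = make_individual(1, s_j, fitness, u, t, opponents=(0,),
                        willingness=willingness)
    return a, b


@pytest.fixture(scope="session")
def desk_sweep() -> pd.DataFrame:
    """Shared scaled-down benefit sweep: 5 replicates per initial U at
    benefit 1 (ten runs total, for the bistability check) plus one replicate
    per initial U at benefits 2..10 (for the benefit-ceiling check and the
    competition strategy profiles)."""
    at_one = main_sweep(DESK_CONFIG, benefits=[1], u_inits=(-1.0, 1.0),
                        n_replicates=5, seed=101)
    above_one = main_sweep(DESK_CONFIG, benefits=range(2, 11),
                           u_inits=(-1.0, 1.0), n_replicates=1, seed=202)
    return pd.concat([at_one, above_one], ignore_index=True)
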