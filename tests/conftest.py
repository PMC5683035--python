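import numpy as np
import pytest
from hypothesis import settings

from biparpred import simulate as sim

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_map():
    """Compact genome: 10 chromosomes x 5 markers, 170 cM each."""
    return sim.default_map(markers_per_chromosome=5)


@pytest.fixture(scope="session")
def f2_population(small_map):
    """Seeded F2-derived population, 60 families, fully polymorphic panel."""
    n = small_map.n_markers
    ped = sim.FounderPair(
        "PA", "PB", np.zeros(n, dtype=np.int8), np.ones(n, dtype=np.int8)
    )
    rng = np.random.default_rng(1234)
    return sim.simulate_population(ped, "F2", 60, small_map, rng, population_id="Fix")


@pytest.fixture(scope="session")
def balanced_trials(f2_population):
    """Balanced 3-env x 2-rep trials with interior variance components.

    Environment main effects are added so that every component of the
    all-random analysis model (env, genotype, GxE, residual) is interior.
    """
    rng = np.random.default_rng(99)
    arch = sim.random_trait_architecture(
        f2_population, "GY_WW", 0.5, rng, n_qtl=15, e=3, r=2, sigma_g2=2.0
    )
    trials = sim.simulate_trials(f2_population, arch, rng)
    env_offsets = {f"E{j + 1}": off for j, off in enumerate(rng.normal(0, 3.0, 3))}
    trials = trials.assign(
        value=trials["value"] + trials["environment_id"].map(env_offsets)
    )
    return trials, arch
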