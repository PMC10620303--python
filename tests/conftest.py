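import numpy as np
import pytest

from turingcross.fixtures import load_fixture
from turingcross.stability import SearchBounds, sample_param_set


@pytest.fixture(scope="session")
def admissible():
    """Packaged general admissible fixture (asymmetric parents)."""
    return load_fixture("admissible")


@pytest.fixture(scope="session")
def symmetric():
    """Packaged symmetric-parent fixture (reduced m_vu)."""
    return load_fixture("symmetric")


@pytest.fixture(scope="session")
def symmetric_parent_spec(symmetric):
    """(rates, kappa) of the symmetric fixture's identical parents."""
    from turingcross.params import AlleleRates

    meta = symmetric.meta
    rates = {
        tf: AlleleRates(**meta["parent_rates"][tf]) for tf in ("u", "v")
    }
    kappa = dict(meta["parent_kappa"])
    return rates, kappa


def draw_param_set(seed: int):
    """One random (not necessarily admissible) F1 parameter set."""
    rng = np.random.default_rng(seed)
    return sample_param_set(rng, SearchBounds())


def random_reaction_system(seed: int, n: int = 4):
    """A random generic n-species system (not tied to any genotype)."""
    from turingcross.systems import HillSpec, ReactionSystem, Species

    rng = np.random.default_rng(seed)
    species = []
    for i in range(n):
        species.append(
            Species(
                name=f"s{i}",
                role="activator" if i % 2 == 0 else "inhibitor",
                alpha=rng.uniform(0.01, 1),
                beta=rng.uniform(0.1, 2),
                gamma=rng.uniform(0, 20),
                hill=HillSpec(
                    tuple(rng.uniform(0, 5, n)), tuple(rng.uniform(0, 5, n))
                ),
            )
        )
    return ReactionSystem(tuple(species), D_u=1.0, D_v=2.0)


@pytest.fixture
def random_params():
    return draw_param_set(12345)
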