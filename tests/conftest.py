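import numpy as np
import pandas as pd
import pytest

from proteome_allocation import (
    AffinityModel,
    NoiseSpec,
    example_model,
    simulate_from_model,
    simulate_half_coordinated,
)


@pytest.fixture
def tiny_model() -> AffinityModel:
    """3 genes x 2 conditions; gene G0 is the biosynthetic sector."""
    aff = pd.DataFrame(
        {"c1": [1.0, 2.0, 3.0], "c2": [1.0, 2.0, 1.0]},
        index=["G0", "G1", "G2"],
    )
    return AffinityModel(aff, ["G0"], t_b=0.5)


def random_model(rng: np.random.Generator, constant: bool = False) -> AffinityModel:
    """Random valid model for property tests; optionally all-constant affinities."""
    n_genes = rng.integers(3, 12)
    n_cond = rng.integers(2, 8)
    base = rng.uniform(0.1, 5.0, size=n_genes)
    n_bio = int(rng.integers(1, n_genes))
    if constant:
        table = np.tile(base[:, None], (1, n_cond))
    else:
        table = rng.uniform(0.1, 5.0, size=(n_genes, n_cond))
        table[:n_bio] = base[:n_bio, None]
    genes = [f"G{i}" for i in range(n_genes)]
    conds = [f"c{i}" for i in range(n_cond)]
    return AffinityModel(
        pd.DataFrame(table, index=genes, columns=conds),
        genes[:n_bio],
        t_b=float(rng.uniform(0.2, 2.0)),
    )


@pytest.fixture(scope="session")
def model_dataset():
    """Noise-free forward simulation of the example affinity model."""
    model = example_model(n_genes=300, n_conditions=12, seed=7)
    return model, simulate_from_model(model, NoiseSpec(cv=0.0, seed=7))


@pytest.fixture(scope="session")
def half_coordinated_noisy():
    """The benchmark: 1000 proteins, 20 conditions, 25% noise, half coordinated."""
    return simulate_half_coordinated(n_proteins=1000, noise=NoiseSpec(cv=0.25, seed=11))


@pytest.fixture(scope="session")
def half_coordinated_clean():
    return simulate_half_coordinated(n_proteins=200, noise=NoiseSpec(cv=0.0, seed=3))
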