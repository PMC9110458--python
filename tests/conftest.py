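import numpy as np
import pandas as pd
import pytest

from culmnet.simulate import ModuleSpec, SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Small two-module design used across test modules."""
    return SimulationConfig(
        n_genotypes=6,
        n_genes=120,
        n_internodes=4,
        n_replicates=2,
        true_ranks=(2, 3, 2),
        noise_sd=0.1,
        module_spec=[
            ModuleSpec(size=25, trait_effect=1.0, inter_gene_cor=0.9),
            ModuleSpec(size=25, trait_effect=-1.0, inter_gene_cor=0.9),
        ],
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """(tensor, truth, counts, meta, traits) for the small design."""
    return simulate_dataset(small_config, trait_noise_sd=0.2)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def random_expression(rng: np.random.Generator, n_genes: int, n_samples: int, unit="log2CPM1"):
    from culmnet.containers import ExpressionMatrix

    vals = pd.DataFrame(
        rng.normal(5, 2, size=(n_genes, n_samples)),
        index=[f"g{i:04d}" for i in range(n_genes)],
        columns=[f"s{j:03d}" for j in range(n_samples)],
    )
    return ExpressionMatrix(vals, unit)
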