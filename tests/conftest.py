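import numpy as np
import pytest

from pertstream import (
    PerturbDataset,
    generate_annotations,
    generate_grn,
    simulate_cells,
)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def tiny_grn():
    """20 genes in 4 modules; dense within-module effects."""
    return generate_grn(n_genes=20, n_modules=4, within_module_density=1.0,
                        effect_scale=2.0, seed=3)


@pytest.fixture(scope="session")
def tiny_conditions(tiny_grn):
    genes = tiny_grn.gene_names
    return [
        frozenset(),
        frozenset({genes[0]}),
        frozenset({genes[5]}),
        frozenset({genes[10]}),
        frozenset({genes[15]}),
        frozenset({genes[0], genes[5]}),
        frozenset({genes[10], genes[15]}),
    ]


@pytest.fixture(scope="session")
def tiny_dataset(tiny_grn, tiny_conditions):
    """Noisy small dataset: 7 conditions x 30 cells."""
    return simulate_cells(tiny_grn, tiny_conditions, cells_per_condition=30,
                          base_mean=5.0, noise_sd=0.4, dropout_rate=0.2, seed=4)


@pytest.fixture(scope="session")
def clean_dataset(tiny_grn, tiny_conditions):
    """Noiseless, dropout-free dataset: planted effects are exact."""
    return simulate_cells(tiny_grn, tiny_conditions, cells_per_condition=5,
                          base_mean=20.0, noise_sd=0.0, dropout_rate=0.0, seed=4)


@pytest.fixture(scope="session")
def tiny_annotations(tiny_grn):
    return generate_annotations(tiny_grn, terms_per_module=3, n_levels=3,
                                annotated_fraction=0.9, seed=5)


@pytest.fixture
def two_gene_dataset():
    """Minimal hand-built dataset: 2 genes, 4 cells."""
    return PerturbDataset(
        expression=np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0], [0.5, 1.0]]),
        labels=[frozenset(), frozenset(), frozenset({"A"}), frozenset({"A", "B"})],
        gene_names=["A", "B"],
    )
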