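import numpy as np
import pytest

from cernakit.cerna import CeRNANetwork, Node
from cernakit.gene_sets import GeneSet
from cernakit.synthetic import (
    SimulationConfig,
    paper_fixture_membership,
    simulate_expression,
)


@pytest.fixture
def membership_fixture():
    return paper_fixture_membership()


@pytest.fixture
def minimal_triple():
    """The smallest valid ceRNA network: L1 - m1 - G1."""
    l, m, g = Node("L1", "lncRNA"), Node("m1", "miRNA"), Node("G1", "mRNA")
    return CeRNANetwork(
        nodes={l, m, g},
        edges={frozenset((l, m)), frozenset((m, g))},
        label="test",
    )


@pytest.fixture
def small_gene_set():
    return GeneSet.from_symbols("s", "apoptosis", ["Bax", "Mapt", "Tnf"],
                                provenance=["test"])


@pytest.fixture
def null_dataset():
    dataset, _ = simulate_expression(
        SimulationConfig(n_genes=2000, de_fraction=0.0, seed=42))
    return dataset


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
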