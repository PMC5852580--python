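import numpy as np
import pytest

from genefam import datasets
from genefam.synthetic_data import DuplicatePlan, FamilySimConfig, simulate_family


@pytest.fixture(scope="session")
def cmagst_family():
    """The bundled published coordinate table of the pumpkin GST family."""
    return datasets.cmagst_coordinates()


@pytest.fixture(scope="session")
def cmagst_pairs():
    """The bundled published duplicate pairs with their Ks/Ka estimates."""
    return datasets.cmagst_duplicate_pairs()


@pytest.fixture(scope="session")
def planted_family():
    """Small synthetic family: one tandem pair, one segmental pair, 2 singletons."""
    cfg = FamilySimConfig(
        duplicate_plan=[
            DuplicatePlan("tanA1", "tanA2", "tandem", target_omega=0.3, target_ks=0.2),
            DuplicatePlan("segB1", "segB2", "segmental", target_omega=0.3, target_ks=0.2),
        ],
        n_singletons=2,
        codon_length=200,
        seed=11,
    )
    return simulate_family(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
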