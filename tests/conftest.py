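import numpy as np
import pandas as pd
import pytest

from microherit.compositional import OtuTable
from microherit.pipeline import default_fixed_effects
from microherit.relationship import build_A
from microherit.simulate import SimulationConfig, TraitSpec, simulate_dataset


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        seed=11,
        n_founders=80,
        n_generations=3,
        n_snps=200,
        n_otus=30,
        depth_range=(2000, 5000),
        trait_specs=[
            TraitSpec("lscs", 0.37, 3.29, 2.25),
            TraitSpec("cv_milk", 0.22, 53.9, 148.0),
            TraitSpec("fat_content", 0.50, 7.4, 1.3),
        ],
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_A(small_dataset):
    return build_A(small_dataset.pedigree)


@pytest.fixture(scope="session")
def effects_for():
    def _effects(traits):
        f = {t: default_fixed_effects(t)[0] for t in traits}
        c = {t: default_fixed_effects(t)[1] for t in traits}
        return f, c

    return _effects


@pytest.fixture
def toy_table():
    counts = np.array(
        [
            [0, 5, 5, 10],
            [2, 3, 5, 0],
            [1, 1, 1, 1],
            [10, 0, 4, 6],
            [3, 3, 0, 4],
        ]
    )
    tax = pd.DataFrame(
        {
            "otu_id": [f"o{j}" for j in range(4)],
            "domain": "Bacteria",
            "phylum": "P1",
            "class": "C1",
            "order": "O1",
            "family": ["F1", "F1", "F2", "F2"],
            "genus": ["g1", "g1", "g2", "unknown"],
            "species": "unknown",
        }
    ).set_index("otu_id")
    return OtuTable(
        counts, [f"s{i}" for i in range(5)], [f"o{j}" for j in range(4)], tax
    )
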