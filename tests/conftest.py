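import numpy as np
import pandas as pd
import pytest

from dielfd.core import DIET_CATEGORY_COLUMNS, SpeciesTable
from dielfd.dendro import DistanceMatrix, upgma
from dielfd.synth import GeneratorParams, generate_species


def make_table(statuses, niches=None, dd_flags=None, seed=0, diet=None):
    """Small valid species table with given statuses/niches and random traits."""
    n = len(statuses)
    rng = np.random.default_rng(seed)
    if niches is None:
        niches = ["nocturnal"] * n
    if dd_flags is None:
        dd_flags = [False] * n
    df = pd.DataFrame(
        {
            "species_id": [f"sp{i}" for i in range(n)],
            "diel_niche": niches,
            "iucn_status": statuses,
            "dd_threatened": dd_flags,
            "body_mass_g": rng.lognormal(4, 1, n),
            "litter_size": rng.lognormal(0.5, 0.4, n),
            "habitat_breadth": rng.integers(1, 8, n),
            "foraging_stratum": rng.integers(1, 5, n),
            "diet_score": diet if diet is not None else rng.normal(0, 1, n),
        }
    )
    return SpeciesTable(df)


@pytest.fixture
def toy_distance():
    """3-species matrix whose UPGMA trace is known by hand."""
    return DistanceMatrix(
        np.array(["A", "B", "C"]),
        np.array([[0.0, 0.2, 0.6], [0.2, 0.0, 0.8], [0.6, 0.8, 0.0]]),
    )


@pytest.fixture
def toy_tree(toy_distance):
    return upgma(toy_distance)


@pytest.fixture(scope="session")
def global_mammals():
    """Full-size synthetic emulation of the study inputs (built once)."""
    table, diet = generate_species(GeneratorParams.global_mammals(), seed=20220812 % 2**20)
    return table, diet


def random_diet_table(n, seed=0):
    rng = np.random.default_rng(seed)
    X = np.round(rng.dirichlet(np.full(10, 0.5), size=n) * 10) * 10
    X[X.sum(axis=1) == 0, 0] = 10
    return pd.DataFrame(
        X, index=[f"sp{i}" for i in range(n)], columns=list(DIET_CATEGORY_COLUMNS)
    )
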