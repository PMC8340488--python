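import numpy as np
import pandas as pd
import pytest

from sporesig import synthetic
from sporesig.types import PipelineConfig


@pytest.fixture(scope="session")
def catalog():
    return synthetic.make_catalog(seed=11)


@pytest.fixture(scope="session")
def genome_set(catalog):
    """Default-condition synthetic genome collection (40 genomes/family)."""
    return synthetic.make_genomes(catalog, n_per_family=40, seed=11)


@pytest.fixture(scope="session")
def small_genome_set(catalog):
    return synthetic.make_genomes(catalog, n_per_family=10, seed=7)


@pytest.fixture()
def config():
    return PipelineConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def calls_from_truth(genome_set) -> pd.DataFrame:
    """Per-genome class calls straight from generator ground truth."""
    rows = [
        {"genome_id": g, "sporulation_class": t["true_class"]}
        for g, t in genome_set.truth["genomes"].items()
    ]
    return pd.DataFrame(rows)
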