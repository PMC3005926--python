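import numpy as np
import pytest
from hypothesis import settings

from mirfish import simulate as sim
from mirfish.mapping import Genome
from mirfish.pipeline import run_synthetic

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_dataset():
    """A small planted dataset shared by mapping/annotation tests."""
    genome, truth = sim.generate_genome(
        n_chrom=1, chrom_len=80_000, n_mirna=4, n_clusters=0,
        n_repeats=1, n_decoys=1, seed=42,
    )
    return genome, truth


@pytest.fixture(scope="session")
def small_genome(small_dataset):
    genome, _ = small_dataset
    return Genome.from_dict(genome)


@pytest.fixture(scope="session")
def pipeline_run():
    """One full synthetic pipeline run at the default study conditions."""
    result, genome, truth = run_synthetic(seed=1)
    return result, genome, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
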