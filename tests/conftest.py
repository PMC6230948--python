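import numpy as np
import pytest

from emmer_survey import synthio


@pytest.fixture(scope="session")
def dataset():
    """One default synthetic dataset shared across the suite."""
    return synthio.generate_dataset(synthio.SyntheticGenomeSpec(seed=7))


@pytest.fixture(scope="session")
def manifest(dataset):
    return dataset.manifest


@pytest.fixture(scope="session")
def chromosomes(dataset):
    return dataset.chromosomes


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def small_spec(**overrides) -> synthio.SyntheticGenomeSpec:
    """A quick-to-generate genome for tests that rebuild from scratch."""
    defaults = dict(
        n_homeologous_pairs=2,
        chromosome_length=120_000,
        n_conserved_genes_per_chr=6,
        n_mirna_hairpins=8,
        n_lncrna=6,
        n_coding_decoys=4,
        n_ssr=8,
        scaffold_n50_target=2_000,
        seed=11,
    )
    defaults.update(overrides)
    return synthio.SyntheticGenomeSpec(**defaults)
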