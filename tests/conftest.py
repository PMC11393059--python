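import numpy as np
import pytest

from thermofungi import synthetic_data as sd


@pytest.fixture(scope="session")
def small_spec() -> sd.SyntheticSpec:
    """A reduced genome panel that keeps module tests fast."""
    return sd.SyntheticSpec(
        n_thermophile=10,
        n_mesophile=14,
        n_thermotolerant=3,
        core_size_by_lifestyle={
            "thermophilic": 30, "mesophilic": 60, "thermotolerant": 50,
        },
        n_accessory=80,
        n_genes=10,
        len_codons=60,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_spec, tmp_path_factory):
    """Full simulated dataset on disk (session-scoped)."""
    outdir = tmp_path_factory.mktemp("dataset")
    paths = sd.simulate(small_spec, outdir)
    return outdir, paths


@pytest.fixture(scope="session")
def study_matrix():
    """Study-sized orthogroup matrix (29/42/8 genomes) with ground truth."""
    spec = sd.SyntheticSpec(seed=5)
    meta, truth = sd.gen_genome_set(spec)
    matrix, truth = sd.gen_hog_matrix(spec, meta, truth)
    return meta, matrix, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
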