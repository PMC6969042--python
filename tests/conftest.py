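import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")

from orpheus import hmm as hmm_mod
from orpheus import simulate

BASE_SEED = 11


@pytest.fixture(scope="session")
def template():
    rec, motif_map = simulate.make_or_template(BASE_SEED)
    return rec, motif_map


@pytest.fixture(scope="session")
def seed_msa():
    return simulate.make_seed_msa(BASE_SEED)


@pytest.fixture(scope="session")
def or_hmm(seed_msa):
    profile = hmm_mod.build_profile_hmm(seed_msa)
    hmm_mod.calibrate(profile, n_null=300, seed=2)
    return profile


@pytest.fixture(scope="session")
def small_genome():
    """One planted gene of every class plus decoys, low divergence."""
    contigs, truths = simulate.plant_genes(3, 2, 2, 2, 2, contig_len=5000,
                                           divergence=0.05, seed=BASE_SEED)
    return contigs, truths


@pytest.fixture(scope="session")
def balanced18():
    return simulate.balanced_tree(18, total_length=5.0)
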