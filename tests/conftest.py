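import warnings

import numpy as np
import pytest

from ifrpred.config import RunConfig
from ifrpred.fixtures import ToyComplexSpec, make_toy_structure
from ifrpred.pipeline import train_corpus


@pytest.fixture(scope="session")
def patch_complex():
    """Two 10-residue chains 10 Å apart with a 2-residue hydrophobic
    contact patch (residues 5 and 6) and two FSR decoy leucines."""
    spec = ToyComplexSpec(n_residues=10, chain_separation=10.0,
                          contact_patch=[4, 5], fsr_decoys=[0, 8], seed=7)
    return make_toy_structure(spec, pdb_id="PATCH")


@pytest.fixture(scope="session")
def far_complex():
    """Two chains 100 Å apart: no inter-chain occlusion, no contacts."""
    spec = ToyComplexSpec(n_residues=8, chain_separation=100.0, seed=3)
    return make_toy_structure(spec, pdb_id="FAR")


def build_toy_corpus(n_entries=12, seed0=0):
    complexes = []
    for i in range(n_entries):
        p = 3 + (i % 3)
        spec = ToyComplexSpec(n_residues=10, chain_separation=10.0,
                              contact_patch=[p, p + 1], fsr_decoys=[0, 8],
                              seed=seed0 + i)
        cx, _ = make_toy_structure(spec, pdb_id=f"TOY{seed0 + i:03d}")
        complexes.append(cx)
    return complexes


@pytest.fixture(scope="session")
def toy_corpus():
    return build_toy_corpus()


@pytest.fixture(scope="session")
def trained_bundle(toy_corpus):
    cfg = RunConfig(k_folds=4, seed=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bundle, report = train_corpus(toy_corpus, cfg)
    return bundle, report, cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
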