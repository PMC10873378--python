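import numpy as np
import pytest

from chemtrace.corpus import Vocabulary
from chemtrace.synthetic import GeneratorConfig, generate_corpus


@pytest.fixture(scope="session")
def small_corpus():
    """120 small diverse molecules, 30% chiral."""
    cfg = GeneratorConfig(n_molecules=120, heavy_atom_range=(3, 12),
                          chiral_fraction=0.3, seed=11)
    return generate_corpus(cfg)


@pytest.fixture(scope="session")
def small_vocab(small_corpus):
    strings = [r.canonical_smiles for r in small_corpus]
    for r in small_corpus:
        strings.extend(r.randomized_smiles)
    return Vocabulary.build(strings)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
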