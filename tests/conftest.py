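import numpy as np
import pytest

from deephop import fixtures, pairs, protein


@pytest.fixture(scope="session")
def spec():
    return fixtures.FixtureSpec(n_molecules=30, n_targets=2, seed=1, n_conf=3)


@pytest.fixture(scope="session")
def library(spec):
    return fixtures.make_library(spec)


@pytest.fixture(scope="session")
def library3d(spec, library):
    return fixtures.attach_conformers(library, n_conf=spec.n_conf)


@pytest.fixture(scope="session")
def mols3d(library3d):
    return {m.mol_id: m for m in library3d}


@pytest.fixture(scope="session")
def bioactivity(spec, library3d):
    records, planted = fixtures.make_bioactivity(spec, library3d,
                                                 return_planted=True)
    return records, planted


@pytest.fixture(scope="session")
def simcache():
    # one 3D-similarity cache for the whole session: sc_score is the
    # expensive step and is deterministic, so sharing it is safe
    return pairs.SimilarityCache()


@pytest.fixture(scope="session")
def protein_embeddings(spec):
    return {p.seq_id: protein.embed_protein(p)
            for p in fixtures.make_proteins(spec)}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
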