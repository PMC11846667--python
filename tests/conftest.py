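import numpy as np
import pytest

from tcrforge import build_tcr_cache, default_bundle, make_toy_reference


@pytest.fixture(scope="session")
def toy_paths(tmp_path_factory):
    out = tmp_path_factory.mktemp("toyref")
    # 4 clippable residues after the V anchor, 3 before the J anchor, and
    # TRAJ33/38/55 present so the tryptophan-anchor exception is exercised
    return make_toy_reference(6, 6, 7, out, v_tail=4, j_head=3, special_j=True)


@pytest.fixture(scope="session")
def cache(toy_paths):
    cdna, pep = toy_paths
    return build_tcr_cache(cdna, pep)


@pytest.fixture(scope="session")
def bundle(cache):
    return default_bundle(cache)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
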