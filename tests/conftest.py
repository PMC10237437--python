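import numpy as np
import pytest

import kleevec as kv
from kleevec.synthetic import make_default_fixtures


@pytest.fixture(scope="session")
def fixtures():
    return make_default_fixtures(seed=0)


@pytest.fixture(scope="session")
def tiny(fixtures):
    return fixtures["tiny"]


@pytest.fixture(scope="session")
def medium(fixtures):
    return fixtures["medium"]


@pytest.fixture(scope="session")
def degenerate(fixtures):
    return fixtures["degenerate"]


@pytest.fixture(scope="session")
def tiny_sets(tiny):
    return kv.encode_sets(kv.impute_ambiguous(tiny.alignment))


@pytest.fixture(scope="session")
def tiny_ref(tiny_sets):
    return kv.compute_reference(tiny_sets)


@pytest.fixture(scope="session")
def tiny_vectors(tiny_sets, tiny_ref):
    return kv.compute_indicators(tiny_sets, tiny_ref)


@pytest.fixture(scope="session")
def medium_sets(medium):
    return kv.encode_sets(kv.impute_ambiguous(medium.alignment))


def random_indicator_vectors(n, dim, seed=0):
    """Random unit vectors wrapped as IndicatorVector records."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        v = rng.standard_normal(dim)
        v /= np.linalg.norm(v)
        out.append(
            kv.IndicatorVector(set_name=f"set{i:04d}", vector=v, eigenvalue=1.0)
        )
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
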