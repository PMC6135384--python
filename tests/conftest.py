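import numpy as np
import pytest

import foramstats as fs


@pytest.fixture(scope="session")
def galapagos():
    """Packaged Galapagos survey: (assemblage, taxa, environment)."""
    return fs.load_galapagos()


@pytest.fixture(scope="session")
def galapagos_env_frame(galapagos):
    a, _, env = galapagos
    return fs.join_environment(a, env)


@pytest.fixture(scope="session")
def galapagos_clusters(galapagos):
    """Hellinger -> chord -> Ward on the fixture, cut at k=5 and k=2."""
    a, _, _ = galapagos
    dend = fs.ward_cluster(fs.chord_distance(fs.hellinger(a)))
    return fs.cut_dendrogram(dend, 5), fs.cut_dendrogram(dend, 2), dend


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
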