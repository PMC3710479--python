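import pytest

from bibool import build_bipartite, build_classical
from bibool.fixtures import simplified_hog, toy_crosstalk


@pytest.fixture(scope="session")
def hog_model():
    return simplified_hog()


@pytest.fixture(scope="session")
def crosstalk_model():
    return toy_crosstalk()


@pytest.fixture(scope="session")
def hog_bipartite(hog_model):
    return build_bipartite(hog_model)


@pytest.fixture(scope="session")
def crosstalk_bipartite(crosstalk_model):
    return build_bipartite(crosstalk_model)


@pytest.fixture(scope="session")
def crosstalk_classical(crosstalk_model):
    bm, _ = build_classical(crosstalk_model)
    return bm
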