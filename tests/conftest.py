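import numpy as np
import pytest

from helentron_scan.simulate import ElementSpec, make_element


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def hine_element():
    """A default master HINE element with its truth record."""
    return make_element(ElementSpec(kind="HINE"), np.random.default_rng(7), "hine1")


@pytest.fixture
def helentron_element():
    spec = ElementSpec(kind="Helentron", body_len=1200, embed_rep_orf=True)
    return make_element(spec, np.random.default_rng(8), "helentron1")


def random_dna(rng, n):
    return "".join(rng.choice(np.array(list("ACGT")), size=n))
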