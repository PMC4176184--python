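import numpy as np
import pytest

from trxflex import get_code, load_trx_scale


@pytest.fixture(scope="session")
def scale():
    return load_trx_scale("canonical")


@pytest.fixture(scope="session")
def code():
    return get_code()


@pytest.fixture(scope="session")
def uniform_scale():
    from trxflex import TRXScale

    return TRXScale(
        values={a + b: 10.0 for a in "ACGT" for b in "ACGT"},
        source_label="uniform-10",
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20140908)


def random_seq(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))


def random_cds_string(rng, n_codons, code):
    sense = [c for c in code.sense_codons]
    return "".join(rng.choice(sense, size=n_codons))


@pytest.fixture(scope="session")
def sense_codons(code):
    return list(code.sense_codons)
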