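import numpy as np
import pytest

from helpers import make_matrix


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def toy_matrix():
    """A=00, B=01, C=1?, D=11: two binary characters, one missing cell."""
    return make_matrix(["00", "01", "1?", "11"], list("ABCD"))


@pytest.fixture
def toy_nexus(tmp_path):
    text = """#NEXUS
BEGIN TAXA;
    DIMENSIONS NTAX=4;
    TAXLABELS A B C D;
END;
BEGIN CHARACTERS;
    DIMENSIONS NCHAR=2;
    FORMAT DATATYPE=STANDARD MISSING=? SYMBOLS="0123456789";
    MATRIX
    A 00
    B 01
    C 1?
    D 11
    ;
END;
"""
    path = tmp_path / "toy.nex"
    path.write_text(text)
    return path
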