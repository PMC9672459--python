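import numpy as np
import pytest

from phageprom.encoders import _load_table


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def raw_di6():
    """Raw (unstandardized) 6-index dinucleotide table as a plain dict."""
    return _load_table("dinucleotide_indices_6.tsv", "di", "raw6").table


@pytest.fixture(scope="session")
def raw_di38():
    return _load_table(
        "dinucleotide_indices_38_synthetic.tsv", "di", "raw38"
    ).table


@pytest.fixture(scope="session")
def raw_tri6():
    return _load_table("trinucleotide_indices_6.tsv", "tri", "rawtri").table
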