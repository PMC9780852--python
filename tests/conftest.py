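import math

import pytest

import focalcbs as f
from focalcbs.datasets import load_sapt_decompositions, load_sapt_reference


@pytest.fixture(scope="session")
def sapt_table():
    return load_sapt_reference()


@pytest.fixture(scope="session")
def set3x6():
    """The 18-dimer benchmark suite with printed group labels."""
    df = load_sapt_reference()
    df = df[df["subset"] == "set3x6"]
    decomps = load_sapt_decompositions("set3x6")
    return list(zip(decomps, df["group_label"].tolist()))


@pytest.fixture
def planted_spec():
    """Noiseless synthetic dimer with known CBS decomposition."""
    return f.SystemSpec(
        "planted", de_hf=-25.0, de_mp2_corr=-20.0, de_post_mp2=-3.0
    )


def hf_forward(e_cbs, a, alpha, x):
    return e_cbs + a * math.exp(alpha * math.sqrt(x))


def corr_forward(e_cbs, a, beta, x):
    return e_cbs + a * float(x) ** -beta
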