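import numpy as np
import pytest

from famtriage.model import Individual, Pedigree
from famtriage.synthetic_data import make_family_fixture


@pytest.fixture(scope="session")
def family_fixture():
    """(variants, genotypes, pedigree) for the 5-member TTN family."""
    return make_family_fixture()


@pytest.fixture()
def trio_pedigree():
    return Pedigree(
        [
            Individual("F", sex="male", status="unaffected"),
            Individual("M", sex="female", status="unaffected"),
            Individual("C", sex="female", status="affected", father_id="F", mother_id="M"),
        ]
    )


@pytest.fixture()
def quartet_pedigree():
    """Two parents, two children (one affected) — sibling and trio substrate."""
    return Pedigree(
        [
            Individual("F", sex="male", status="unaffected"),
            Individual("M", sex="female", status="unaffected"),
            Individual("S1", sex="female", status="affected", father_id="F", mother_id="M"),
            Individual("S2", sex="male", status="unaffected", father_id="F", mother_id="M"),
        ]
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
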