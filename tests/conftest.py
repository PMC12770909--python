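import numpy as np
import pytest

from dstacs import (
    BasisFieldSet,
    default_montages,
    make_basis_fields,
    make_sphere_sheet,
)


@pytest.fixture(scope="session")
def sheet():
    """Small spherical cortical sheet shared across tests (642 nodes)."""
    return make_sphere_sheet(subdivisions=3)


@pytest.fixture(scope="session")
def basis(sheet):
    """Overlapping-mode basis fields of the first default montage."""
    return make_basis_fields(sheet, default_montages()[0])


@pytest.fixture(scope="session")
def separated_basis(sheet):
    """Separated-mode basis fields (disjoint site supports)."""
    return make_basis_fields(sheet, default_montages("separated")[0])


def random_basis(sheet, seed: int) -> BasisFieldSet:
    """Arbitrary dense basis fields for property tests."""
    rng = np.random.default_rng(seed)
    n = sheet.n_nodes
    return BasisFieldSet(
        e_r1=rng.normal(size=(n, 3)),
        e_c1=rng.normal(size=(n, 3)),
        e_r2=rng.normal(size=(n, 3)),
    )
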