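import numpy as np
import pytest

from ctdecomp import (
    Blob,
    BlobSpec,
    compute_global,
    difference_density,
    make_cube_pair,
    split_signs,
    two_blob_spec,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20220902)


@pytest.fixture(scope="session")
def separated_spec():
    """Unit blob hopping 4 bohr along x (10 sigma separation)."""
    return two_blob_spec(separation=4.0, sigma=0.4, shape=(80, 80, 80))


@pytest.fixture(scope="session")
def separated_pair(separated_spec):
    return make_cube_pair(separated_spec)


@pytest.fixture(scope="session")
def two_group_case():
    """Asymmetric donor/acceptor blob pair with one pseudo-atom per pole."""
    spec = BlobSpec(
        gs_blobs=[Blob([-2.0, 0, 0], 0.4, 1.0), Blob([2.0, 0, 0], 0.4, 0.5)],
        ex_blobs=[Blob([-2.0, 0, 0], 0.4, 0.3), Blob([2.0, 0, 0], 0.4, 1.2)],
        shape=(72, 72, 72),
        atoms=np.array([[-2.0, 0, 0], [2.0, 0, 0]]),
    )
    gs, ex = make_cube_pair(spec)
    split = split_signs(difference_density(gs, ex))
    glob = compute_global(split, gs)
    return spec, gs, ex, split, glob
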