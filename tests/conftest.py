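import numpy as np
import pytest

import spectransfer as st


@pytest.fixture(scope="session")
def paired_sets():
    """Small default-condition paired master/slave sets on the common grid."""
    master, slave = st.generate_paired_sets(n_per_class=16, seed=11)
    grid = st.common_grid(master, slave)
    return (
        st.resample_to_grid(master, grid),
        st.resample_to_grid(slave, grid),
        grid,
    )


@pytest.fixture(scope="session")
def spxy_default_split(paired_sets):
    master, _, _ = paired_sets
    n_train = int(round(2 / 3 * master.n_samples))
    return st.spxy_split(master.spectra, master.labels, n_train)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
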