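import numpy as np
import pytest

from mtkit.transport import Trajectory


@pytest.fixture
def traj_from_speeds():
    """Factory: 1-D trajectory whose interval speeds equal the given list."""

    def make(speeds, dt=2.0, axis=(1.0, 0.0)):
        x = np.concatenate([[0.0], np.cumsum(np.asarray(speeds, float) * dt)])
        pos = np.column_stack([x, np.zeros_like(x)])
        return Trajectory("t", np.arange(len(x)) * dt, pos, axis=axis)

    return make


@pytest.fixture(scope="session")
def table2_psms():
    """The packaged exact-counts PSM fixture (three genotypes)."""
    from mtkit.pipeline import fixture_psm_table

    return fixture_psm_table(seed=0)
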