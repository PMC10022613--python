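import numpy as np
import pytest

from cavistress import synthesis


@pytest.fixture(scope="session")
def geometry():
    """One default procedural leaf, shared across tests (read-only)."""
    return synthesis.build_leaf_geometry(seed=1)


@pytest.fixture(scope="session")
def short_psi_series():
    """A half-day drydown ramp (145 frames at 5-min cadence), noiseless."""
    return synthesis.generate_psychrometer_series(
        psi0=-0.5, psi_end=-6.0, days=0.5, dt_min=5.0, noise_sd=0.0, seed=0
    )


@pytest.fixture(scope="session")
def full_psi_series():
    """The five-day study ramp, noiseless."""
    return synthesis.generate_psychrometer_series(seed=0)
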