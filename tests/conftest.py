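import numpy as np
import pytest
from hypothesis import settings

import caspike as cs
from caspike.gp import reference_intensity

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def unit_intensity():
    """x = 1 on [0, 10], delta 0.1."""
    return cs.IntensityGrid(np.ones(101), 0.1)


@pytest.fixture(scope="session")
def xdet_fine():
    """x_det on [0, 40] at delta 0.02 (simulation grid)."""
    return reference_intensity("x_det", 2000, 0.02)


@pytest.fixture(scope="session")
def xdet_coarse():
    """x_det on [0, 40] at delta 0.25 (inference grid)."""
    return reference_intensity("x_det", 160, 0.25)


@pytest.fixture(scope="session")
def ig_cells(xdet_fine):
    """50 IG(5.9) cells simulated from x_det, snapped to the fine grid."""
    from caspike.surrogate import simulate_ensemble, snap_sequence

    model = cs.ISIModel("IG", 5.9)
    seqs = simulate_ensemble(xdet_fine, model, "rescaling", m=50, seed=1234)
    return [snap_sequence(s, xdet_fine.delta) for s in seqs]
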