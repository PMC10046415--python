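import warnings

import numpy as np
import pytest

from thermowave.dielectric import load_tissue_table
from thermowave.forward import AntennaLayout, FrequencySet, MomForwardSolver
from thermowave.phantom import PhantomConfig, build_neck_phantom


@pytest.fixture(scope="session")
def tissue_table():
    return load_tissue_table()


@pytest.fixture(scope="session")
def default_phantom():
    return build_neck_phantom(PhantomConfig())


@pytest.fixture(scope="session")
def small_phantom():
    """Coarse 48x48 phantom for quick forward solves."""
    return build_neck_phantom(PhantomConfig(grid_n=48))


@pytest.fixture(scope="session")
def ring_layout():
    return AntennaLayout.default_ring()


@pytest.fixture(scope="session")
def small_solver(small_phantom, ring_layout):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return MomForwardSolver(
            small_phantom, ring_layout, FrequencySet(np.array([1.0e9, 1.35e9]))
        )


@pytest.fixture(scope="session")
def small_baseline_fields(small_phantom, small_solver):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return small_solver.solve(small_phantom)


@pytest.fixture(scope="session")
def cached_operator(small_baseline_fields, small_phantom):
    from thermowave.imaging import build_roi_operator

    return build_roi_operator(small_baseline_fields, small_phantom.tumor_roi)
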