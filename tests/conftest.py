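import numpy as np
import pytest

from hrfboost.design import build_design
from hrfboost.hrf import HRFParameters, canonical_hrf, informed_basis
from hrfboost.simulate import VoxelSimSpec, periodic_event_timeline


@pytest.fixture(scope="session")
def params():
    return HRFParameters()


@pytest.fixture(scope="session")
def canonical(params):
    return canonical_hrf(params)


@pytest.fixture(scope="session")
def basis(params):
    return informed_basis(params)


@pytest.fixture(scope="session")
def default_voxel_spec():
    return VoxelSimSpec()


@pytest.fixture(scope="session")
def events():
    return periodic_event_timeline(n_events=10)


@pytest.fixture(scope="session")
def design_canonical(default_voxel_spec, params):
    s = default_voxel_spec
    return build_design(s.events, s.tr, s.n_scans, params, basis="canonical")


@pytest.fixture(scope="session")
def design_informed(default_voxel_spec, params):
    s = default_voxel_spec
    return build_design(s.events, s.tr, s.n_scans, params, basis="informed")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
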