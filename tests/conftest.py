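import numpy as np
import pytest

from gpcrsel.geometry import build_reference
from gpcrsel.synth import make_reference_stub, stub_from_features


@pytest.fixture(scope="session")
def reference_stub():
    return make_reference_stub()


@pytest.fixture(scope="session")
def reference_orientations(reference_stub):
    return build_reference(reference_stub)


@pytest.fixture(scope="session")
def gs_stub():
    """A Gs-like receptor stub at the group-mean geometry (tip 5.73)."""
    return stub_from_features(23, 12.0, 23.8, structure_id="gs_mean", coupling_label="GS")


@pytest.fixture(scope="session")
def gi_stub():
    """A Gi/o-like receptor stub at the group-mean geometry (tip 5.69)."""
    return stub_from_features(19, 6.0, 19.7, structure_id="gio_mean", coupling_label="GIO")


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
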