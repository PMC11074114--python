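import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240506)


@pytest.fixture
def geometry():
    """Default surrogate slab: zero planes at 0.5 and 19.5 nm in a 20 nm box."""
    from spinatmos.trajectory import SlabGeometry
    return SlabGeometry(bottom_zero=0.5, top_zero=19.5)


@pytest.fixture
def mn_species_map():
    from spinatmos.dipolar import MN2P
    return {"Mn": MN2P, "Na": "diamagnetic", "Cl": "diamagnetic", "P": "diamagnetic"}


def make_frame(xyz, species="Mn", box=(1000.0, 1000.0, 1000.0), time=0.0):
    """Small helper used across test modules."""
    from spinatmos.trajectory import Frame
    xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
    if isinstance(species, str):
        species = [species] * len(xyz)
    return Frame(time=time, ids=np.arange(len(xyz)),
                 species=np.array(species, dtype=object), xyz=xyz, box=box)
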