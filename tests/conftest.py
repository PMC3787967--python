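import numpy as np
import pytest

from minidock import fixtures as fx


@pytest.fixture(scope="session")
def fig1_system():
    return fx.make_fig1_system()


@pytest.fixture(scope="session")
def planted_site():
    """One seeded planted binding site shared by engine-level tests."""
    return fx.make_planted_site(seed=1)


def random_sphere_system(rng, n_lig, n_rec, extent=6.0):
    from minidock.spheres import SphereSet
    return (SphereSet(rng.uniform(0, extent, size=(n_lig, 3))),
            SphereSet(rng.uniform(0, extent, size=(n_rec, 3))))
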