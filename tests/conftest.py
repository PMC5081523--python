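import numpy as np
import pytest

from chromosteer import builder, synthetic
from chromosteer.engine import ForceFieldParams


@pytest.fixture(scope="session")
def small_spec():
    """Two 3-Mb chromosomes with tracks and radial targets."""
    return synthetic.gen_genome_spec(2, 3_000_000, seed=7,
                                     nucleus_radius=1500.0)


@pytest.fixture(scope="session")
def small_disc(small_spec):
    return builder.discretize_genome(small_spec)


@pytest.fixture()
def ff_params():
    return ForceFieldParams()


@pytest.fixture(scope="session")
def free_chain_factory():
    """Factory for an unconfined single-chain system of n beads."""
    from chromosteer.system import BeadSystem, Chain

    def make(n_beads, coords=None, centromere=None, nucleus_radius=np.inf):
        if coords is None:
            coords = builder.build_rosette(n_beads, n_loop=21,
                                           petals_per_turn=8)
        cen = np.zeros(n_beads, dtype=bool)
        if centromere is not None:
            cen[centromere] = True
        return BeadSystem([Chain("chrT", 0, 0, n_beads)], coords, cen,
                          nucleus_radius=nucleus_radius)

    return make
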