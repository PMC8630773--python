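import numpy as np
import pytest

from cryofit.fixtures import FixtureSpec, Segment, make_toy_structure, simulate_experimental_map
from cryofit.io import Atom, AtomicModel, DensityMap
from cryofit.simulate import SimulationParams


@pytest.fixture
def small_map():
    """Deterministic random 4x4x4 map with unit voxels."""
    rng = np.random.default_rng(42)
    return DensityMap(rng.random((4, 4, 4)), [1.0, 1.0, 1.0], [0.0, 0.0, 0.0])


@pytest.fixture
def tripeptide():
    """Three-residue single-chain peptide with CA atoms only."""
    atoms = [
        Atom("A", i + 1, "GLY", "CA", "C", [3.0 * i + 2.0, 5.0, 5.0])
        for i in range(3)
    ]
    return AtomicModel(atoms)


@pytest.fixture(scope="session")
def standard_spec():
    """The standard mixed-architecture single-chain benchmark condition."""
    return FixtureSpec(
        chains=((Segment("helix", 12), Segment("loop", 6), Segment("strand", 8)),),
        resolution=3.0,
        noise_sd=0.05,
        seed=1,
    )


@pytest.fixture(scope="session")
def standard_truth(standard_spec):
    return make_toy_structure(standard_spec)


@pytest.fixture(scope="session")
def standard_map(standard_spec, standard_truth):
    return simulate_experimental_map(standard_truth, standard_spec)


@pytest.fixture(scope="session")
def sim_params(standard_spec):
    return SimulationParams(resolution=standard_spec.resolution)
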