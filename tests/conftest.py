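import numpy as np
import pytest

from kvphasegen.phasespace import ParticleBatch, PhaseSpace
from kvphasegen.source import SourceConfig, sample_source_phase_space


def make_batch(n: int, seed: int = 0, kvp: float = 100.0) -> ParticleBatch:
    """Small valid particle batch with mildly divergent directions."""
    rng = np.random.default_rng(seed)
    tx = rng.uniform(-0.1, 0.1, n)
    ty = rng.uniform(-0.1, 0.1, n)
    norm = np.sqrt(tx**2 + ty**2 + 1)
    return ParticleBatch(
        x=rng.uniform(-50, 50, n),
        y=rng.uniform(-50, 50, n),
        dx=tx / norm,
        dy=ty / norm,
        dz=1.0 / norm,
        e=rng.uniform(15.0, kvp, n),
    )


@pytest.fixture
def small_batch() -> ParticleBatch:
    return make_batch(1000, seed=1)


@pytest.fixture
def small_phase_space(small_batch) -> PhaseSpace:
    return PhaseSpace(small_batch, kvp_label=100, z_plane=500.0)


@pytest.fixture(scope="session")
def source_ps_100() -> PhaseSpace:
    """A medium synthetic 100 kV phase space shared across tests."""
    return sample_source_phase_space(SourceConfig(kvp=100), 40_000, seed=11)
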