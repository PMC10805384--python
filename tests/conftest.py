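import numpy as np
import pytest

from thalcort.meanfield import (ExternalInput, ModelConfig, Population,
                                Projection)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def single_population_config(alpha=20.0, beta=80.0, drive=0.0, noise=0.0,
                             coupling=0.0, duration=5.0, dt=1e-4):
    """One population with a single self-projection: the smallest model."""
    pop = Population("cortex_excitatory", Q_max=300.0, theta=0.014,
                     sigma_prime=0.0038, alpha=alpha, beta=beta)
    proj = Projection("cortex_excitatory", "cortex_excitatory",
                      coupling_strength=coupling, delay=0.002)
    return ModelConfig(
        populations=(pop,), projections=(proj,),
        external={"cortex_excitatory": ExternalInput(drive, noise)},
        dt=dt, duration=duration,
    )


@pytest.fixture(scope="session")
def waking_small():
    """Waking preset trimmed to a short duration for fast tests."""
    from thalcort.presets import waking_config
    return waking_config(duration=5.0)
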