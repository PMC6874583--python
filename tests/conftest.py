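import numpy as np
import pytest

from trodnet import assembly, simulate
from trodnet.model import ModelConfig, build_model, train


@pytest.fixture(scope="session")
def default_paradigm():
    return simulate.ParadigmSpec()


@pytest.fixture(scope="session")
def components():
    return simulate.default_components()


@pytest.fixture(scope="session")
def tiny_cohort():
    """4 + 4 subjects with a strong effect and mild noise; session-scoped
    because epoch synthesis dominates the unit tests' runtime."""
    return simulate.generate_cohort(
        4,
        4,
        effect=simulate.EffectSpec.strong(),
        noise=simulate.NoiseParams(pink_scale=2.0, alpha_scale=1.5, white_scale=1.0),
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_tensor(tiny_cohort):
    return assembly.assemble_cohort(tiny_cohort, seed=8)


@pytest.fixture(scope="session")
def small_model_config():
    """A reduced network for mechanics tests (full input geometry, fewer
    steps)."""
    return ModelConfig(n_steps=40, batch_size=64)


@pytest.fixture(scope="session")
def trained_tiny_model(tiny_tensor, small_model_config):
    std = assembly.fit_standardizer(tiny_tensor)
    Z = std.transform(tiny_tensor)
    model = build_model(small_model_config, seed=3)
    train(model, Z.X, Z.labels, seed=4)
    return model, std, Z


def separable_observations(n_per_class=5, seed=0, scale=3.0):
    """Linearly separable toy observations on the real input geometry."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((2 * n_per_class, 192, 332)).astype(np.float32)
    y = np.repeat([0, 1], n_per_class)
    X[y == 1, 64:128, 100:150] += scale  # class signal in the FDev block
    return X, y
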