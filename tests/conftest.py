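import numpy as np
import pytest

from cytomil.profiles import train_reduced_mil, train_reduced_patch_classifier


@pytest.fixture(scope="session")
def patch_run():
    """Reduced-scale patch-CNN training on synthetic data (shared by the
    end-to-end recovery and Grad-CAM localization tests)."""
    return train_reduced_patch_classifier(seed=0)


@pytest.fixture(scope="session")
def mil_run():
    """Reduced-scale AD-MIL training on synthetic bags with known signal
    slots."""
    return train_reduced_mil(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def perturb_biases(model_or_layers, rng, scale=0.05):
    """Give all biases small nonzero values. Finite-difference gradient
    checks need this: with zero biases, dead ReLU regions upstream put
    downstream pre-activations exactly on the ReLU kink, where central
    differences measure half-slopes."""
    layers = getattr(model_or_layers, "_all_layers", lambda: model_or_layers)()
    for layer in layers:
        if "b" in layer.params:
            layer.params["b"][...] = rng.normal(0, scale, layer.params["b"].shape)
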