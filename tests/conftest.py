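import numpy as np
import pytest

from nodulefab import NoduleRecipe, ResponseRecipe, make_synthetic_nodule_volume
from nodulefab.synthetic import make_synthetic_responses


@pytest.fixture(scope="session")
def clean_nodule():
    """Noiseless concentric-sphere nodule volume plus ground truth."""
    recipe = NoduleRecipe(noise_sd_hu=0.0, seed=0)
    vol, truth = make_synthetic_nodule_volume(recipe)
    return recipe, vol, truth


@pytest.fixture(scope="session")
def guessing_responses():
    """1071 responses from readers operating exactly at chance."""
    recipe = ResponseRecipe(
        sensitivity={"senior": 0.5, "resident": 0.5},
        specificity={"senior": 0.5, "resident": 0.5},
        seed=42,
    )
    return make_synthetic_responses(recipe)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
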