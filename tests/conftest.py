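import pytest

from mirella import (
    TranslationParams,
    default_translation_params,
    default_degradation_params,
)
from mirella.sampling import random_translation_params  # noqa: F401 (test helper)


@pytest.fixture
def tparams() -> TranslationParams:
    return default_translation_params()


@pytest.fixture
def dparams():
    return default_degradation_params()
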