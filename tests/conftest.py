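import math

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from nocisyn import GeneratorConfig, gen_single_drug  # noqa: E402

MORPHINE_ED50 = 2.3  # mg/kg
MORPHINE_DOSES = (0.3, 1.0, 3.0, 10.0)


@pytest.fixture
def morphine_config():
    """Generator settings emulating a morphine-alone formalin experiment."""
    return GeneratorConfig(
        seed=42,
        true_log_ed50=math.log10(MORPHINE_ED50),
        doses=MORPHINE_DOSES,
    )


@pytest.fixture
def morphine_dataset(morphine_config):
    return gen_single_drug(morphine_config, drug="morphine")
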