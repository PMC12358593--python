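import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from capsorb import (  # noqa: E402
    IsothermParams,
    KineticParams,
    SorptionDataset,
    evaluate_isotherm,
)

# Published fit parameters used repeatedly as ground truth in round trips.
SMITH_25 = IsothermParams("Smith", {"a": -8.05, "b": -17.01})
SMITH_37 = IsothermParams("Smith", {"a": -2.63, "b": -7.98})
GAB_32 = IsothermParams("GAB", {"k": 0.89, "c": 13.17, "x0": 177.03})
FIRST_ORDER_25 = KineticParams("first_order", {"a": 8.48, "b": 2.05})
FIRST_ORDER_37 = KineticParams("first_order", {"a": 7.13, "b": 2.40})

AW_25 = (0.45, 0.62, 0.73, 0.79, 0.88, 0.92)
AW_32 = (0.46, 0.61, 0.72, 0.77, 0.84, 0.92)


@pytest.fixture
def smith25_dataset() -> SorptionDataset:
    """Noise-free sorption data generated from the 25 degC Smith truth."""
    aw = np.array(AW_25)
    return SorptionDataset(
        temperature_k=298.15,
        points=tuple(zip(aw.tolist(), evaluate_isotherm(SMITH_25, aw).tolist())),
    )


@pytest.fixture
def gab32_dataset() -> SorptionDataset:
    """Noise-free sorption data generated from the 32 degC GAB truth."""
    aw = np.array(AW_32)
    return SorptionDataset(
        temperature_k=305.15,
        points=tuple(zip(aw.tolist(), evaluate_isotherm(GAB_32, aw).tolist())),
    )
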