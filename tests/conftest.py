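import numpy as np
import pytest

from ocupk import OneCompartmentFit, calibrate_from_summary

# Published summary parameters of the two treatment arms: ganciclovir
# chitosan microspheres (test) and plain ganciclovir solution (reference).
GCM = {"ka": 0.7252, "ke": 0.1233, "cmax": 51.23, "auc_0_24": 607.187,
       "auc_0_inf": 645.116}
SOLUTION = {"ka": 1.2981, "ke": 0.1662, "cmax": 18.98, "auc_0_24": 121.634,
            "auc_0_inf": 137.692}
MIC90 = 1.22


@pytest.fixture(scope="session")
def gcm_fit() -> OneCompartmentFit:
    return calibrate_from_summary(GCM["ka"], GCM["ke"], GCM["cmax"])


@pytest.fixture(scope="session")
def solution_fit() -> OneCompartmentFit:
    return calibrate_from_summary(SOLUTION["ka"], SOLUTION["ke"], SOLUTION["cmax"])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)
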