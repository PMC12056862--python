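import numpy as np
import pytest

from scdsim import (
    InterventionParams,
    RiskFactor,
    RiskFactorTable,
    SimulationConfig,
    default_risk_table,
)

#: (name, prevalence, rrr, modifiable, effectiveness) — published 12-factor set.
PUBLISHED_ROWS = [
    ("Low education", 0.20, 0.07, False, None),
    ("Hearing loss", 0.30, 0.08, True, 0.50),
    ("Hypertension", 0.40, 0.02, True, 0.70),
    ("Smoking", 0.25, 0.05, True, 0.60),
    ("Obesity", 0.30, 0.01, True, 0.40),
    ("Depression", 0.20, 0.04, True, 0.50),
    ("Physical inactivity", 0.50, 0.03, True, 0.50),
    ("Diabetes", 0.25, 0.01, True, 0.50),
    ("Excessive alcohol use", 0.15, 0.01, True, 0.50),
    ("Traumatic brain injury", 0.10, 0.03, False, None),
    ("Air pollution", 0.30, 0.02, True, 0.30),
    ("Social isolation", 0.40, 0.04, True, 0.60),
]


@pytest.fixture(scope="session")
def table():
    return default_risk_table()


@pytest.fixture(scope="session")
def params():
    return InterventionParams()


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_table():
    """Two-factor table small enough for brute-force cross-checks."""
    return RiskFactorTable(
        (
            RiskFactor("alpha", prevalence=0.4, rrr=0.3, modifiable=True, effectiveness=0.6),
            RiskFactor("beta", prevalence=0.25, rrr=0.5, modifiable=True, effectiveness=0.3),
        )
    )
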