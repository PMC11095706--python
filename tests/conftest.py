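import numpy as np
import pytest

from metanat import (GrowthParams, KPDParams, MetParams, Schedule,
                     default_population)


@pytest.fixture(scope="session")
def median_growth() -> GrowthParams:
    """Published median growth constants for the LM2-4 ortho-surgical model."""
    return GrowthParams(alpha=1.94, beta=0.0911, lam=0.837, V0=1.0, Vi=1.0e6)


@pytest.fixture(scope="session")
def median_kpd() -> KPDParams:
    return KPDParams(k=0.446, ke=3.26, Vd=12.0)


@pytest.fixture(scope="session")
def median_met() -> MetParams:
    return MetParams(mu=2.12e-11)


@pytest.fixture(scope="session")
def pm_default():
    return default_population()


@pytest.fixture(scope="session")
def control_schedule() -> Schedule:
    """Untreated arm of the regimen grid: detection and surgery at day 27."""
    return Schedule(doses=(), resection_day=27.0, horizon=85.0)
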