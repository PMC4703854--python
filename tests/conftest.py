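import math

import numpy as np
import pytest

import forestedge as fe


@pytest.fixture(scope="session")
def noiseless_scenario():
    return fe.SyntheticScenario(rows=100, cols=100, theta1=300.0, theta2=150.0,
                                theta3=2.0, noise_sd=0.0, n_clearings=5,
                                n_tendrils=2, seed=1)


@pytest.fixture(scope="session")
def noiseless_landscape(noiseless_scenario):
    """Mask, distance field and noiseless biomass for one synthetic tile."""
    scen = noiseless_scenario
    mask = fe.generate_mask(scen)
    dist = fe.distance_to_edge(mask, scen.pixel_size_km)
    biomass = fe.generate_biomass(mask, dist, scen)
    return scen, mask, dist, biomass


def scenario_from_metrics(theta1: float, m_true: float, a_true: float, **kw):
    """Invert (M, A(90)) to (theta2, theta3) and build a scenario.

    From A = ln(theta2 / (0.1 theta1)) / theta3 and
    M = theta2 exp(-0.232 theta3) / theta1:
    theta3 = ln(10 M) / (A - 0.232), theta2 = 0.1 theta1 exp(A theta3).
    Requires M > 0.1 and A > 0.232.
    """
    theta3 = math.log(10.0 * m_true) / (a_true - 0.232)
    theta2 = 0.1 * theta1 * math.exp(a_true * theta3)
    return fe.SyntheticScenario(theta1=theta1, theta2=theta2, theta3=theta3, **kw)
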