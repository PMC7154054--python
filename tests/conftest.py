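import numpy as np
import pytest

import colicarb as cc
from colicarb.network import RegulationMap, TFActivities


@pytest.fixture(scope="session")
def params():
    return cc.default_parameters()


@pytest.fixture(scope="session")
def regmap(params):
    return RegulationMap.from_parameters(params)


@pytest.fixture
def wt():
    return cc.Genotype()


@pytest.fixture
def mid_tfs():
    return TFActivities(crp=0.5, cra=0.5, arca=0.2, xylr=0.5)


@pytest.fixture(scope="session")
def reference_state(params):
    """A fixed physiological state used for flux-oracle comparisons."""
    state = cc.NetworkState(
        G6P=1.2, F6P=0.45, FBP=0.8, GAP=0.3, PEP=1.5, PYR=2.0, ACCOA=0.6,
        P6G=0.15, RU5P=0.12, X5P=0.18, R5P=0.1, S7P=0.08, E4P=0.06,
        ICIT=0.2, AKG=0.4, SUC=0.5, FUM=0.3, MAL=0.9, OAA=0.05, GLX=0.02,
        XYLIN=0.3, XYLU=0.2, AACOA=0.05, HMGCOA=0.03,
        ATP=2.5, ADP=1.5, AMP=0.3, NADH=0.2, NAD=1.75, NADPH=0.15, NADP=0.35,
        GLC=2.0, XYL=3.0, ACE=0.3, MVA=0.1, X=1.0,
    )
    return state


@pytest.fixture(scope="session")
def wt_batch_trajectory(params):
    """One WT aerobic batch on 5+5 g/l glucose/xylose, shared across tests."""
    scenario = cc.CultureScenario(glucose=5.0, xylose=5.0, horizon=40.0)
    return cc.simulate_batch(scenario, cc.Genotype(), params)


def rng(seed=0):
    return np.random.default_rng(seed)
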