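"""Shared fixtures.

Small hand-built networks for exact checks, plus session-scoped ensembles at
the full study size (300-node network, 50 replicates, 365 days) shared by the
acceptance-level tests so the expensive scenario runs happen once.
"""

import numpy as np
import pytest
from hypothesis import settings

import streamspom as sp
from streamspom.experiments import ScenarioConfig, run_scenario, sensitivity_analysis

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


def make_chain(n: int, spacing: float = 100.0, width: float = 2.0) -> sp.StreamNetwork:
    """A straight chain 0 ← 1 ← ... ← n−1 with node 0 as outlet."""
    net = sp.StreamNetwork(
        downstream=np.array([-1] + list(range(n - 1)), dtype=np.int64),
        xy=np.column_stack([np.arange(n) * spacing, np.zeros(n)]),
        reach_length=np.full(n, spacing),
        cell_area=np.full(n, spacing**2),
        cell_size=spacing,
    )
    net.area = sp.compute_contributing_area(net)
    net.width = np.full(n, width)
    return net


@pytest.fixture
def chain3():
    return make_chain(3)


@pytest.fixture
def small_net():
    """A ~60-node generated network with all attributes attached."""
    net = sp.generate_network(60, cell_size=100.0, seed=11)
    net.slope = sp.assign_slopes(net, seed=12)
    net.twi = sp.compute_twi(net)
    net.width = sp.compute_width(net)
    return net


@pytest.fixture(scope="session")
def intermediate_climate():
    return sp.ClimateParams.preset("intermediate")


@pytest.fixture(scope="session")
def nine_scenarios():
    """Full Monte-Carlo ensembles for the 3 climates × 3 persistency scenarios."""
    results = {}
    for scen in ("area", "twi", "random"):
        for clim in ("wet", "intermediate", "dry"):
            cfg = ScenarioConfig(climate=clim, scenario=scen, base_seed=1)
            results[(clim, scen)] = run_scenario(cfg)
    return results


@pytest.fixture(scope="session")
def sensitivity_maps():
    """Reduced 5×5 (c, e) survival grids, 20 replicates, all three climates."""
    grids = {}
    for clim in ("wet", "intermediate", "dry"):
        cfg = ScenarioConfig(climate=clim, scenario="area", base_seed=3)
        grids[clim] = sensitivity_analysis(
            cfg, c_grid=np.logspace(-5, 2, 5), e_grid=np.logspace(-3, 3, 5), n_mc=20
        )
    return grids
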