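import numpy as np
import pytest

import seabed_era as se


@pytest.fixture()
def chain_net():
    """Two-node chain A -> B with P(a1)=0.3, P(b1|a1)=0.9, P(b1|a2)=0.5."""
    variables = {
        "A": se.Variable("A", ("a1", "a2")),
        "B": se.Variable("B", ("b1", "b2")),
    }
    cpts = {
        "A": se.Cpt("A", (), np.array([[0.3, 0.7]])),
        "B": se.Cpt("B", ("A",), np.array([[0.9, 0.1], [0.5, 0.5]])),
    }
    return se.Network(variables=variables, cpts=cpts)


@pytest.fixture(scope="session")
def default_model():
    config = se.default_config()
    net = se.assemble_network(config)
    return config, net


@pytest.fixture(scope="session")
def scenario_runs(default_model):
    """Pressure and impact records for both shipped scenarios."""
    config, net = default_model
    return {
        name: se.run_scenario(net, config.scenario(name), config)
        for name in ("high", "intermediate")
    }
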