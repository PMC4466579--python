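import numpy as np
import pytest

import vegftraffic as vt


@pytest.fixture(scope="session")
def full_net():
    return vt.build_network()


@pytest.fixture(scope="session")
def reduced_net():
    """Phospho-free (marginalized) network."""
    return vt.build_network(include_phospho=False)


@pytest.fixture(scope="session")
def other_vb_tc(full_net):
    """Immobilized VEGF, 20 ng/mL, HUVEC configuration, 30 min."""
    proto = vt.make_scenario(
        "other", mode="immobilized", vegf_ng_ml=20.0, duration_s=1800.0
    )
    return vt.simulate(proto, full_net)


@pytest.fixture(scope="session")
def other_vs_tc(full_net):
    """Soluble VEGF, 20 ng/mL, HUVEC configuration, 30 min."""
    proto = vt.make_scenario(
        "other", mode="soluble", vegf_ng_ml=20.0, duration_s=1800.0
    )
    return vt.simulate(proto, full_net)
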