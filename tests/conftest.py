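import numpy as np
import pytest

import zrm
from zrm import presets


@pytest.fixture(scope="session")
def xt5():
    return presets.CAPSULES["XT5"]


@pytest.fixture(scope="session")
def xt140():
    return presets.CAPSULES["XT140"]


@pytest.fixture(scope="session")
def spreading():
    return presets.get_binding("XT5-spreading")


@pytest.fixture(scope="session")
def langmuir():
    return presets.get_binding("XT5-langmuir")


@pytest.fixture(scope="session")
def xt5_spreading_curve(spreading):
    """Binding breakthrough of the calibrated axial capsule (reference run)."""
    topo = presets.get_topology("XT5-2zone")
    cond = zrm.RunConditions(c0=1.0, Q=topo.Q, t_end=900.0, dt_out=1.0)
    return zrm.simulate_breakthrough(topo, spreading, cond, keep_state=True)


@pytest.fixture(scope="session")
def nonbinding_curves():
    """Fine-grid non-binding simulations of all flow presets, for moment tests."""
    out = {}
    for name, dt in [("XT5-1zone", 0.05), ("XT5-2zone", 0.05),
                     ("XT140-sym", 0.2), ("XT140-asym", 0.2)]:
        topo = presets.get_topology(name)
        cond = zrm.RunConditions(c0=1.0, Q=topo.Q, t_end=120.0, dt_out=dt)
        out[name] = (topo, zrm.simulate_breakthrough(topo, None, cond))
    return out
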