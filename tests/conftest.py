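import numpy as np
import pytest

import porekinetics as pk


@pytest.fixture(scope="session")
def hsumo1_scheme():
    return pk.sensor_scheme("hsumo1")


@pytest.fixture(scope="session")
def egfr_scheme():
    return pk.sensor_scheme("egfr")


@pytest.fixture(scope="session")
def hsumo1_sim(hsumo1_scheme):
    """A 30 s hSUMO1-like recording at 130 nM with its generator truth."""
    conc = 130e-9
    path = pk.simulate_path(hsumo1_scheme, conc, 30.0, seed=42)
    cfg = pk.TraceConfig(duration=30.0, noise_sigma=1.0, concentration=conc, seed=43)
    trace = pk.render_trace(path, hsumo1_scheme, cfg)
    return {"path": path, "trace": trace, "scheme": hsumo1_scheme, "concentration": conc}


@pytest.fixture(scope="session")
def hsumo1_events(hsumo1_sim):
    baseline = pk.estimate_baseline(hsumo1_sim["trace"])
    events = pk.detect_events(hsumo1_sim["trace"], baseline, deepest_level=2.9)
    return {"baseline": baseline, "events": events, **hsumo1_sim}
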