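import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import scoredif as sd

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def null_2pl():
    """Null (no DIF, no impact) 2PL dataset with its converged MML fit."""
    cfg = sd.StudyConfig(
        model="2PL", n_persons=2000, n_items=10, covariate="categorical",
        impact=False, dif="none", seed=42,
    )
    ds = sd.generate_dataset(cfg, 0)
    fitted = sd.fit(ds.data, model="2PL", method="MML")
    return ds, fitted


@pytest.fixture(scope="session")
def map_3pl():
    """Null 3PL dataset fitted by MAP with the agreeing prior."""
    cfg = sd.StudyConfig(
        model="3PL", n_persons=2000, n_items=10, covariate="categorical",
        impact=False, dif="none", seed=43,
    )
    ds = sd.generate_dataset(cfg, 0)
    fitted = sd.fit(ds.data, model="3PL", method="MAP",
                    prior=sd.PriorSpec.agreeing())
    return ds, fitted


@pytest.fixture()
def rng(request):
    """Per-test deterministic generator, independent of execution order."""
    import zlib

    return np.random.default_rng(
        zlib.crc32(request.node.nodeid.encode()) & 0x7FFFFFFF
    )
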