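import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def sync_text():
    """A tiny two-pool sync fixture: 3 sites on 2 scaffolds."""
    return (
        "sc1\t100\tA\t10:0:5:0:0:0\t15:0:0:0:0:0\n"
        "sc1\t200\tG\t0:0:0:30:0:0\t12:18:0:0:0:0\n"
        "sc2\t50\tT\t0:20:0:20:1:2\t5:5:5:5:0:0\n"
    )


@pytest.fixture
def sync_file(tmp_path, sync_text):
    p = tmp_path / "pools.sync"
    p.write_text(sync_text)
    return p
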