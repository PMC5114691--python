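import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sync_lines():
    """Canonical 4-population sync fixture (tab-separated text)."""
    return [
        "2L\t5002\tA\t58:0:0:2:0:0\t30:0:0:30:0:0\t40:0:0:5:0:0\t33:0:0:12:0:0",
        "2L\t5009\tT\t0:60:0:0:0:0\t0:55:5:0:0:0\t0:44:8:0:1:0\t0:50:9:0:0:1",
        "2R\t17\tG\t10:0:0:50:0:0\t12:0:0:48:0:0\t9:0:0:51:0:0\t20:0:0:40:0:0",
        "3R\t999999\tC\t0:0:61:0:0:0\t0:0:59:1:0:0\t0:4:56:0:0:0\t0:0:60:0:2:0",
    ]


@pytest.fixture
def sync_file(tmp_path, sync_lines):
    path = tmp_path / "fixture.sync"
    path.write_text("\n".join(sync_lines) + "\n")
    return path
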