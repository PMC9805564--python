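import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)


@pytest.fixture
def toy_gmt(tmp_path):
    path = tmp_path / "toy.gmt"
    path.write_text(
        "SETA\tfirst set\tG1\tG2\tG3\n"
        "SETB\t\tG2\tG4\tG5\tG6\n",
        encoding="utf-8",
    )
    return path


@pytest.fixture
def toy_rnk(tmp_path):
    path = tmp_path / "toy.rnk"
    path.write_text("A\t1.0\nB\t3.0\nC\t-2.0\n", encoding="utf-8")
    return path
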