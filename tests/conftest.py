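import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def decay_csv(tmp_path):
    """A small noiseless exponential-decay CSV (header time_s,signal)."""
    t = np.arange(0.0, 11.0)
    s = 100.0 * np.exp(-t / 13.3)
    path = tmp_path / "decay.csv"
    lines = ["time_s,signal"] + [f"{ti},{si}" for ti, si in zip(t, s)]
    path.write_text("\n".join(lines) + "\n")
    return path
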