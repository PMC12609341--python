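import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from climres import SyntheticConfig, generate_panel
from climres.panel_ops import interpolate_missing


@pytest.fixture(scope="session")
def default_panel():
    """One default 30x12 synthetic panel with its truth (missing repaired)."""
    panel, truth = generate_panel(SyntheticConfig(seed=0))
    return interpolate_missing(panel.frame), truth


@pytest.fixture(scope="session")
def clean_panel():
    """Default panel generated without missing values."""
    panel, truth = generate_panel(SyntheticConfig(seed=1, missing_rate=0.0))
    return panel.frame, truth
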