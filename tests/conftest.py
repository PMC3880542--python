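import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from notchscreen import ExpressionMatrix
from notchscreen.synthetic import GroundTruth, default_ground_truth

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def truth() -> GroundTruth:
    return default_ground_truth(seed=11)


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """4 genes x 4 samples, hand-checkable intensities."""
    data = pd.DataFrame(
        {
            "control_1": [10.0, 20.0, 30.0, 40.0],
            "control_2": [100.0, 200.0, 300.0, 400.0],
            "treated_1": [20.0, 10.0, 30.0, 40.0],
            "treated_2": [200.0, 100.0, 300.0, 400.0],
        },
        index=pd.Index(["gA", "gB", "gC", "gD"], name="gene"),
    )
    cond = pd.Series(
        ["control", "control", "treated", "treated"], index=data.columns
    )
    return ExpressionMatrix(data, cond)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
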