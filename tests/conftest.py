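import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from kinfiber import CalibrationParams, ViniTable

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


@pytest.fixture
def params() -> CalibrationParams:
    """Indo-1-like calibration constants used across fiber tests."""
    return CalibrationParams(kd_um=0.25, beta=3.0, r_min=0.2, r_max=1.0)


def make_vini(values: dict[str, list[float]], conditions: dict[str, str]) -> ViniTable:
    """Small hand-built velocity table (wells as dict keys)."""
    df = pd.DataFrame(values)
    df.index = [f"P{i + 1:03d}" for i in range(len(df))]
    df.index.name = "peptide_id"
    wells = pd.DataFrame(
        {
            "condition": pd.Series(conditions),
            "replicate": np.arange(1, len(conditions) + 1),
        }
    ).loc[df.columns]
    wells.index.name = "well_id"
    return ViniTable(values=df, wells=wells)
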