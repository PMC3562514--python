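import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from mirhost import DesignTable, ExpressionMatrix, make_paired_dataset


@pytest.fixture(scope="session")
def paired_dataset():
    """Shared synthetic paired dataset at the default geometry."""
    return make_paired_dataset(seed=1)


@pytest.fixture
def small_matrix():
    data = pd.DataFrame(
        np.array(
            [
                [5.0, 5.1, 5.2, 7.0, 7.1, 7.2],
                [6.0, 6.2, 6.1, 6.1, 6.0, 6.2],
                [8.0, 8.1, 7.9, 6.0, 6.1, 5.9],
            ]
        ),
        index=["g1", "g2", "g3"],
        columns=[f"s{i}" for i in range(6)],
    )
    return ExpressionMatrix(data, role="mrna")


@pytest.fixture
def two_group_design():
    return DesignTable(
        pd.Series(
            ["ctrl", "ctrl", "ctrl", "case", "case", "case"],
            index=[f"s{i}" for i in range(6)],
        )
    )
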