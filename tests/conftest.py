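from __future__ import annotations

import numpy as np
import pytest

from netpsych import (
    ResponseTable,
    VariableSchema,
    default_item_spec,
    default_study_spec,
    sample_responses,
)
from netpsych.impute import impute


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_table():
    """3 participants x 2 ordinal variables with one missing cell."""
    schema = [
        VariableSchema("a", "ordinal", levels=5),
        VariableSchema("b", "ordinal", levels=3),
    ]
    values = np.array([[0.0, 2.0], [4.0, np.nan], [2.0, 1.0]])
    mask = np.isnan(values)
    return ResponseTable(values=values, missing_mask=mask, schema=schema)


@pytest.fixture(scope="session")
def item_sample():
    """Default 14-item synthetic draw at the study's sample size."""
    return sample_responses(default_item_spec(n=400, seed=7))


@pytest.fixture(scope="session")
def item_table_complete(item_sample):
    return impute(item_sample.table, method="mode_median")


@pytest.fixture(scope="session")
def study_sample():
    """Items + 10 covariates draw at the study's dimensions."""
    return sample_responses(default_study_spec(n=400, seed=11))
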