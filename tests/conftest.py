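"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import pytest

from caspcleave import (
    CleavageModel,
    ModelConfig,
    build_training_set,
    make_fixture,
)
from caspcleave.pwm import compute_background
from caspcleave.structure import predict_structures


@pytest.fixture(scope="session")
def tiny_fixture():
    """10 synthetic proteins carrying 20 planted cleavage sites."""
    return make_fixture("tiny")


@pytest.fixture(scope="session")
def tiny_training_set(tiny_fixture):
    return build_training_set(list(tiny_fixture.records), list(tiny_fixture.annotations))


@pytest.fixture(scope="session")
def ratio_fixture():
    """40 proteins, 150 sites: big enough for stable classifier behavior."""
    return make_fixture("ratio")


@pytest.fixture(scope="session")
def small_model(ratio_fixture):
    """A fitted small random forest shared across prediction tests."""
    records = list(ratio_fixture.records)
    ts = build_training_set(records, list(ratio_fixture.annotations))
    model = CleavageModel.from_training_data(
        records, ts, ModelConfig(n_trees=150, seed=11)
    )
    return model.fit()


@pytest.fixture(scope="session")
def ratio_records(ratio_fixture):
    return list(ratio_fixture.records)
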