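"""Shared fixtures: one synthetic cohort and one fitted pipeline per session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from adrelabel import (
    ClusterRelabelModel,
    FeatureTable,
    LabelSet,
    SyntheticConfig,
    generate_dataset,
    run_preprocess,
)

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("suite")

SEED = 1  # fixed seed for every expensive session fixture


@pytest.fixture(scope="session")
def default_dataset():
    """Default 559-sample cohort (Table-style composition, 6% missing)."""
    return generate_dataset(SyntheticConfig(seed=SEED))


@pytest.fixture(scope="session")
def processed_table(default_dataset):
    return run_preprocess(default_dataset.table)


@pytest.fixture(scope="session")
def fitted(default_dataset, processed_table):
    """Full embed -> cluster -> relabel fit on the default cohort."""
    model = ClusterRelabelModel(processed_table, default_dataset.labels,
                                preprocessed=True)
    return model.fit(seed=SEED)


def make_table(data: dict, blocks: dict | None = None,
               kinds: dict | None = None, index=None) -> FeatureTable:
    """Small hand-built FeatureTable; untagged columns default to numeric cfa."""
    df = pd.DataFrame(data, index=index)
    if df.index.name is None:
        df.index = pd.Index([f"S{i:02d}" for i in range(len(df))],
                            name="sample_id")
    blocks = {**{c: "cfa" for c in df.columns}, **(blocks or {})}
    kinds = {**{c: "numeric" for c in df.columns}, **(kinds or {})}
    return FeatureTable(df, blocks, kinds)


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)
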