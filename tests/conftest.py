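"""Shared fixtures: small synthetic datasets and a quickly trained model.

Everything is generated at test time; nothing is read from checked-in
binary fixtures.  The session-scoped model fixture is deliberately tiny
(it backs smoke/unit tests, not the acceptance experiments).
"""

from __future__ import annotations

import numpy as np
import pytest

from m6awin.dataset import BuilderConfig, build_dataset
from m6awin.model import ModelConfig, build_model, train
from m6awin.simulate import SimConfig, simulate

TINY_MODEL_CONFIG = dict(
    filter_counts=(8, 4),
    blstm_units=8,
    fc_units=8,
    batch_size=32,
    learning_rate=1e-2,
    blstm_reduction="mean",
    max_epochs=8,
    patience=8,
    dropout_rate=0.1,
)


@pytest.fixture(scope="session")
def sim_small():
    return simulate(SimConfig(n_transcripts=80, seed=42, sites_min=1, sites_max=1))


@pytest.fixture(scope="session")
def dataset_small(sim_small):
    return build_dataset(
        sim_small.fasta, sim_small.sites, BuilderConfig(seed=42)
    )


@pytest.fixture(scope="session")
def trained_small(dataset_small):
    """A small model trained for a few epochs on the small dataset."""
    config = ModelConfig(seed=42, **TINY_MODEL_CONFIG)
    model = build_model(config)
    record = train(
        model, dataset_small.subset("train"), dataset_small.subset("val"), config
    )
    return model, record


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
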