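"""Shared fixtures: deterministic synthetic graphs and one pre-trained
model reused across evaluation-layer tests (training is the slow part)."""

import numpy as np
import pytest

from snolink import (AssociationModel, SyntheticSpec, TrainConfig,
                     fixture_suite, generate, make_split)


@pytest.fixture(scope="session")
def suite():
    return fixture_suite()


@pytest.fixture(scope="session")
def tiny_graph(suite):
    return suite["tiny"]


@pytest.fixture(scope="session")
def sim_sample(suite):
    return suite["similarity_dominant"]


@pytest.fixture(scope="session")
def balanced_sample(suite):
    return suite["balanced"]


@pytest.fixture(scope="session")
def pop_sample(suite):
    return suite["popularity_dominant"]


@pytest.fixture(scope="session")
def fast_config():
    """Scaled-down training configuration for test-speed fits."""
    return TrainConfig(epochs=80, hidden_dim=32, latent_dim=16,
                       degree_hidden_dim=16, degree_latent_dim=8,
                       em_warmup=20, seed=1)


@pytest.fixture(scope="session")
def trained_sim(sim_sample, fast_config):
    """Model fitted on the similarity-dominant fixture's train split."""
    graph = sim_sample.graph
    split = make_split(graph, 0.8, seed=1)
    model = AssociationModel(graph, fast_config)
    results = model.fit(train_edges=split.train_edges,
                        exclude_negatives=split.negatives, seed=1)
    return results, split
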