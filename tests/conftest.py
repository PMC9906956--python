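"""Shared fixtures: small synthetic datasets and a toy model.

Heavy artifacts (the 300-molecule benchmark, trained model variants) are
session-scoped so the acceptance tests share them.
"""

from __future__ import annotations

import numpy as np
import pytest

from simscreen.chem import similarity_matrix, tanimoto_metric
from simscreen.fixtures import SPEC_PRESETS, FixtureSpec, generate_dataset
from simscreen.model import ModelConfig, TransformerAutoencoder
from simscreen.tokenizer import build_vocabulary


@pytest.fixture(scope="session")
def tiny_dataset():
    """25 molecules: 3 families x 5 plus 10 background."""
    records, manifest = generate_dataset(SPEC_PRESETS["tiny"])
    return records, manifest


@pytest.fixture(scope="session")
def tiny_records(tiny_dataset):
    return tiny_dataset[0]


@pytest.fixture(scope="session")
def tiny_sims(tiny_records):
    return similarity_matrix(tiny_records, tanimoto_metric())


@pytest.fixture(scope="session")
def tiny_vocab(tiny_records):
    return build_vocabulary(tiny_records)


@pytest.fixture(scope="session")
def toy_model(tiny_vocab):
    """Untrained toy-profile model (deterministic weights, seed 0)."""
    cfg = ModelConfig(d=64, n_layers=2, n_heads=2, feedforward_dim=128,
                      vocab_size=len(tiny_vocab), max_len=96, dropout=0.0)
    return TransformerAutoencoder(cfg, seed=0)


@pytest.fixture(scope="session")
def benchmark_dataset():
    """The default clustered benchmark: 20 families x 10 + 100 background."""
    records, manifest = generate_dataset(FixtureSpec())
    return records, manifest


@pytest.fixture(scope="session")
def benchmark_sims(benchmark_dataset):
    records, _ = benchmark_dataset
    return similarity_matrix(records, tanimoto_metric())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
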