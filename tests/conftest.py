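"""Shared fixtures: synthetic hosts, gene sets and (expensive) trained models.

Trained-model fixtures are session-scoped so the recurrent classifier is
trained once per configuration and reused by every test that needs it.
"""

import numpy as np
import pytest

from codonoptim import (
    GeneLengthSpec,
    default_usage_table,
    make_host,
    sample_genes,
)
from codonoptim.model import quick_profile, train_optimizer


@pytest.fixture(scope="session")
def ecoli_usage():
    return default_usage_table()


@pytest.fixture(scope="session")
def order1_host():
    return make_host(seed=7, context_order=1, bias_strength=0.8)


@pytest.fixture(scope="session")
def order0_host():
    return make_host(seed=7, context_order=0, bias_strength=0.8)


@pytest.fixture(scope="session")
def order1_genes(order1_host):
    return sample_genes(
        order1_host, 300, GeneLengthSpec(90, 160), seed=8
    )


@pytest.fixture(scope="session")
def order1_held_out(order1_host):
    return sample_genes(
        order1_host, 50, GeneLengthSpec(90, 160), seed=9, id_prefix="held"
    )


@pytest.fixture(scope="session")
def order1_model(order1_genes):
    """Test-profile classifier trained on the order-1 synthetic host."""
    return train_optimizer(
        order1_genes[:270], order1_genes[270:], quick_profile(seed=1)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
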