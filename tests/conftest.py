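import numpy as np
import pandas as pd
import pytest

from cncl import (
    DerivationParams,
    ExpressionSimConfig,
    build_centroids,
    derive_signature,
    generate_expression,
)


@pytest.fixture(scope="session")
def sim_config():
    """Default-conditions simulation, modest gene universe for speed."""
    return ExpressionSimConfig(n_genes=300, noise_sd=0.25, seed=11)


@pytest.fixture(scope="session")
def planted_dataset(sim_config):
    return generate_expression(sim_config)


@pytest.fixture(scope="session")
def planted_pair(sim_config):
    """Two independent cohorts sharing the same planted 8-up/7-down signature."""
    a = generate_expression(sim_config)
    b = generate_expression(ExpressionSimConfig(n_genes=300, noise_sd=0.25, seed=22))
    return a, b


@pytest.fixture(scope="session")
def derived_signature(planted_pair):
    (mat_a, lab_a, _), (mat_b, lab_b, _) = planted_pair
    return derive_signature(mat_a, lab_a, mat_b, lab_b, DerivationParams())


@pytest.fixture(scope="session")
def reference_centroids(planted_dataset, derived_signature):
    matrix, labels, _ = planted_dataset
    return build_centroids(matrix, labels, derived_signature)
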