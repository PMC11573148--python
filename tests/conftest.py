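"""Shared fixtures: small synthetic organs generated at test time."""

import numpy as np
import pytest

from cwfkit.data_model import (
    BulkReplicates,
    CellAnnotation,
    CountMatrix,
    ReferenceRatios,
)
from cwfkit.signatures import select_signature_genes
from cwfkit.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def trio_dataset():
    """Three-type organ with 2.5x size steps, light bulk noise."""
    cfg = SimulationConfig(
        n_types=3,
        n_genes=200,
        cells_per_type=(150, 150, 150),
        true_sizes=(1.0, 2.5, 5.0),
        true_ratios=(0.5, 0.3, 0.2),
        noise_cv=0.02,
        seed=11,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def trio_signature(trio_dataset):
    sc, annotation, _, _ = trio_dataset
    return select_signature_genes(sc, annotation, 20, split_seed=11, tune=False)


@pytest.fixture(scope="session")
def quad_noiseless():
    """Four-type noiseless organ, sizes 1/2/4/8 — the size-recovery fixture."""
    cfg = SimulationConfig(
        n_types=4,
        n_genes=300,
        cells_per_type=(200,) * 4,
        true_sizes=(1.0, 2.0, 4.0, 8.0),
        true_ratios=(0.25,) * 4,
        noise_cv=0.0,
        seed=1,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def quad_signature(quad_noiseless):
    sc, annotation, _, _ = quad_noiseless
    return select_signature_genes(sc, annotation, 50, split_seed=1, tune=False)


@pytest.fixture
def tiny_matrix():
    return CountMatrix(
        ("Actb", "Gapdh", "Myh6"),
        ("c1", "c2"),
        np.array([[1.0, 4.0], [1.0, 4.0], [2.0, 8.0]]),
    )


@pytest.fixture
def tiny_bulk():
    return BulkReplicates(
        ("Actb", "Gapdh", "Myh6"),
        ("rep1",),
        np.array([[3.0], [2.0], [5.0]]),
    )


@pytest.fixture
def tiny_annotation():
    return CellAnnotation({"c1": "alpha", "c2": "beta"})


@pytest.fixture
def even_ratios():
    return ReferenceRatios({"alpha": 0.5, "beta": 0.5})
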