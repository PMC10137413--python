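import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from atlascmp.core import ExpressionMatrix
from atlascmp.synthetic import AtlasConfig, generate_atlas

settings.register_profile("deterministic", derandomize=True, deadline=None, max_examples=40)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_atlas():
    """A reduced two-species atlas for module-level tests."""
    cfg = AtlasConfig(
        n_genes=800,
        n_tissues=6,
        samples_per_tissue=4,
        n_tsg_per_tissue=4,
        n_hkg=40,
        n_deg_per_tissue=20,
        seed=101,
    )
    return (*generate_atlas(cfg), cfg)


@pytest.fixture(scope="session")
def default_atlas():
    """The full study-condition atlas: 20 tissues, 10 samples/tissue/species,
    planted effects of 3 log2 units, noise sd 0.25."""
    cfg = AtlasConfig(seed=11)
    return (*generate_atlas(cfg), cfg)


@pytest.fixture
def tiny_matrix():
    """Hand-built 3-gene × 4-sample matrix, two tissues, one species."""
    values = pd.DataFrame(
        {
            "s1": [1.0, 5.0, 100.0],
            "s2": [2.0, 6.0, 110.0],
            "s3": [10.0, 7.0, 120.0],
            "s4": [4.0, 8.0, 130.0],
        },
        index=["g1", "g2", "g3"],
    )
    meta = pd.DataFrame(
        {
            "species": ["sp1"] * 4,
            "tissue": ["liver", "liver", "liver", "brain"],
        },
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
    )
    return ExpressionMatrix(values, meta)
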