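import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cooccurnet import AbundanceMatrix

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def small_matrix() -> AbundanceMatrix:
    """4 OTUs × 6 locations with ties, zeros and a monotone pair (rows 0/1)."""
    counts = np.array(
        [
            [0, 3, 7, 1, 0, 12],
            [1, 4, 9, 2, 1, 20],
            [5, 0, 0, 8, 2, 0],
            [0, 0, 1, 0, 0, 2],
        ],
        dtype=float,
    )
    return AbundanceMatrix(
        counts=counts,
        otu_ids=["otu_a", "otu_b", "otu_c", "otu_d"],
        location_ids=[f"L{j}" for j in range(6)],
        phylum={"otu_a": "Acido", "otu_b": "Acido", "otu_c": "Proteo"},
    )


@pytest.fixture
def sparse_matrix() -> AbundanceMatrix:
    """A 30×40 sparse random count matrix (fixed seed)."""
    rng = np.random.default_rng(123)
    counts = rng.negative_binomial(0.4, 0.15, size=(30, 40)) * (rng.random((30, 40)) < 0.35)
    return AbundanceMatrix(
        counts=counts.astype(float),
        otu_ids=[f"OTU_{i:03d}" for i in range(30)],
        location_ids=[f"L{j:03d}" for j in range(40)],
    )
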