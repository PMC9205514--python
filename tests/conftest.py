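import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import orthoscan as osc

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def width1_motif():
    """Width-1 motif with q = (0.7, 0.1, 0.1, 0.1)."""
    return osc.motif_from_probs("W1", "w1", [[0.7, 0.1, 0.1, 0.1]])


@pytest.fixture
def uniform_motif():
    return osc.motif_from_probs("U3", "u3", [[0.25] * 4] * 3)


@pytest.fixture
def strong_motif():
    """Near-deterministic 10-bp motif used for planted-site constructions."""
    return osc.make_informative_motif(
        width=10, dominant=0.95, seed=3, motif_id="SYN0002", name="SYNTF2"
    )


@pytest.fixture
def tiny_study():
    """Small planted study: 12 clusters, 8 species, 500 bp promoters."""
    spec = osc.SyntheticSpec(
        n_clusters=12,
        n_species=8,
        promoter_length=500,
        planted_fraction=0.5,
        conservation_rate=1.0,
        n_background=60,
        seed=7,
    )
    motif = osc.make_informative_motif(
        width=10, dominant=0.95, seed=7, motif_id="SYN0003", name="SYNTF3"
    )
    clusters, background, truth = osc.make_study(spec, motif)
    config = osc.ScanConfig(n_subsets=4, subset_size=30, seed=7)
    return motif, clusters, background, truth, config


@pytest.fixture
def rng():
    return np.random.default_rng(0)
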