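import pytest
from hypothesis import HealthCheck, settings

import seqzip as sz

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def config():
    return sz.DesignConfig()


@pytest.fixture(scope="session")
def small_model():
    """Three 2-variant clusters with separating blocks: 8 isoforms."""
    return sz.synth_gene(variants_per_cluster=[2, 2, 2], exon_length=60,
                         block_length=60, similarity=0.5, seed=3)


@pytest.fixture(scope="session")
def small_pool(small_model, config):
    return sz.plan_pool(small_model, config, barcode_seed=5)


@pytest.fixture(scope="session")
def small_dual_pools(small_model, config):
    return sz.plan_dual_pools(small_model, config, barcode_seed=5)
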