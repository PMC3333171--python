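import pytest
from hypothesis import HealthCheck, settings

from irdna import (
    ClusteringParams,
    CommunitySpec,
    build_model,
    make_community,
    write_community,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_community():
    """A fast four-genome community for unit-level checks."""
    return make_community(
        CommunitySpec(n_genomes=4, genome_length=20_000, reads_per_genome=40, seed=7)
    )


@pytest.fixture(scope="session")
def community():
    """The reference synthetic community at generator defaults (seed 42)."""
    return make_community(CommunitySpec())


@pytest.fixture(scope="session")
def community_paths(community, tmp_path_factory):
    out = tmp_path_factory.mktemp("community")
    return write_community(community, out)


@pytest.fixture(scope="session")
def model(community_paths):
    """Model built from the reference community at fixture defaults."""
    return build_model(community_paths["genomes"], community_paths["markers"])


@pytest.fixture(scope="session")
def fine_model(community_paths):
    """Finer clustering under which the marker family spans several clusters."""
    return build_model(
        community_paths["genomes"],
        community_paths["markers"],
        clus=ClusteringParams(n_clusters=96, random_seed=0),
    )
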