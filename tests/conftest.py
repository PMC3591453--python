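"""Shared fixtures: small planted communities reused across the suite.

Community builds are session-scoped — they are deterministic pure
functions of their seed, so sharing them across tests changes nothing but
runtime.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import hidiv as hd

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def community_25():
    """25 well-separated OTUs, log-normal memberships — the workhorse for
    clustering equivalence checks."""
    design = hd.CommunityDesign(
        n_otus=25, mu=1.0, sigma=0.8, seed_min_separation=0.06, seed_length=250
    )
    return hd.build_community(design, np.random.default_rng(101))


@pytest.fixture(scope="session")
def community_50():
    """50 well-separated OTUs at the oracle-equivalence scale."""
    design = hd.CommunityDesign(
        n_otus=50, mu=1.0, sigma=0.8, seed_min_separation=0.06, seed_length=250
    )
    return hd.build_community(design, np.random.default_rng(202))


@pytest.fixture(scope="session")
def singleton_community_200():
    """200 OTUs with exactly one member each (mu=0, sigma -> 0+): the
    regime where singleton-driven estimators explode."""
    design = hd.CommunityDesign(
        n_otus=200, mu=0.0, sigma=1e-9, seed_min_separation=0.06, seed_length=250
    )
    return hd.build_community(design, np.random.default_rng(303))


@pytest.fixture(scope="session")
def lognormal_community_200():
    """200 OTUs with log-normal(1, 1) memberships — a realistic abundance
    spread (~1300 reads)."""
    design = hd.CommunityDesign(
        n_otus=200, mu=1.0, sigma=1.0, seed_min_separation=0.06, seed_length=250
    )
    return hd.build_community(design, np.random.default_rng(404))


@pytest.fixture(scope="session")
def clustered_200(lognormal_community_200):
    return hd.greedy_cluster(lognormal_community_200.reads, 0.03)


@pytest.fixture(scope="session")
def scenario_100():
    """End-to-end scenario: 100 OTUs plus contaminants, unlabeled pairs,
    planted unclassified singletons and chimeras."""
    spec = hd.ScenarioSpec(
        design=hd.CommunityDesign(
            n_otus=100, mu=1.0, sigma=1.0, seed_min_separation=0.06, seed_length=250
        ),
        contaminant_fraction=0.01,
        unlabeled_fraction=0.17,
        n_planted_singletons=5,
        n_chimeras=3,
        seed=7,
    )
    return hd.make_scenario(spec)
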