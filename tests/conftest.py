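"""Shared fixtures: one desk-scale synthetic universe and its linkage runs.

The desk-scale configuration (3,000 individuals, 20,000 background
registry records) keeps every structural phenomenon of the full-size
problem — alias-only links, duplicate identifiers, post-death contacts,
registry records missing day/month of birth — while letting the whole
suite run on one CPU in minutes. Session scope: the fixture and the two
linkage arms are computed once and shared.
"""

from __future__ import annotations

import pytest

from aliaslink import GeneratorConfig, generate_fixture, run_linkage

DESK_CONFIG = dict(
    n_individuals=3_000,
    registry_background_size=20_000,
    duplicate_person_id_count=4,
    post_death_contact_count=6,
    seed=11,
)


@pytest.fixture(scope="session")
def desk_fixture():
    return generate_fixture(GeneratorConfig(**DESK_CONFIG))


@pytest.fixture(scope="session")
def desk_linkage(desk_fixture):
    """(all-records arm, verified-only arm) at identical parameters."""
    fx = desk_fixture
    all_arm = run_linkage(fx.cohort, fx.registry, seed=11)
    verified_arm = run_linkage(
        fx.cohort, fx.registry, mu=all_arm.mu, verified_only=True, seed=11
    )
    return all_arm, verified_arm


@pytest.fixture(scope="session")
def tiny_config():
    """A fast small configuration for tests that regenerate their own data."""
    return GeneratorConfig(
        n_individuals=300,
        registry_background_size=2_000,
        duplicate_person_id_count=1,
        post_death_contact_count=1,
        seed=5,
    )
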