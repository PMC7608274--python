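"""Shared fixtures: one deterministic helix-bundle study reused across tests.

The structure/alignment fixture is expensive to featurize over the whole
substitution universe, so it is built once per session; cohort sampling seeds
vary per test.
"""

import pytest

from protvp.conservation import build_profile
from protvp.feature_assembly import featurize_cohort
from protvp.synthetic_fixtures import (
    FixtureSpec,
    _universe,
    default_conserved_blocks,
    make_helix_bundle,
    make_msa,
)


@pytest.fixture(scope="session")
def fixture_spec():
    return FixtureSpec(seed=7)


@pytest.fixture(scope="session")
def bundle(fixture_spec):
    model, topology, refseq = make_helix_bundle(fixture_spec)
    return model, topology, refseq


@pytest.fixture(scope="session")
def msa(fixture_spec, bundle):
    _, topology, refseq = bundle
    return make_msa(refseq, fixture_spec, conserved_blocks=default_conserved_blocks(topology))


@pytest.fixture(scope="session")
def profile(msa):
    return build_profile(msa)


@pytest.fixture(scope="session")
def universe_features(bundle, profile):
    model, topology, refseq = bundle
    return featurize_cohort(
        _universe(refseq), model, topology, profile, reference_sequence=refseq
    )


@pytest.fixture(scope="session")
def small_bundle():
    """A 2-helix, 10-residue-per-helix bundle for cheap geometry tests."""
    spec = FixtureSpec(n_helices=2, helix_length=10, ctd_length=12, seed=3)
    model, topology, refseq = make_helix_bundle(spec)
    return model, topology, refseq
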