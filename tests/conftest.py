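"""Shared fixtures: toy bundles, sampled profiles, small model ensembles.

Everything is generated programmatically and seeded, so the suite needs no
data files.  Session scope keeps the MILP sampling and sympy compilation
costs paid once.
"""

import numpy as np
import pytest

from strainkit.fixtures import (
    FixtureSpec,
    make_fixture,
    make_ground_truth_model,
)
from strainkit.kinetics import assign_rate_laws, sample_kinetic_models
from strainkit.thermo import sample_steady_states


@pytest.fixture(scope="session")
def chain_bundle():
    return make_fixture(FixtureSpec(topology="chain", n_reactions=5))


@pytest.fixture(scope="session")
def branched_bundle():
    return make_fixture(FixtureSpec(topology="branched10"))


@pytest.fixture(scope="session")
def feedback_bundle():
    return make_fixture(FixtureSpec(topology="feedback_branch"))


@pytest.fixture(scope="session")
def bistable_bundle():
    return make_fixture(FixtureSpec(topology="bistable_toy"))


@pytest.fixture(scope="session")
def carbon_bundle():
    return make_fixture(FixtureSpec(topology="carbon_closed"))


def _profiles(bundle, n=3, seed=1):
    return sample_steady_states(
        bundle.network, bundle.thermo, bundle.flux_bounds, n=n, seed=seed
    )


@pytest.fixture(scope="session")
def feedback_profiles(feedback_bundle):
    return _profiles(feedback_bundle)


@pytest.fixture(scope="session")
def branched_profiles(branched_bundle):
    return _profiles(branched_bundle)


@pytest.fixture(scope="session")
def feedback_models(feedback_bundle, feedback_profiles):
    a = assign_rate_laws(feedback_bundle.network)
    return sample_kinetic_models(
        feedback_bundle.network, a, feedback_bundle.thermo,
        feedback_profiles, per_profile=5, seed=2,
    )


@pytest.fixture(scope="session")
def branched_models(branched_bundle, branched_profiles):
    a = assign_rate_laws(branched_bundle.network)
    return sample_kinetic_models(
        branched_bundle.network, a, branched_bundle.thermo,
        branched_profiles, per_profile=5, seed=2,
    )


@pytest.fixture(scope="session")
def feedback_gt(feedback_bundle):
    return make_ground_truth_model(feedback_bundle, seed=0)


@pytest.fixture(scope="session")
def carbon_gt(carbon_bundle):
    return make_ground_truth_model(carbon_bundle, seed=0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
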