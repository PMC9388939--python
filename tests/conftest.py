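"""Shared fixtures.

The expensive Monte Carlo runs (one high-statistics static field, one
full simulation per technique) are session-scoped and reused by both
the physics property tests and the acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from oofdose.phantom import default_pediatric_phantom
from oofdose.plan import aperture_at
from oofdose.synthetic import fixture_plans
from oofdose.transport import (
    CollimationModel,
    SourceModel,
    TransportConfig,
    calibrate_cf,
    run_beam,
    simulate_plan,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

SEED = 20260920


@pytest.fixture(scope="session")
def pediatric_phantom():
    return default_pediatric_phantom()


@pytest.fixture(scope="session")
def source():
    return SourceModel()


@pytest.fixture(scope="session")
def collimation():
    return CollimationModel()


@pytest.fixture(scope="session")
def plans():
    return fixture_plans(seed=0)


@pytest.fixture(scope="session")
def conversion_factor(source, collimation):
    return calibrate_cf(source, collimation, TransportConfig(n_histories=200_000, seed=SEED))


@pytest.fixture(scope="session")
def field1_tally(pediatric_phantom, plans, source, collimation):
    """High-statistics run of the first static brain field (3.2 x 3.2 cm,
    gantry 320 deg): 2e6 histories in 20 batches, fixed seed."""
    field1 = plans[0].fields[0]
    cfg = TransportConfig(n_histories=2_000_000, batches=20, seed=SEED)
    return run_beam(pediatric_phantom, field1, aperture_at(field1), source, collimation, cfg)


@pytest.fixture(scope="session")
def crt_report(pediatric_phantom, plans, source, collimation, conversion_factor):
    cfg = TransportConfig(n_histories=600_000, seed=SEED + 1)
    return simulate_plan(
        pediatric_phantom, plans[0], source, cfg, collimation=collimation, cf=conversion_factor
    )


@pytest.fixture(scope="session")
def imrt_report(pediatric_phantom, plans, source, collimation, conversion_factor):
    cfg = TransportConfig(n_histories=1_400_000, seed=SEED + 2)
    return simulate_plan(
        pediatric_phantom, plans[1], source, cfg, collimation=collimation, cf=conversion_factor
    )
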