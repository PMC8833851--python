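"""Shared fixtures: phantom anatomy, training cohort and fitted template model.

Session scope keeps the expensive generators to one run; every fixture is
seeded, so the suite is deterministic end to end.
"""

from __future__ import annotations

import numpy as np
import pytest

from pctreg import (
    RegistrationConfig,
    Volume,
    fit_pc_model,
    fix_component_signs,
)
from pctreg.phantom import generate_cohort, make_anatomy, make_atlas

COHORT_SEED = 11
COHORT_N = 20


@pytest.fixture(scope="session")
def anatomy():
    return make_anatomy()


@pytest.fixture(scope="session")
def train_cohort(anatomy):
    """Stratified-burden template-building cohort, 5% noise, no warps."""
    return generate_cohort(anatomy, COHORT_N, warp=False, seed=COHORT_SEED)


@pytest.fixture(scope="session")
def model(anatomy, train_cohort):
    """Sign-fixed two-component template model on the brain mask."""
    m = fit_pc_model(train_cohort.stack, k=2, mask=anatomy.brain_mask)
    return fix_component_signs(m, anatomy.brain_mask, anatomy.mask("cortical_gm"))


@pytest.fixture(scope="session")
def atlas(anatomy, model):
    """VOI atlas with ThPons derived from the training mean image."""
    return make_atlas(anatomy, model.mean_image)


@pytest.fixture(scope="session")
def config():
    return RegistrationConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def small_volume(rng):
    """A smooth 16^3 test volume with a non-trivial affine."""
    x, y, z = np.indices((16, 16, 16), dtype=float)
    data = np.exp(-(((x - 8) ** 2 + (y - 7) ** 2 + (z - 9) ** 2) / 30.0))
    aff = np.diag([2.0, 2.0, 2.0, 1.0])
    aff[:3, 3] = [-16, -14, -18]
    return Volume(data + 0.01 * rng.standard_normal(data.shape), aff)
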