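"""Shared fixtures: phantom cohorts, prior libraries and analysis setups.

Heavy setups are session-scoped so unit tests and acceptance tests share
one computation.  All cohorts here use deliberately small grids and
amplified aging-trend coefficients so age effects span more than a voxel.
"""

from __future__ import annotations

import numpy as np
import pytest

from agetpl.evaluate import HarnessCase
from agetpl.phantom import PhantomSpec, make_cohort, make_phantom
from agetpl.pipeline import prepare_cases
from agetpl.register import ResolutionSchedule
from agetpl.template import build_prior_library, scheme_groups

# shell radii that fit a 32^3 x 3 mm grid
SMALL_GEOM = dict(
    scalp_radius=40.0,
    skull_outer_radius=37.5,
    inner_skull_radius=35.5,
    brain_radius=33.5,
)

# amplified aging trends: the default coefficients move tissue boundaries
# by well under a voxel per decade, which buries the age signal at test
# resolutions
AMP_TRENDS = dict(gm_slope=-0.0028, wm_curv=4.0e-5)

FAST_PLAN = [
    ResolutionSchedule((8, 0, 0)),
    ResolutionSchedule((8, 4, 0)),
    ResolutionSchedule((8, 4, 2)),
]

MED_PLAN = [
    ResolutionSchedule((10, 0, 0)),
    ResolutionSchedule((10, 5, 0)),
    ResolutionSchedule((10, 5, 3)),
]


@pytest.fixture(scope="session")
def clean_case():
    """Noise-free, bias-free 48^3 phantom."""
    return make_phantom(PhantomSpec(age=40.0, seed=1, grid_shape=(48, 48, 48)))


@pytest.fixture(scope="session")
def noisy_case():
    return make_phantom(
        PhantomSpec(age=62.0, seed=5, grid_shape=(40, 40, 40), voxel_size=2.5,
                    noise_sigma=8.0, shape_jitter=1.0)
    )


@pytest.fixture(scope="session")
def biased_case():
    return make_phantom(
        PhantomSpec(age=40.0, seed=6, grid_shape=(48, 48, 48), bias_amplitude=0.3)
    )


@pytest.fixture(scope="session")
def harness_setup():
    """Small library (young + one aged group, both bases) plus one test case."""
    cohort = make_cohort(
        [(20, 24), (70, 74)], 3, seed=11, grid_shape=(40, 40, 40),
        voxel_size=2.5, noise_sigma=12.0, shape_jitter=0.8, **AMP_TRENDS,
    )
    prepared = prepare_cases(cohort)
    library = build_prior_library(
        prepared, schemes=["five_year", "ten_year"], schedule_plan=MED_PLAN,
        max_iter=2,
    )
    case, prep = cohort[3], prepared[3]
    hc = HarnessCase(case.subject_id, prep.brain, prep.mask,
                     case.truth_labels(), case.age)
    return {"library": library, "case": hc, "cohort": cohort, "prepared": prepared}


@pytest.fixture(scope="session")
def offset_setup():
    """Full 14-group five-year cohort (4/group), library and subsample."""
    groups = [(g.low, g.high) for g in scheme_groups("five_year")]
    cohort = make_cohort(
        groups, 4, seed=21, grid_shape=(32, 32, 32), voxel_size=3.0,
        noise_sigma=12.0, shape_jitter=0.6, **SMALL_GEOM, **AMP_TRENDS,
    )
    prepared = prepare_cases(cohort)
    library = build_prior_library(
        prepared, schemes=["five_year"], schedule_plan=FAST_PLAN,
        max_iter=2, include_reference_base=False,
    )
    subsample = [
        HarnessCase(c.subject_id, p.brain, p.mask, c.truth_labels(), c.age)
        for i, (c, p) in enumerate(zip(cohort, prepared))
        if i % 4 == 0
    ]
    return {
        "cohort": cohort,
        "prepared": prepared,
        "library": library,
        "subsample": subsample,
    }


@pytest.fixture(scope="session")
def ordering_setup():
    """Aged cohorts and a five-year library for the headline Dice ordering."""
    groups = [(20, 24), (70, 74), (75, 79), (80, 84), (85, 89)]
    cohort = make_cohort(
        groups, 4, seed=11, grid_shape=(40, 40, 40), voxel_size=2.5,
        noise_sigma=18.0, shape_jitter=0.6, **AMP_TRENDS,
    )
    prepared = prepare_cases(cohort)
    library = build_prior_library(
        prepared, schemes=["five_year"], schedule_plan=MED_PLAN, max_iter=2,
    )
    test_cohort = make_cohort(
        groups[1:], 5, seed=99, grid_shape=(40, 40, 40), voxel_size=2.5,
        noise_sigma=18.0, shape_jitter=0.6, **AMP_TRENDS,
    )
    test_prepared = prepare_cases(test_cohort)
    return {
        "library": library,
        "test_cohort": test_cohort,
        "test_prepared": test_prepared,
    }
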