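"""Shared fixtures: simulated cohorts and fitted dual-regression results.

The default cohort (18 + 18 subjects, 8 networks on a 24x24x16 grid,
T = 178, TR = 2 s, all three Group-B manipulations) is expensive enough to
share session-wide; everything that consumes it treats it as read-only.
"""

from __future__ import annotations

import numpy as np
import pytest

from dualreg import DualRegression, GroupDesign
from dualreg.simulate import simulate_cohort, synthesize_subject

COHORT_SEED = 0


@pytest.fixture(scope="session")
def cohort():
    """Default simulated cohort ground truth (seed fixed)."""
    return simulate_cohort(seed=COHORT_SEED)


@pytest.fixture(scope="session")
def cohort_subjects(cohort):
    """Synthesized BOLD datasets for every subject of the default cohort."""
    return [synthesize_subject(cohort, i) for i in range(cohort.n_subjects)]


@pytest.fixture(scope="session")
def dr_results(cohort, cohort_subjects):
    """Design-normalized dual-regression fits for the default cohort."""
    return [DualRegression(ds, cohort.maps).fit(design_norm=True) for ds in cohort_subjects]


@pytest.fixture(scope="session")
def dr_results_raw(cohort, cohort_subjects):
    """Raw-coefficient (no design normalization) fits for the same cohort."""
    return [DualRegression(ds, cohort.maps).fit(design_norm=False) for ds in cohort_subjects]


@pytest.fixture(scope="session")
def cohort_design(cohort):
    return GroupDesign(labels=cohort.group_labels)


def component_index(cohort, name: str) -> int:
    return cohort.maps.component_names.index(name)


def effect_of_kind(cohort, kind: str):
    return next(e for e in cohort.effects if e.kind == kind)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
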