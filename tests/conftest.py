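"""Shared fixtures: one default synthetic cohort, calibrated once per session."""

from __future__ import annotations

import pytest

from ctmeth import calling, simulate


@pytest.fixture(scope="session")
def default_cohort():
    return simulate.simulate_cohorts(simulate.CohortSpec(seed=1))


@pytest.fixture(scope="session")
def cohort_profiles(default_cohort):
    return calling.profiles_from_table(default_cohort.droplets)


@pytest.fixture(scope="session")
def calibrated(default_cohort, cohort_profiles):
    base = default_cohort.samples[default_cohort.samples.timepoint == "baseline"]
    ctrl = {s: cohort_profiles[s]
            for s in base.loc[base.cohort == "control", "sample_id"]}
    case = {s: cohort_profiles[s]
            for s in base.loc[base.cohort == "localized", "sample_id"]}
    return calling.calibrate_panel(ctrl, case)


@pytest.fixture(scope="session")
def default_panel():
    """The published panel: printed LoBs, k = 2, {NPY, GDAP1L1} exception."""
    return calling.MarkerPanel()
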