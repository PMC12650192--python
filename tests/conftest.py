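"""Shared fixtures: small synthetic configurations and cohorts.

All fixtures are deterministic (fixed seeds) and sized for desk-scale runs;
the clean (noise-free) configurations switch off jitter, drift, sensor
noise and leak so generator ground truth is exact.
"""

import numpy as np
import pytest

from breathfit import (
    PlanBlock,
    SynthConfig,
    default_session_plan,
    simulate_cohort,
    simulate_subject,
)


def clean_config(duration_s=300.0, rate=12.0, label="fit", leak=0.0, seed=1,
                 insp_sd=0.0):
    """Single-block noiseless session at a fixed breathing rate."""
    return SynthConfig(
        n_subjects=1,
        session_plan=(PlanBlock(duration_s, label, "proper_fit", leak),),
        rate_range_bpm=(rate, rate),
        cycle_jitter_cv=0.0,
        insp_fraction_sd=insp_sd,
        drift_sd={},
        noise_sd={},
        phase_noise_sd_s=0.0,
        amp_subject_cv=0.0,
        seed=seed,
    )


@pytest.fixture(scope="session")
def clean_session():
    """Noiseless 300 s fit session at exactly 12 bpm, with its ground truth."""
    rec, labels, truth = simulate_subject(clean_config(), 0)
    return rec, labels, truth


@pytest.fixture(scope="session")
def small_cohort():
    """Three-subject cohort with a 0.3×-scaled default protocol, full noise."""
    cfg = SynthConfig(n_subjects=3, session_plan=default_session_plan(0.3), seed=7)
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
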