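"""Shared fixtures: small deterministic synthetic cohorts."""

import numpy as np
import pytest

from sslrun import loads, synth


@pytest.fixture(scope="session")
def small_cohort():
    """4 subjects x 2 speeds x 12 steps at default noise."""
    cfg = synth.GeneratorConfig(
        n_subjects=4, speeds=(2.22, 2.78), noise_scale=1.0, seed=11
    )
    subjects, trials = synth.generate_cohort(cfg, n_steps_per_trial=12)
    return cfg, subjects, trials


@pytest.fixture(scope="session")
def small_steps(small_cohort):
    """All step samples (accepted and not) from the small cohort."""
    _cfg, subjects, trials = small_cohort
    profiles = {s.subject_id: s for s in subjects}
    out = []
    for trial in trials:
        out.extend(loads.build_step_samples(trial, profiles[trial.subject_id]))
    return subjects, out


@pytest.fixture(scope="session")
def accepted_steps(small_steps):
    subjects, steps = small_steps
    return subjects, [s for s in steps if s.accepted]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
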