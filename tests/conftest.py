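"""Shared fixtures: one synthetic data set and its analysis, computed once.

Everything is generated programmatically (no stored data files); the
default generator settings are the study conditions, so most tests share
the same session-scoped trial.
"""

import numpy as np
import pytest

from pafoot import (SubjectConfig, SyntheticTrialSpec, analyze_trial,
                    generate_gait_trial, generate_quiet_standing)


@pytest.fixture(scope="session")
def spec():
    return SyntheticTrialSpec()


@pytest.fixture(scope="session")
def gait_and_truth(spec):
    return generate_gait_trial(spec)


@pytest.fixture(scope="session")
def gait(gait_and_truth):
    return gait_and_truth[0]


@pytest.fixture(scope="session")
def truth(gait_and_truth):
    return gait_and_truth[1]


@pytest.fixture(scope="session")
def standing(spec):
    bundle, _ = generate_quiet_standing(spec)
    return bundle


@pytest.fixture(scope="session")
def config(spec) -> SubjectConfig:
    return spec.config()


@pytest.fixture(scope="session")
def analysis(gait, standing, config):
    """Paired with/without-aponeurosis runs on the default trial."""
    return analyze_trial(gait, standing.markers, config)


@pytest.fixture(scope="session")
def result_with(analysis):
    return analysis.with_pa


@pytest.fixture(scope="session")
def result_without(analysis):
    return analysis.without_pa


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
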