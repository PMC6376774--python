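"""Shared fixtures: small synthetic cohorts and landmark risk sets."""

import numpy as np
import pytest

from landmarkdpo.data import build_landmark_dataset
from landmarkdpo.simulate import Scenario, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_rows(
    seed=0,
    n=30,
    frailty="gamma",
    lambda01=1.0,
    lambda02=1.5,
    lambda0D=0.0,
    lambda_c=0.5,
    max_events=3,
    k_max=2,
    window=1.0,
    terminal_mode=None,
):
    """Risk-set rows at s=0 from one simulated cohort."""
    scenario = Scenario(
        frailty=frailty,
        lambda01=lambda01,
        lambda02=lambda02,
        lambda0D=lambda0D,
        lambda_c=lambda_c,
        n=n,
        max_events=max_events,
    )
    histories, potentials = simulate_cohort(scenario, seed)
    if terminal_mode is None:
        terminal_mode = scenario.terminal_mode
    dataset = build_landmark_dataset(histories, [0.0], window, k_max, terminal_mode)
    return dataset.rows_at(0.0), potentials
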