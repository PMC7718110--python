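import numpy as np
import pandas as pd
import pytest

import pseudoneglect as pn


def make_proportion_table(
    loc=0.0, scale=2.5, lapse=0.02,
    levels=(-10, -8, -6, -4, -2, 0, 2, 4, 6, 8, 10),
    n_per=15, n_zero=30, seed=0,
) -> pd.DataFrame:
    """Landmark counts drawn straight from the closed-form psychometric
    probability (no trial-level machinery), for fitting tests."""
    rng = np.random.default_rng(seed)
    rows = []
    for x in levels:
        n = n_zero if x == 0 else n_per
        p = pn.predicted_proportion(x, loc, scale, lapse)
        rows.append((float(x), n, int(rng.binomial(n, p))))
    table = pd.DataFrame(rows, columns=["asymmetry_mm", "n_trials", "n_right"])
    table["prop_right"] = table["n_right"] / table["n_trials"]
    return table


@pytest.fixture(scope="session")
def default_design():
    return pn.default_design()


@pytest.fixture(scope="session")
def small_study():
    """An 8-participant study with the default stimulus structure, shared
    across tests that only need plausible trial-level data."""
    import dataclasses

    design = dataclasses.replace(pn.default_design(), n_participants=8)
    return pn.simulate_study(design, seed=20240)


@pytest.fixture(scope="session")
def small_session_matrices(small_study):
    """Filtered session-error matrices for all three tasks of the small
    study (landmark cells via per-session psychometric fits)."""
    trials = pn.filter_trials(
        small_study.trials, small_study.design.response_timeout_s
    )
    lm, fits, _ = pn.landmark_session_errors(trials)
    line = pn.session_means(trials[trials["task"] == pn.Task.LINE.value])
    rod = pn.session_means(trials[trials["task"] == pn.Task.ROD.value])
    return {
        pn.Task.LANDMARK.value: lm,
        pn.Task.LINE.value: line,
        pn.Task.ROD.value: rod,
    }, fits
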