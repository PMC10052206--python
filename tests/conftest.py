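"""Shared fixtures: canonical variable set and cached simulations.

Scenario simulations and sliding trends are expensive, so they are built
once per session and shared; tests must not mutate them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import openqct as q

NAMES = ("hr", "sbp", "dbp", "mbp", "lvet", "pep", "sv", "co", "hi", "tac", "svr")

#: Seed fixed for every deterministic end-to-end check in this suite.
SEED = 1

#: Trend step (beats) used by the end-to-end checks to keep runtimes sane
#: while still sampling every phase densely (a point every ~3 s).
STEP = 4


@pytest.fixture(scope="session")
def anthro():
    return q.SubjectAnthropometry(weight=80.0, height=180.0, sex="male")


def _simulate(name: str):
    scn = q.get_scenario(name, seed=SEED)
    records, truth = q.simulate_hutt(scn)
    data, mask, times = q.assemble_state_matrix(records, scn.subject)
    return scn, records, truth, data, mask, times


@pytest.fixture(scope="session")
def supine_run():
    return _simulate("supine_baseline")


@pytest.fixture(scope="session")
def negative_run():
    return _simulate("negative_with_ntg")


@pytest.fixture(scope="session")
def warning_run():
    return _simulate("type1_mixed_with_warning")


@pytest.fixture(scope="session")
def early_run():
    return _simulate("type1_mixed_early")


def make_trend(data, mask, times, window=100, step=STEP, seed=SEED, **kw):
    return q.sliding_trend(data, mask, times, window=window, step=step,
                           variable_names=NAMES, seed=seed, **kw)


@pytest.fixture(scope="session")
def supine_trend(supine_run):
    _, _, _, data, mask, times = supine_run
    return make_trend(data, mask, times)


@pytest.fixture(scope="session")
def negative_trend(negative_run):
    """Trend over supine + tilt + passive (sliced before the NTG phase)."""
    _, _, truth, data, mask, times = negative_run
    i_end = int(np.searchsorted(times, truth.events["ntg"]))
    return make_trend(data[:i_end], mask[:i_end], times[:i_end])


@pytest.fixture(scope="session")
def warning_trend(warning_run):
    _, _, _, data, mask, times = warning_run
    return make_trend(data, mask, times)


@pytest.fixture(scope="session")
def small_beats():
    """Tiny, gap-free, hand-sized beat table for unit tests."""
    rng = np.random.default_rng(7)
    n = 12
    t = np.cumsum(rng.uniform(0.7, 1.1, n))
    hr = 60.0 / np.diff(np.concatenate([[0], t]))
    return pd.DataFrame({
        "t": t, "hr": hr,
        "sbp": rng.uniform(110, 130, n), "dbp": rng.uniform(70, 85, n),
        "mbp": rng.uniform(85, 100, n),
        "lvet": rng.uniform(0.28, 0.34, n), "pep": rng.uniform(0.08, 0.1, n),
        "z0": rng.uniform(22, 28, n), "dzmax": rng.uniform(1.2, 1.8, n),
        "trc": rng.uniform(0.12, 0.18, n),
    })
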