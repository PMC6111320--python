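"""Shared fixtures.

The expensive multi-seed cohort batteries are session-scoped so the
synthetic-data, statistics and classification suites all reuse one set
of simulated cohorts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import stresskit as sk
from stresskit.classify import label_epochs

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")

#: number of independent cohort simulations in the default battery
N_BATTERY_SEEDS = 20
#: seeds for the chance-level leave-one-subject-out battery
N_LOSO_SEEDS = 10
#: offset scale regarded as "large" (subject clouds effectively disjoint)
LARGE_OFFSET_SCALE = 25.0


@pytest.fixture(scope="session")
def default_params() -> sk.SimulationParams:
    return sk.SimulationParams()


@pytest.fixture(scope="session")
def short_timeline() -> sk.EventTimeline:
    """A compressed but order-valid timeline for cheap structural tests."""
    return sk.EventTimeline(
        mvc_start=1, mvc_end=3, rs1_start=5, rs1_end=15, t1=15,
        mist_train_start=17, mist_task_start=20, mist_end=29, t2=29,
        relax_start=31, relax_end=43, t3=43, rs2_start=45, rs2_end=55,
    )


@pytest.fixture()
def small_session(short_timeline) -> sk.SubjectSession:
    """A small random 8-channel session (55 s at 100 Hz)."""
    rng = np.random.default_rng(42)
    fs = 100.0
    return sk.SubjectSession(
        subject_id="tiny",
        sampling_rate=fs,
        channels=rng.standard_normal((8, int(55 * fs))),
        timeline=short_timeline,
        spsl=(1, 4, 0),
    )


@pytest.fixture(scope="session")
def one_subject(default_params) -> sk.SubjectSession:
    """One full-scale synthetic subject shared across marker tests."""
    return sk.generate_session("S01", default_params, 42)


@pytest.fixture(scope="session")
def one_subject_markers(one_subject) -> pd.DataFrame:
    return sk.extract_markers(one_subject)


def _cohort_markers(params: sk.SimulationParams, seed: int, n_subjects: int = 10):
    tables = []
    spsl = []
    for sess in sk.iter_cohort(n_subjects, params, seed):
        tables.append(sk.extract_markers(sess))
        spsl.append(sess.spsl)
    return pd.concat(tables, ignore_index=True), spsl


@pytest.fixture(scope="session")
def cohort_battery(default_params):
    """Marker tables for N_BATTERY_SEEDS independent default cohorts of
    10 subjects each; the study-scale simulation battery."""
    return [
        _cohort_markers(default_params, seed) for seed in range(N_BATTERY_SEEDS)
    ]


@pytest.fixture(scope="session")
def cohort_battery_labeled(cohort_battery, default_params):
    """Per-subject labeled feature tables for every battery cohort."""
    tl = default_params.timeline
    out = []
    for table, _ in cohort_battery:
        labeled = label_epochs(table, tl)
        out.append([g for _, g in labeled.groupby("subject_id", sort=True)])
    return out


@pytest.fixture(scope="session")
def loso_offset_battery():
    """Cohorts with large per-subject marker offsets, where subjects'
    feature clouds are effectively disjoint."""
    params = sk.SimulationParams(subject_offset_scale=LARGE_OFFSET_SCALE)
    out = []
    for seed in range(N_LOSO_SEEDS):
        table, _ = _cohort_markers(params, seed)
        labeled = label_epochs(table, params.timeline)
        out.append([g for _, g in labeled.groupby("subject_id", sort=True)])
    return out
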