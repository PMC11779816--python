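"""Shared fixtures: small traces and session-scoped simulated cohorts.

The cohort screens are expensive (~20 s each), so the acceptance tests share
one WT cohort and one mixed WT + clock-deficient cohort, both from a fixed
seed chosen up front.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import pytest

import cagerhythm as cr
from cagerhythm.screen import AnalysisParams, analyze_cohort

logging.disable(logging.WARNING)

COHORT_SEED = 1


def make_trace(values, bin_seconds=60, start="2024-01-01 07:00", **kw):
    defaults = dict(animal_id="T1", start_time=pd.Timestamp(start), bin_seconds=bin_seconds)
    defaults.update(kw)
    return cr.ActivityTrace(values=np.asarray(values, dtype=float), **defaults)


def square_day(active_start_h, amp=20.0, bin_minutes=1, day_h=24.0, active_h=12.0):
    """One day of square-wave activity starting at active_start_h (hours from bin 0)."""
    n = int(day_h * 60 / bin_minutes)
    t = (np.arange(n) + 0.5) * bin_minutes / 60.0
    rel = (t - active_start_h) % day_h
    return np.where(rel < active_h, amp, 0.0)


@pytest.fixture(scope="session")
def wt_cohort():
    return cr.simulate_cohort(cr.CohortSpec(n_animals=12, seed=COHORT_SEED))


@pytest.fixture(scope="session")
def wt_screen(wt_cohort):
    proto = wt_cohort.protocol
    metrics, onsets, _ = analyze_cohort(
        wt_cohort.animals, proto.phases,
        target_onset_tod=proto.target_onset_tod,
        pulse_day=proto.pulse_day, shift_day=proto.shift_day,
    )
    return metrics, onsets


@pytest.fixture(scope="session")
def dko_cohort():
    spec = cr.CohortSpec(n_animals=12, genotypes=("WT",) * 6 + ("CRY_dKO",) * 6,
                         seed=COHORT_SEED)
    return cr.simulate_cohort(spec)


@pytest.fixture(scope="session")
def dko_screen(dko_cohort):
    proto = dko_cohort.protocol
    metrics, onsets, _ = analyze_cohort(
        dko_cohort.animals, proto.phases,
        target_onset_tod=proto.target_onset_tod,
        pulse_day=proto.pulse_day, shift_day=proto.shift_day,
    )
    return metrics, onsets
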