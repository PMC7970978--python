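from datetime import datetime

import numpy as np
import pytest

from glycoscope import GlucoseSeries
from glycoscope.cgm_core import SLOTS_PER_DAY


def make_series(values, gap_mask=None, subject_id="s1", t0=None, n_days=None):
    values = np.asarray(values, dtype=float)
    if n_days is None:
        n_days = len(values) // SLOTS_PER_DAY
    if gap_mask is None:
        gap_mask = np.zeros(len(values), dtype=bool)
    if t0 is None:
        t0 = datetime(2020, 1, 1, 0, 0)
    return GlucoseSeries(subject_id, t0, values, gap_mask, n_days)


@pytest.fixture
def series_factory():
    return make_series


@pytest.fixture
def sinusoid_factory():
    """Series = baseline + amplitude * sin(2*pi*t/period_days) on the 5-min grid."""

    def make(period_days, amplitude, baseline=120.0, n_days=6, **kwargs):
        n = n_days * SLOTS_PER_DAY
        t_days = np.arange(n) / SLOTS_PER_DAY
        vals = baseline + amplitude * np.sin(2 * np.pi * t_days / period_days)
        return make_series(vals, n_days=n_days, **kwargs)

    return make
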