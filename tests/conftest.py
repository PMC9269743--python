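import numpy as np
import pandas as pd
import pytest

from glucosynth.cgm_io import GlucoseSeries, SAMPLES_PER_DAY


@pytest.fixture
def grid_series():
    """Factory for a gridded series from an array of values (NaN = missing)."""

    def make(values, start="2024-01-01 00:00", patient_id="P"):
        values = np.asarray(values, dtype=float)
        times = pd.date_range(start, periods=len(values), freq="5min")
        return GlucoseSeries(patient_id, times, values)

    return make


@pytest.fixture
def day_matrix_from_values():
    """Build a one-row DayMatrix repeating the given values to 288 samples."""
    from glucosynth.cgm_io import DayMatrix

    def make(values, anchor_hour=0):
        values = np.asarray(values, dtype=float)
        reps = SAMPLES_PER_DAY // len(values)
        if reps * len(values) != SAMPLES_PER_DAY:
            raise ValueError("values must evenly divide 288")
        return DayMatrix("P", np.tile(values, reps)[None, :], anchor_hour=anchor_hour)

    return make
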