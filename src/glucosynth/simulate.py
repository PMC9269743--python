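"""Synthetic CGM trace generator with controllable glycemic statistics.

This is a statistical fixture, not a metabolic simulator: it produces
traces whose per-day time-in-range distributions, mean glucose, and
nocturnal-hypoglycemia prevalence are tunable to the ranges typical of
adults with type 1 diabetes wearing a CGM, so the generative model, the
acceptance battery, and the night classifier can all be exercised without
access to restricted clinical cohorts.

Signal model, per 5-minute sample:

    glucose(t) = basal + day_offset(d) + circadian(t) + meals(t)
                 + hypo_excursion(t) + AR(1) noise,  clamped to [40, 400]

* ``circadian`` is a sinusoid with its minimum near 03:00 and maximum near
  15:00.
* meals are jittered-in-time, jittered-in-amplitude rises with exponential
  decay.
* on a night selected with probability ``hypo_night_prob``, a broad
  negative excursion is applied from the late evening onwards and a sharp
  dip is enforced so the night is guaranteed to register at least three
  consecutive sub-70 mg/dL readings between 22:00 and 06:00.  The evening
  portion of the excursion makes pre-sleep glucose genuinely predictive of
  the night label, as it is in real patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .cgm_io import (GLUCOSE_MAX, GLUCOSE_MIN, SAMPLES_PER_DAY, GlucoseSeries,
                     STEP)

__all__ = ["SimPatientParams", "SimValidationError", "simulate_patient",
           "inject_gaps", "preset_params", "PRESETS"]

_BASE_DATE = pd.Timestamp("2024-01-01")


class SimValidationError(ValueError):
    """Simulation parameters outside their admissible ranges."""


@dataclass
class SimPatientParams:
    """Knobs of the fixture patient.

    Units: glucose quantities in mg/dL, ``meal_times`` in hours of day,
    ``meal_decay`` as a per-minute exponential rate.
    """

    basal_mean: float = 150.0
    circadian_amplitude: float = 20.0
    meal_times: tuple = (8.0, 13.5, 20.0)
    meal_rise: float = 60.0
    meal_decay: float = 0.012
    hypo_night_prob: float = 0.15
    noise_sd: float = 12.0
    day_offset_sd: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        bad = []
        if not (80.0 <= self.basal_mean <= 250.0):
            bad.append("basal_mean")
        if not (0.0 <= self.hypo_night_prob <= 1.0):
            bad.append("hypo_night_prob")
        if self.noise_sd < 0:
            bad.append("noise_sd")
        if self.circadian_amplitude < 0:
            bad.append("circadian_amplitude")
        if self.meal_rise < 0:
            bad.append("meal_rise")
        if self.meal_decay <= 0:
            bad.append("meal_decay")
        if self.day_offset_sd < 0:
            bad.append("day_offset_sd")
        if any(not (0.0 <= m < 24.0) for m in self.meal_times):
            bad.append("meal_times")
        if bad:
            raise SimValidationError(f"invalid parameter(s): {', '.join(bad)}")


#: Two preset patients bracketing typical poorly- and moderately-controlled
#: glycemic profiles (high hyperglycemia exposure vs. mostly in range).
PRESETS = {
    "high_glycemia": SimPatientParams(basal_mean=172.0, circadian_amplitude=25.0,
                                      meal_rise=70.0, hypo_night_prob=0.25,
                                      noise_sd=15.0, day_offset_sd=14.0),
    "moderate": SimPatientParams(basal_mean=150.0, circadian_amplitude=20.0,
                                 meal_rise=70.0, hypo_night_prob=0.18,
                                 noise_sd=14.0, day_offset_sd=12.0),
}


def preset_params(name: str, seed: int = 0) -> SimPatientParams:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    p = PRESETS[name]
    return SimPatientParams(**{**p.__dict__, "seed": seed})


def _meal_kernel(minutes: np.ndarray, start_min: float, amplitude: float,
                 decay: float) -> np.ndarray:
    """Linear 30-minute rise to ``amplitude`` then exponential decay."""
    rel = minutes - start_min
    rise = np.clip(rel / 30.0, 0.0, 1.0)
    fall = np.where(rel > 30.0, np.exp(-decay * (rel - 30.0)), 1.0)
    return np.where(rel >= 0.0, amplitude * rise * fall, 0.0)


def simulate_patient(params: SimPatientParams, n_days: int,
                     patient_id: str = "SIM") -> GlucoseSeries:
    """Simulate ``n_days`` full days (midnight to midnight) at 5-min cadence.

    Deterministic under a fixed ``params.seed``.  Nights are indexed by the
    day they start in; night ``d`` spans 22:00 of day ``d`` to 06:00 of day
    ``d + 1``, so only the first ``n_days - 1`` nights are complete and
    eligible for an induced excursion.
    """
    params.validate()
    if n_days < 1:
        raise SimValidationError("n_days must be >= 1")
    rng = np.random.default_rng(params.seed)
    n = n_days * SAMPLES_PER_DAY
    minutes = np.arange(n) * 5.0
    hours = (minutes / 60.0) % 24.0

    signal = np.full(n, params.basal_mean, dtype=float)
    # circadian: minimum near 03:00, maximum near 15:00
    signal += params.circadian_amplitude * np.sin(2 * np.pi * (hours - 9.0) / 24.0)
    day_offsets = rng.normal(0.0, params.day_offset_sd, size=n_days)
    signal += np.repeat(day_offsets, SAMPLES_PER_DAY)

    # each meal only influences a bounded window: 30-min rise plus the decay
    # tail down to ~1% of its amplitude
    tail_min = 30.0 + np.log(100.0) / params.meal_decay
    for d in range(n_days):
        for m in params.meal_times:
            start = d * 1440.0 + m * 60.0 + rng.normal(0.0, 20.0)
            amp = params.meal_rise * rng.uniform(0.7, 1.3)
            i0 = max(int(start / 5.0), 0)
            i1 = min(int((start + tail_min) / 5.0) + 2, n)
            if i0 < i1:
                signal[i0:i1] += _meal_kernel(minutes[i0:i1], start, amp,
                                              params.meal_decay)

    # AR(1) noise with stationary SD = noise_sd
    phi = 0.9
    innov_sd = params.noise_sd * np.sqrt(1.0 - phi ** 2)
    eps = rng.normal(0.0, innov_sd, size=n)
    x0 = rng.normal(0.0, params.noise_sd) if params.noise_sd > 0 else 0.0
    noise, _ = lfilter([1.0], [1.0, -phi], eps, zi=np.array([phi * x0]))
    signal += noise

    # induced nocturnal hypoglycemia
    hypo_nights = rng.random(max(n_days - 1, 0)) < params.hypo_night_prob

    def _subtract_bump(center: int, sd_slots: float, depth: float) -> None:
        i0 = max(int(center - 4 * sd_slots), 0)
        i1 = min(int(center + 4 * sd_slots) + 1, n)
        idx = np.arange(i0, i1)
        signal[i0:i1] -= depth * np.exp(-0.5 * ((idx - center) / sd_slots) ** 2)

    for d in np.flatnonzero(hypo_nights):
        # broad evening-to-night lowering centred ~23:45 with a 3 h width:
        # by 21:00-22:00 glucose already trends ~25-40 mg/dL low, so the
        # pre-sleep window genuinely predicts the night label
        center = (d + 1) * SAMPLES_PER_DAY - 3 + int(rng.integers(-12, 13))
        _subtract_bump(center, 36.0, 55.0)
        # sustained dip (~1 h core): guarantee >= 9 consecutive samples
        # below ~60 mg/dL inside the 22:00-06:00 window
        dip_center = int(np.clip(center + rng.integers(-6, 7),
                                 d * SAMPLES_PER_DAY + 276,
                                 (d + 1) * SAMPLES_PER_DAY + 60))
        excess = signal[dip_center - 4: dip_center + 5].max() - 58.0
        if excess > 0:
            depth = excess / np.exp(-0.5 * (4.0 / 12.0) ** 2)
            _subtract_bump(dip_center, 12.0, depth)

    np.clip(signal, GLUCOSE_MIN, GLUCOSE_MAX, out=signal)
    times = pd.date_range(_BASE_DATE, periods=n, freq=STEP)
    return GlucoseSeries(patient_id, times, signal)


def inject_gaps(series: GlucoseSeries, gap_spec: list, seed: int | None = None) -> GlucoseSeries:
    """Blank out the specified slots of a (gridded) series.

    ``gap_spec`` is a list of ``(start, duration)`` pairs — start as a
    timestamp (or ISO string), duration as minutes or a timedelta.
    Overlapping gaps are rejected.  ``seed`` is accepted for interface
    symmetry with the other generators; the gaps themselves are
    deterministic.
    """
    g = series.on_grid()
    values = g.glucose.copy()
    claimed = np.zeros(len(g), dtype=bool)
    for start, duration in gap_spec:
        start = pd.Timestamp(start)
        if not isinstance(duration, pd.Timedelta):
            duration = pd.Timedelta(minutes=float(duration))
        n_slots = int(duration / STEP)
        i0 = int((start - g.times[0]) / STEP)
        if i0 < 0 or i0 + n_slots > len(g):
            raise SimValidationError(f"gap at {start} lies outside the series span")
        sl = slice(i0, i0 + n_slots)
        if claimed[sl].any():
            raise SimValidationError(f"gap at {start} overlaps a previous gap")
        claimed[sl] = True
        values[sl] = np.nan
    return GlucoseSeries(g.patient_id, g.times, values)
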