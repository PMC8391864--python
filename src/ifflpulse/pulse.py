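"""Pulse detection and ensemble pulse statistics.

A time course counts as a pulse when, on its unmasked analysis window,
the maximum is strictly interior and the signal both rises to the peak
and falls away from it by at least a threshold fraction (20% by default):

    rise  = (peak - signal[first]) / peak >= theta_rise
    decay = (peak - signal[last])  / peak >= theta_decay

The criterion is scale invariant and deliberately conservative: a
monotone approach to steady state, a boundary maximum, or a constant
signal never counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AnalysisError
from .simulate import TimeCourse

__all__ = ["PulseReport", "detect_pulse", "pulse_fraction", "reports_to_frame"]

DEFAULT_THETA_RISE = 0.2
DEFAULT_THETA_DECAY = 0.2


@dataclass(frozen=True)
class PulseReport:
    is_pulse: bool
    t_peak: float | None
    peak_value: float
    rise_fraction: float
    decay_fraction: float
    window: tuple[float, float]
    theta_rise: float = DEFAULT_THETA_RISE
    theta_decay: float = DEFAULT_THETA_DECAY


def detect_pulse(tc: TimeCourse, theta_rise: float = DEFAULT_THETA_RISE,
                 theta_decay: float = DEFAULT_THETA_DECAY) -> PulseReport:
    """Classify one GFP time course on its unmasked window.

    Ties at the maximum break to the earliest time; an all-zero signal
    reports no pulse with zero fractions.
    """
    times, signal = tc.unmasked()
    if len(times) < 5:
        raise AnalysisError(
            f"pulse detection needs >= 5 unmasked points, got {len(times)}")
    if np.any(signal < 0):
        raise AnalysisError("pulse detection expects a non-negative signal")
    window = (float(times[0]), float(times[-1]))
    i_peak = int(np.argmax(signal))          # argmax returns the earliest tie
    peak = float(signal[i_peak])
    if peak <= 0:
        return PulseReport(False, None, 0.0, 0.0, 0.0, window,
                           theta_rise, theta_decay)
    rise = float((peak - signal[0]) / peak)
    decay = float((peak - signal[-1]) / peak)
    interior = 0 < i_peak < len(signal) - 1
    is_pulse = bool(interior and rise >= theta_rise and decay >= theta_decay)
    t_peak = float(times[i_peak]) if interior else None
    return PulseReport(is_pulse, t_peak, peak, rise, decay, window,
                       theta_rise, theta_decay)


def pulse_fraction(ensemble, theta_rise: float = DEFAULT_THETA_RISE,
                   theta_decay: float = DEFAULT_THETA_DECAY) -> dict:
    """Fraction of successful ensemble trajectories per condition that pulse.

    The nominal trajectory counts alongside the draws.  Conditions whose
    every draw failed to simulate are reported as ``None`` (missing), not
    as 0.
    """
    out = {}
    for label, courses in ensemble.trajectories.items():
        ok = [tc for tc in courses if tc is not None]
        if not ok:
            out[label] = None
            continue
        hits = sum(detect_pulse(tc, theta_rise, theta_decay).is_pulse
                   for tc in ok)
        out[label] = hits / len(ok)
    return out


def reports_to_frame(reports: dict) -> pd.DataFrame:
    """Flatten ``{label: [PulseReport, ...]}`` into a tidy table."""
    rows = []
    for label, reps in reports.items():
        for i, r in enumerate(reps):
            rows.append({
                "condition": label, "trajectory": i, "is_pulse": r.is_pulse,
                "t_peak_min": r.t_peak, "peak_value": r.peak_value,
                "rise_fraction": r.rise_fraction,
                "decay_fraction": r.decay_fraction,
                "window_lo": r.window[0], "window_hi": r.window[1],
            })
    return pd.DataFrame(rows)
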