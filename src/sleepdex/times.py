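"""Circular clock-time arithmetic on the 24-hour dial.

Survey bed/wake times are clock times without a date, so every interval
computation has to respect the wrap at midnight: time in bed is the forward
arc from bedtime to wake time, a sleep midpoint is the point halfway along
that arc, and the distance between two midpoints is the shorter of the two
arcs between them.  All functions work in minutes since midnight, accept
scalars or numpy arrays, and propagate NaN for missing values.
"""

from __future__ import annotations

import numpy as np

MINUTES_PER_DAY = 1440
#: survey responses are collected in half-hour increments
GRID_MINUTES = 30


def parse_clock(value) -> float:
    """Parse an ``HH:MM`` string to minutes since midnight (NaN for missing).

    ``24:00`` is accepted as an alias for midnight (0 minutes).
    """
    if value is None:
        return np.nan
    if isinstance(value, float) and np.isnan(value):
        return np.nan
    s = str(value).strip()
    if not s or s.upper() in {"NA", "NAN"}:
        return np.nan
    hh, mm = s.split(":")
    minutes = int(hh) * 60 + int(mm)
    if not 0 <= minutes <= MINUTES_PER_DAY:
        raise ValueError(f"clock time out of range: {value!r}")
    return float(minutes % MINUTES_PER_DAY)


def format_clock(minutes) -> str:
    """Render minutes since midnight as ``HH:MM`` (empty string for NaN)."""
    if minutes is None or (isinstance(minutes, float) and np.isnan(minutes)):
        return ""
    m = int(round(minutes)) % MINUTES_PER_DAY
    return f"{m // 60:02d}:{m % 60:02d}"


def on_grid(minutes, grid: int = GRID_MINUTES):
    """True where a clock time sits on the survey's half-hour grid."""
    m = np.asarray(minutes, dtype=float)
    return np.where(np.isnan(m), True, np.mod(m, grid) == 0)


def forward_arc_minutes(start, end):
    """Minutes travelled clockwise from ``start`` to ``end`` (0..1439)."""
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    return np.mod(end - start, MINUTES_PER_DAY)


def duration_hours(bed, wake):
    """Forward arc from bedtime to wake time, in hours.

    A bed/wake pair that crosses midnight (bed 23:00, wake 07:00) yields the
    expected 8 h; identical times yield 0 h.
    """
    return forward_arc_minutes(bed, wake) / 60.0


def midpoint_minutes(bed, wake):
    """Clock time halfway along the forward arc from bed to wake.

    With bed 22:00 and wake 04:00 the midpoint is 01:00, on the far side of
    midnight from the bedtime.
    """
    bed = np.asarray(bed, dtype=float)
    return np.mod(bed + forward_arc_minutes(bed, wake) / 2.0, MINUTES_PER_DAY)


def circular_distance_hours(a, b):
    """Shorter-arc distance between two clock times, in hours (<= 12)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    d = np.abs(a - b)
    d = np.minimum(d, MINUTES_PER_DAY - d)
    return d / 60.0
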