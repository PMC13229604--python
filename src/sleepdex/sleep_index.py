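"""Sleep Lifestyle Index: survey cleaning, derived traits, and 0-8 scoring.

The index aggregates eight favorable sleep behaviors per participant: four
derived from self-reported weekday/weekend bed and wake times (adequate time
in bed, regular time in bed, healthy weekend sleep midpoint, low social
jetlag) and four from the EHR (no sleep medication, no insomnia disorder, no
sleep-related breathing disorder, no other sleep disorder).  One point per
favorable behavior; a participant with any component unresolvable (cleaned
survey value or a single-code disorder flag) gets a missing index
(complete-case aggregation).

Cleaning follows the AM/PM-misreport heuristics for self-reported clock
times: bedtimes between 08:00 and 14:00 and wake times between 18:00 and
midnight (exclusive of 00:00 itself) are set to missing, as is any time in
bed shorter than 3 h or longer than 18 h.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import times

# cleaning windows, minutes since midnight
BEDTIME_INVALID = (8 * 60, 14 * 60)       # closed interval [08:00, 14:00]
WAKETIME_INVALID = (18 * 60, 24 * 60)     # half-open [18:00, 24:00): 00:00 kept
TIB_BOUNDS_HOURS = (3.0, 18.0)            # closed; outside -> missing

# component cutpoints (boundary conventions mirror the printed symbols:
# closed for the 7-9 h window and the 02:00-04:00 midpoint window, strict
# for the <60 min irregularity and <2 h jetlag rules)
ADEQUATE_TIB_HOURS = (7.0, 9.0)
REGULAR_TIB_MAX_HOURS = 1.0
HEALTHY_MIDPOINT = (2 * 60, 4 * 60)
SOCIAL_JETLAG_MAX_HOURS = 2.0

TIME_COLUMNS = ["weekday_bed", "weekday_wake", "weekend_bed", "weekend_wake"]

BEHAVIOR_COMPONENTS = [
    "adequate_tib",
    "regular_tib",
    "healthy_midpoint",
    "low_social_jetlag",
]
EHR_COMPONENTS = [
    "no_sleep_medication",
    "no_insomnia_disorder",
    "no_breathing_disorder",
    "no_other_sleep_disorder",
]
COMPONENTS = BEHAVIOR_COMPONENTS + EHR_COMPONENTS

_FLAG_TO_COMPONENT = {
    "sleep_medication": "no_sleep_medication",
    "insomnia_disorder": "no_insomnia_disorder",
    "breathing_disorder": "no_breathing_disorder",
    "other_sleep_disorder": "no_other_sleep_disorder",
}


def clean_survey(survey: pd.DataFrame,
                 bedtime_invalid: tuple = BEDTIME_INVALID,
                 waketime_invalid: tuple = WAKETIME_INVALID) -> pd.DataFrame:
    """Blank out implausible bed/wake times (likely AM/PM misreports).

    ``survey`` holds clock times in minutes since midnight (floats, NaN for
    missing) in the four ``TIME_COLUMNS``.  Returns a cleaned copy; the
    counts removed per rule are stored in ``.attrs["cleaning_counts"]``.
    """
    out = survey.copy()
    counts: dict[str, int] = {}
    lo_b, hi_b = bedtime_invalid
    lo_w, hi_w = waketime_invalid
    for col in ("weekday_bed", "weekend_bed"):
        v = out[col].astype(float)
        bad = (v >= lo_b) & (v <= hi_b)
        counts[col] = int(bad.sum())
        out[col] = v.mask(bad)
    for col in ("weekday_wake", "weekend_wake"):
        v = out[col].astype(float)
        bad = (v >= lo_w) & (v < hi_w)
        counts[col] = int(bad.sum())
        out[col] = v.mask(bad)
    out.attrs["cleaning_counts"] = counts
    return out


def time_in_bed(bed, wake, bounds=TIB_BOUNDS_HOURS):
    """Hours from bedtime to wake time on the 24 h circle.

    Values outside ``bounds`` (default 3-18 h) are implausible and become
    NaN, as does any pair with a missing member.
    """
    bed = np.asarray(bed, dtype=float)
    wake = np.asarray(wake, dtype=float)
    tib = times.duration_hours(bed, wake)
    tib = np.where(np.isnan(bed) | np.isnan(wake), np.nan, tib)
    return np.where((tib < bounds[0]) | (tib > bounds[1]), np.nan, tib)


def weighted_time_in_bed(tib_weekday, tib_weekend):
    """Weekly time in bed: 5/7 weekday + 2/7 weekend weighting."""
    wd = np.asarray(tib_weekday, dtype=float)
    we = np.asarray(tib_weekend, dtype=float)
    return (5.0 * wd + 2.0 * we) / 7.0


def sleep_midpoint(bed, wake):
    """Clock time halfway through the bed-to-wake interval (NaN-propagating)."""
    bed = np.asarray(bed, dtype=float)
    wake = np.asarray(wake, dtype=float)
    mid = times.midpoint_minutes(bed, wake)
    return np.where(np.isnan(bed) | np.isnan(wake), np.nan, mid)


def social_jetlag(midpoint_weekday, midpoint_weekend):
    """Circular absolute difference between weekend and weekday midpoints (h).

    The distance is taken on the 24 h dial, so midpoints of 23:00 and 01:00
    differ by 2 h, never 22 h; the result is capped at 12 h by construction.
    """
    a = np.asarray(midpoint_weekday, dtype=float)
    b = np.asarray(midpoint_weekend, dtype=float)
    d = times.circular_distance_hours(a, b)
    return np.where(np.isnan(a) | np.isnan(b), np.nan, d)


def derive_traits(survey: pd.DataFrame) -> pd.DataFrame:
    """Compute the four derived sleep traits from a *cleaned* survey table.

    Returns one row per participant with tib_weekday, tib_weekend,
    tib_weighted, tib_irregularity, midpoint_weekday, midpoint_weekend
    (minutes since midnight) and social_jetlag (hours).
    """
    t = pd.DataFrame({"participant_id": survey["participant_id"].to_numpy()})
    tib_wd = time_in_bed(survey["weekday_bed"], survey["weekday_wake"])
    tib_we = time_in_bed(survey["weekend_bed"], survey["weekend_wake"])
    t["tib_weekday"] = tib_wd
    t["tib_weekend"] = tib_we
    t["tib_weighted"] = weighted_time_in_bed(tib_wd, tib_we)
    t["tib_irregularity"] = np.abs(tib_wd - tib_we)
    t["midpoint_weekday"] = sleep_midpoint(survey["weekday_bed"], survey["weekday_wake"])
    t["midpoint_weekend"] = sleep_midpoint(survey["weekend_bed"], survey["weekend_wake"])
    t["social_jetlag"] = social_jetlag(t["midpoint_weekday"], t["midpoint_weekend"])
    return t


def score_components(traits: pd.DataFrame, flags: pd.DataFrame) -> pd.DataFrame:
    """Score the eight index components as 1 (favorable) / 0 / NaN (missing).

    Behavioral components come from the derived traits; EHR components invert
    the disorder/medication flags from :mod:`sleepdex.phenotypes` (a flag of
    ``present`` is unfavorable, ``absent`` favorable, ``missing`` missing).
    Participants present in ``traits`` but absent from ``flags`` get missing
    EHR components.
    """
    comp = pd.DataFrame({"participant_id": traits["participant_id"].to_numpy()})

    def _tri(values, favorable_mask):
        v = np.asarray(values, dtype=float)
        return np.where(np.isnan(v), np.nan, favorable_mask.astype(float))

    tw = traits["tib_weighted"].to_numpy(dtype=float)
    comp["adequate_tib"] = _tri(tw, (tw >= ADEQUATE_TIB_HOURS[0]) & (tw <= ADEQUATE_TIB_HOURS[1]))
    irr = traits["tib_irregularity"].to_numpy(dtype=float)
    comp["regular_tib"] = _tri(irr, irr < REGULAR_TIB_MAX_HOURS)
    mid = traits["midpoint_weekend"].to_numpy(dtype=float)
    comp["healthy_midpoint"] = _tri(mid, (mid >= HEALTHY_MIDPOINT[0]) & (mid <= HEALTHY_MIDPOINT[1]))
    sj = traits["social_jetlag"].to_numpy(dtype=float)
    comp["low_social_jetlag"] = _tri(sj, sj < SOCIAL_JETLAG_MAX_HOURS)

    fl = flags.set_index("participant_id")
    idx = comp["participant_id"]
    for flag_col, comp_col in _FLAG_TO_COMPONENT.items():
        if flag_col == "sleep_medication":
            # boolean exposure flag: never missing when the participant has flags
            aligned = fl[flag_col].reindex(idx)
            vals = np.where(aligned.isna(), np.nan,
                            (~aligned.astype("boolean").fillna(False)).astype(float))
        else:
            aligned = fl[flag_col].reindex(idx)
            vals = np.select(
                [aligned.eq("absent"), aligned.eq("present")],
                [1.0, 0.0],
                default=np.nan,
            )
        comp[comp_col] = vals
    return comp


def aggregate_index(components: pd.DataFrame) -> pd.DataFrame:
    """Sum favorable components into the 0-8 index; any missing -> missing.

    Complete-case aggregation: the printed index is only defined for
    participants with all eight components resolved.
    """
    out = components.copy()
    mat = out[COMPONENTS].to_numpy(dtype=float)
    total = mat.sum(axis=1)
    total[np.isnan(mat).any(axis=1)] = np.nan
    out["index"] = total
    return out


def build_sleep_index(survey: pd.DataFrame, flags: pd.DataFrame):
    """Full survey -> index pipeline: clean, derive, score, aggregate.

    Returns ``(traits, index_table)``; the cleaning counts of
    :func:`clean_survey` are carried over on ``traits.attrs``.
    """
    cleaned = clean_survey(survey)
    traits = derive_traits(cleaned)
    traits.attrs["cleaning_counts"] = cleaned.attrs["cleaning_counts"]
    index = aggregate_index(score_components(traits, flags))
    return traits, index
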