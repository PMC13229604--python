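"""Phecode case/control phenotyping from ICD billing-code streams.

Raw EHR diagnosis events are noisy: the same code is often billed several
times on one encounter, codes from other vocabularies leak in, and only
events near the survey date are informative for a cross-sectional analysis.
This module applies the standard PheWAS phenotyping recipe:

* drop non-ICD-9/10 rows and same-day duplicate diagnoses;
* keep events within a symmetric +/- ``window_years`` calendar window around
  each participant's reference (survey completion) date, closed at both ends;
* roll ICD codes up to phecodes and call each participant *case* (>= 2
  qualifying codes), *control* (0 codes) or *excluded* (exactly 1 code);
* derive the tri-state sleep-disorder flags and the sleep-medication flag
  that feed the Sleep Lifestyle Index, where *present* additionally requires
  codes on >= 2 distinct dates.

Control exclusion ranges of full phecode maps are deliberately not applied;
phenotyping here is exactly the two-code/zero-code rule.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STATUS_CASE = "case"
STATUS_CONTROL = "control"
STATUS_EXCLUDED = "excluded"

FLAG_CATEGORIES = ["insomnia_disorder", "breathing_disorder", "other_sleep_disorder"]


def deduplicate_events(events: pd.DataFrame) -> pd.DataFrame:
    """Remove same-day duplicate diagnoses and non-ICD-9/10 rows.

    Keeps at most one event per (participant, version, code, date); output is
    stably ordered by (participant, date, code).  Raises ``ValueError`` on an
    unparseable date, identifying the offending row.
    """
    ev = events.copy()
    dates = pd.to_datetime(ev["date"], format="mixed", errors="coerce")
    bad = dates.isna() & ev["date"].notna() & (ev["date"].astype(str).str.len() > 0)
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"unparseable event date {ev['date'].iloc[i]!r} at row {i}")
    ev["date"] = dates
    version = pd.to_numeric(ev["icd_version"], errors="coerce")
    n_dropped = int((~version.isin([9, 10])).sum())
    if n_dropped:
        logger.info("dropped %d events with non-ICD-9/10 version", n_dropped)
    ev = ev[version.isin([9, 10])].copy()
    ev["icd_version"] = version[version.isin([9, 10])].astype(int)
    ev = ev.drop_duplicates(subset=["participant_id", "icd_version", "code", "date"])
    return ev.sort_values(["participant_id", "date", "code"], kind="stable").reset_index(drop=True)


def _window_bounds(reference_dates: pd.Series, window_years: int):
    """Closed calendar bounds ref -/+ window_years for each participant.

    Calendar arithmetic (not a fixed day count), so an event dated exactly
    five years from the reference sits on the closed boundary regardless of
    leap days.  Offsets are computed once per unique date for speed.
    """
    uniq = pd.Series(reference_dates.dropna().unique())
    lo_map = dict(zip(uniq, uniq - pd.DateOffset(years=window_years)))
    hi_map = dict(zip(uniq, uniq + pd.DateOffset(years=window_years)))
    lo = pd.to_datetime(reference_dates.map(lo_map))
    hi = pd.to_datetime(reference_dates.map(hi_map))
    return lo, hi


def window_filter(events: pd.DataFrame, reference_dates: pd.Series,
                  window_years: int = 5):
    """Keep events within +/- ``window_years`` of the participant's reference date.

    ``reference_dates`` is indexed by participant_id.  The window is symmetric
    and closed: an event exactly ``window_years`` calendar years before or
    after the reference date is retained.  Returns ``(in_window_events,
    unusable_participant_ids)`` where the second element lists participants
    whose reference date is missing; their events are excluded from the
    result but reported rather than silently dropped.
    """
    refs = pd.to_datetime(reference_dates)
    ev = events.copy()
    ev["date"] = pd.to_datetime(ev["date"])
    ref = refs.reindex(ev["participant_id"]).to_numpy()
    unusable = sorted(set(ev.loc[pd.isna(ref), "participant_id"]))
    if unusable:
        logger.warning("%d participants have events but no reference date; "
                       "their events are unusable", len(unusable))
    lo, hi = _window_bounds(refs, window_years)
    lo = lo.reindex(ev["participant_id"]).to_numpy()
    hi = hi.reindex(ev["participant_id"]).to_numpy()
    d = ev["date"].to_numpy()
    keep = (~pd.isna(ref)) & (d >= lo) & (d <= hi)
    return ev[keep].reset_index(drop=True), unusable


def call_phecodes(events: pd.DataFrame, phecode_map: pd.DataFrame,
                  reference_dates: pd.Series, min_cases: int = 100,
                  window_years: int = 5):
    """Roll windowed ICD events up to phecodes and call case/control status.

    Parameters
    ----------
    events : deduplicated ICD event table (participant_id, icd_version, code, date).
    phecode_map : rows of (icd_version, icd_code, phecode_id, phecode_label,
        disease_group); one ICD code may map to several phecodes.
    reference_dates : Series of survey-completion dates indexed by
        participant_id; defines both the event window and the participant
        universe of the calls table.
    min_cases : phecodes with fewer cases are dropped from the *retained*
        list (their calls are still emitted).

    Returns
    -------
    calls : DataFrame (participant_id, phecode_id, status, n_qualifying_codes)
        over the full participant x phecode grid.  Participants with a
        missing reference date are omitted and listed in
        ``calls.attrs["unusable_participants"]``.
    retained : list of phecode_ids with >= ``min_cases`` cases.
    """
    in_window, unusable = window_filter(events, reference_dates, window_years)
    mapped = in_window.merge(
        phecode_map.rename(columns={"icd_code": "code"}),
        on=["icd_version", "code"], how="left",
    )
    n_unmapped = int(mapped["phecode_id"].isna().sum())
    if n_unmapped:
        logger.info("%d windowed events had ICD codes absent from the phecode map",
                    n_unmapped)
    mapped = mapped.dropna(subset=["phecode_id"])

    counts = (mapped.groupby(["participant_id", "phecode_id"], sort=False)
              .size().rename("n_qualifying_codes"))

    participants = reference_dates.dropna().index
    phecodes = pd.unique(phecode_map["phecode_id"])
    grid = pd.MultiIndex.from_product([participants, phecodes],
                                      names=["participant_id", "phecode_id"])
    calls = counts.reindex(grid, fill_value=0).reset_index()
    n = calls["n_qualifying_codes"].to_numpy()
    calls["status"] = np.select(
        [n >= 2, n == 0], [STATUS_CASE, STATUS_CONTROL], default=STATUS_EXCLUDED)
    calls = calls[["participant_id", "phecode_id", "status", "n_qualifying_codes"]]
    calls.attrs["unusable_participants"] = unusable
    calls.attrs["n_unmapped_events"] = n_unmapped

    case_counts = calls[calls["status"] == STATUS_CASE].groupby("phecode_id").size()
    retained = sorted(case_counts[case_counts >= min_cases].index.tolist())
    return calls, retained


def derive_sleep_flags(events: pd.DataFrame, med_events: pd.DataFrame,
                       classification: pd.DataFrame,
                       reference_dates: pd.Series,
                       window_years: int = 5) -> pd.DataFrame:
    """Tri-state sleep-disorder flags plus the sleep-medication flag.

    ``classification`` labels sleep-relevant codes with columns
    (code_type in {icd9, icd10, med}, code, category in
    {insomnia_disorder, breathing_disorder, other_sleep_disorder,
    sleep_medication}).  For each disorder category: *present* requires >= 2
    codes on >= 2 distinct dates within the window, *absent* means no code at
    all, anything in between (one code, or several on a single date) is
    *missing*.  ``sleep_medication`` is True iff >= 1 listed medication event
    falls in the window.
    """
    for required in ("code_type", "code", "category"):
        if required not in classification.columns:
            raise ValueError(f"classification table lacks required column {required!r}")

    icd_class = classification[classification["code_type"].isin(["icd9", "icd10"])].copy()
    icd_class["icd_version"] = icd_class["code_type"].map({"icd9": 9, "icd10": 10})
    in_window, _ = window_filter(events, reference_dates, window_years)
    tagged = in_window.merge(icd_class[["icd_version", "code", "category"]],
                             on=["icd_version", "code"], how="inner")

    participants = reference_dates.dropna().index
    flags = pd.DataFrame({"participant_id": participants})
    for cat in FLAG_CATEGORIES:
        sub = tagged[tagged["category"] == cat]
        g = sub.groupby("participant_id").agg(
            n_codes=("code", "size"), n_dates=("date", "nunique"))
        g = g.reindex(participants).fillna(0)
        flags[cat] = np.select(
            [g["n_dates"].to_numpy() >= 2, g["n_codes"].to_numpy() == 0],
            ["present", "absent"], default="missing")

    med_codes = set(classification.loc[
        (classification["code_type"] == "med") &
        (classification["category"] == "sleep_medication"), "code"])
    med = med_events[med_events["code"].isin(med_codes)].copy()
    if len(med):
        med_in, _ = window_filter(med, reference_dates, window_years)
        exposed = set(med_in["participant_id"])
    else:
        exposed = set()
    flags["sleep_medication"] = flags["participant_id"].isin(exposed)
    return flags
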