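"""Tab-separated readers and writers for the pipeline's tables.

All on-disk formats are plain TSV with headers; clock times are serialized
as ``HH:MM`` strings, dates as ISO-8601, and the dosage matrix as
participants x ``variant:allele`` columns.  Readers return the in-memory
representations the rest of the package uses (minutes since midnight,
``pd.Timestamp`` dates), so write -> read round-trips are lossless.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import times
from .simulate import SyntheticCohort

SURVEY_TIME_COLUMNS = ["weekday_bed", "weekday_wake", "weekend_bed", "weekend_wake"]


def write_tsv(df: pd.DataFrame, path, index=False):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%d")
    out.to_csv(path, sep="\t", index=index)
    return path


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_survey(survey: pd.DataFrame, path):
    out = survey.copy()
    for col in SURVEY_TIME_COLUMNS:
        out[col] = [times.format_clock(v) for v in out[col]]
    return write_tsv(out, path)


def read_survey(path) -> pd.DataFrame:
    df = read_tsv(path, dtype={c: str for c in SURVEY_TIME_COLUMNS})
    for col in SURVEY_TIME_COLUMNS:
        df[col] = [times.parse_clock(v) for v in df[col]]
    df["completion_date"] = pd.to_datetime(df["completion_date"])
    return df


def read_participants(path) -> pd.DataFrame:
    df = read_tsv(path)
    for col in ("enrollment_date", "survey_date"):
        if col in df.columns:
            df[col] = pd.to_datetime(df[col])
    return df


def read_events(path) -> pd.DataFrame:
    df = read_tsv(path)
    df["date"] = pd.to_datetime(df["date"])
    return df


def write_dosages(dosages: pd.DataFrame, path):
    return write_tsv(dosages.reset_index(), path)


def read_dosages(path) -> pd.DataFrame:
    return read_tsv(path).set_index("participant_id")


def write_cohort(cohort: SyntheticCohort, directory) -> dict:
    """Write the 7 data tables + truth.json; returns a name -> path manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "participants": write_tsv(cohort.participants, directory / "participants.tsv"),
        "survey": write_survey(cohort.survey, directory / "survey.tsv"),
        "icd_events": write_tsv(cohort.icd_events, directory / "icd_events.tsv"),
        "med_events": write_tsv(cohort.med_events, directory / "med_events.tsv"),
        "kinship": write_tsv(cohort.kinship_pairs, directory / "kinship.tsv"),
        "weights": write_tsv(cohort.weights, directory / "weights.tsv"),
        "dosages": write_dosages(cohort.dosages, directory / "dosages.tsv"),
    }
    truth_path = directory / "truth.json"
    truth_path.write_text(json.dumps(cohort.truth, indent=2, default=str))
    manifest["truth"] = truth_path
    return {k: Path(v) for k, v in manifest.items()}


def read_cohort(directory) -> SyntheticCohort:
    """Read a cohort written by :func:`write_cohort`."""
    directory = Path(directory)
    truth = json.loads((directory / "truth.json").read_text())
    med = read_tsv(directory / "med_events.tsv")
    if len(med):
        med["date"] = pd.to_datetime(med["date"])
    else:
        med["date"] = pd.to_datetime(med.get("date", pd.Series(dtype=object)))
    return SyntheticCohort(
        participants=read_participants(directory / "participants.tsv"),
        survey=read_survey(directory / "survey.tsv"),
        dosages=read_dosages(directory / "dosages.tsv"),
        weights=read_tsv(directory / "weights.tsv"),
        icd_events=read_events(directory / "icd_events.tsv"),
        med_events=med,
        kinship_pairs=read_tsv(directory / "kinship.tsv"),
        truth=truth,
    )


def write_components(index_table: pd.DataFrame, path):
    """sleep_index.tsv: components coded {1,0,NA} plus the 0-8 index."""
    out = index_table.copy()
    for col in out.columns:
        if col == "participant_id":
            continue
        v = out[col].astype(float)
        out[col] = np.where(np.isnan(v), "NA",
                            pd.Series(v).fillna(0).astype(int).astype(str))
    return write_tsv(out, path)
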