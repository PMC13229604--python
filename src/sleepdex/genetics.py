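"""Polygenic score computation, standardization, and relatedness pruning.

The polygenic sleep-health score is the weighted sum of effect-allele
dosages over a (pre-shrunk) variant weight table.  Dosage columns are named
``"<variant_id>:<counted_allele>"``; when the counted allele is the weight
table's *other* allele the dosage is flipped to ``2 - d`` before weighting,
and variants whose counted allele matches neither allele are dropped with a
logged count.  Scores are z-standardized (sample SD, n-1 denominator) over
the analytic sample after one member of each related pair (kinship
coefficient > 0.0625, strict) has been removed.
"""

from __future__ import annotations

import logging
from collections import defaultdict

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

KINSHIP_THRESHOLD = 0.0625


def split_dosage_columns(columns) -> pd.DataFrame:
    """Parse ``variant:allele`` dosage column names into a small table."""
    rows = []
    for col in columns:
        if ":" not in col:
            raise ValueError(f"dosage column {col!r} lacks a ':counted_allele' suffix")
        vid, allele = col.rsplit(":", 1)
        rows.append((col, vid, allele))
    return pd.DataFrame(rows, columns=["column", "variant_id", "counted_allele"])


def harmonize_and_score(weights: pd.DataFrame, dosages: pd.DataFrame) -> pd.DataFrame:
    """Raw polygenic score per participant.

    Parameters
    ----------
    weights : table with variant_id, effect_allele, other_allele, weight.
    dosages : DataFrame indexed by participant_id with ``variant:allele``
        columns holding effect-allele counts in [0, 2].

    Returns
    -------
    DataFrame (participant_id, raw) with
    ``raw = sum_i weight_i * harmonized_dosage_i`` over retained variants.

    Raises ``ValueError`` when no variant overlaps; warns when more than half
    of the weight table's variants are dropped.
    """
    cols = split_dosage_columns(dosages.columns)
    merged = cols.merge(weights, on="variant_id", how="inner")
    match_eff = merged["counted_allele"] == merged["effect_allele"]
    match_oth = merged["counted_allele"] == merged["other_allele"]
    usable = merged[match_eff | match_oth]
    n_allele_dropped = len(merged) - len(usable)
    if n_allele_dropped:
        logger.warning("%d variants dropped: counted allele matches neither "
                       "effect nor other allele", n_allele_dropped)
    if usable.empty:
        raise ValueError("no overlapping variants between weights and dosages")
    if len(usable) < 0.5 * len(weights):
        logger.warning("only %d of %d weight-table variants usable (>50%% dropped)",
                       len(usable), len(weights))

    mat = dosages[usable["column"].to_numpy()].to_numpy(dtype=float)
    flip = (usable["counted_allele"] == usable["other_allele"]).to_numpy()
    mat[:, flip] = 2.0 - mat[:, flip]
    raw = mat @ usable["weight"].to_numpy(dtype=float)
    return pd.DataFrame({"participant_id": dosages.index.to_numpy(), "raw": raw})


def standardize(scores: pd.DataFrame, sample_ids=None) -> pd.DataFrame:
    """Z-standardize raw scores over the analytic sample.

    ``sample_ids`` restricts the rows (e.g. the post-pruning unrelated set);
    mean and SD (n-1 denominator) are computed over exactly those rows, so
    the returned table has mean 0 and SD 1 to numerical precision.
    """
    out = scores if sample_ids is None else scores[
        scores["participant_id"].isin(set(sample_ids))]
    out = out.copy()
    if len(out) < 2:
        raise ValueError("standardization needs at least 2 participants")
    raw = out["raw"].to_numpy(dtype=float)
    sd = raw.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance in raw polygenic scores")
    out["standardized"] = (raw - raw.mean()) / sd
    return out.reset_index(drop=True)


def prune_related(pairs: pd.DataFrame, threshold: float = KINSHIP_THRESHOLD,
                  all_ids=None):
    """Greedily remove samples until no related pair survives.

    A pair is related when its kinship coefficient is strictly greater than
    ``threshold``.  Removal is greedy by descending degree in the relatedness
    graph; among equally connected samples the lexicographically greatest id
    is removed first, which makes the output deterministic (for an isolated
    pair A-B, B goes).

    Returns ``(kept_ids, removed_ids)`` as sorted lists.  ``kept_ids`` covers
    ``all_ids`` when given, otherwise the ids appearing in ``pairs``.
    """
    adj: dict[str, set] = defaultdict(set)
    related = pairs[pairs["coefficient"] > threshold]
    for a, b in zip(related["id_a"], related["id_b"]):
        if a != b:
            adj[a].add(b)
            adj[b].add(a)
    removed = []
    while True:
        degrees = {v: len(nb) for v, nb in adj.items() if nb}
        if not degrees:
            break
        dmax = max(degrees.values())
        victim = max(v for v, d in degrees.items() if d == dmax)
        removed.append(victim)
        for nb in adj.pop(victim):
            adj[nb].discard(victim)
    universe = set(all_ids) if all_ids is not None else (
        set(pairs["id_a"]) | set(pairs["id_b"]))
    kept = sorted(universe - set(removed))
    return kept, sorted(removed)
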