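"""Independent nested-loop oracles shared by the test suite."""

import pandas as pd


def oracle_calls(events, pmap, refs, window_years=5):
    """Nested-loop recount of the case/control/excluded rule."""
    from datetime import date

    def in_window(ev_date, ref):
        def shift(d, years):
            try:
                return d.replace(year=d.year + years)
            except ValueError:          # Feb 29 -> Feb 28
                return d.replace(year=d.year + years, day=28)
        return shift(ref, -window_years) <= ev_date <= shift(ref, window_years)

    lookup = {}
    for _, row in pmap.iterrows():
        lookup.setdefault((row["icd_version"], row["icd_code"]), []).append(
            row["phecode_id"])
    statuses = {}
    for pid, ref in refs.items():
        if pd.isna(ref):
            continue
        seen = set()
        counts = {}
        for _, ev in events.iterrows():
            if ev["participant_id"] != pid:
                continue
            if ev["icd_version"] not in (9, 10):
                continue
            key = (ev["icd_version"], ev["code"], ev["date"])
            if key in seen:
                continue
            seen.add(key)
            if not in_window(pd.Timestamp(ev["date"]).date(), ref.date()):
                continue
            for phe in lookup.get((ev["icd_version"], ev["code"]), []):
                counts[phe] = counts.get(phe, 0) + 1
        for phe in pmap["phecode_id"].unique():
            k = counts.get(phe, 0)
            statuses[(pid, phe)] = ("case" if k >= 2
                                    else "control" if k == 0 else "excluded")
    return statuses
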