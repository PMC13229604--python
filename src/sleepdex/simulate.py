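"""Synthetic biobank cohort with planted, recoverable effect sizes.

The generator emulates the full data model a survey+EHR+genotype analysis
consumes: a participant table with covariates, a sleep survey on the
half-hour clock grid, ICD and medication event streams, a dosage matrix with
a variant weight table, and a kinship pair list.  Every planted parameter is
chosen so the downstream pipeline can recover it:

* the polygenic score raises the probability of each of the eight favorable
  index components by ``prs_index_beta / 8`` per SD (clipped linear
  probability), so the regression slope of the 0-8 index on the
  standardized score equals ``prs_index_beta`` exactly in expectation;
* survey bed/wake times are *inverse-scored*: the favorable/unfavorable
  state of the four behavioral components is drawn first and clock times on
  the 30-minute grid are then constructed to reproduce those states exactly
  through the cleaning and scoring rules (including boundary conventions);
* disease status per outcome follows
  ``logit(p) = alpha + log(OR_prs)*z + log(OR_index)*index +
  interaction*z*index + gamma'covariates`` with ``alpha`` solved so the
  marginal prevalence matches the spec; cases then emit >= 2 dated ICD codes
  inside the +/- 5-year survey window, except engineered fractions that get
  exactly one code (``one_code_rate``) or codes outside the window
  (``window_violation_rate``);
* a configurable fraction of bedtimes is shifted 12 h into the implausible
  morning window to emulate AM/PM misreporting.

The ``truth`` record on the returned cohort echoes the configuration and the
solved intercepts so recovery tests can compare estimates to ground truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from . import maps, sleep_index

SURVEY_EPOCH = pd.Timestamp("2016-06-15")

#: baseline probability that each component is favorable, loosely matching
#: the prevalence profile of a clinical-biobank survey cohort (rare coded
#: sleep disorders, common favorable behavioral traits)
COMPONENT_BASE_RATES = {
    "adequate_tib": 0.75,
    "regular_tib": 0.70,
    "healthy_midpoint": 0.55,
    "low_social_jetlag": 0.85,
    "no_sleep_medication": 0.90,
    "no_insomnia_disorder": 0.981,
    "no_breathing_disorder": 0.965,
    "no_other_sleep_disorder": 0.971,
}

#: mild covariate effects on the disease logit (age and BMI centered)
OUTCOME_COVARIATE_EFFECTS = {
    "age": 0.01,        # per year
    "sex_male": 0.15,
    "bmi": 0.02,        # per kg/m^2
    "charlson": 0.10,   # per point
}

#: mild confounding: older age slightly lowers the probability of each
#: favorable *behavioral* component (the rare EHR components are left
#: unconfounded so their probabilities keep clear of the clipping bounds)
CONFOUND_AGE_PER_COMPONENT = -0.10 / 8  # per SD of age, per component


@dataclass
class OutcomeSpec:
    """One planted disease outcome."""
    phecode_id: str
    prevalence: float
    or_per_sd_prs: float = 1.0
    or_per_index_unit: float = 1.0
    interaction_log_or: float = 0.0


def default_outcome_specs():
    """Planted outcomes with effect sizes in the range biobank scans report:
    per-SD polygenic ORs around 0.85-0.95 and per-index-unit ORs around
    0.7-0.85, plus one fully null outcome."""
    return [
        OutcomeSpec("296.2", 0.15, 0.90, 0.70, 0.0),
        OutcomeSpec("300.1", 0.12, 0.92, 0.72, 0.0),
        OutcomeSpec("278.1", 0.18, 0.85, 0.85, 0.0),
        OutcomeSpec("401.1", 0.25, 1.00, 1.00, 0.0),
    ]


@dataclass
class SimulationConfig:
    n_participants: int = 15884
    n_variants: int = 100
    allele_freq_range: tuple = (0.05, 0.5)
    prs_index_beta: float = 0.05
    outcome_specs: list = field(default_factory=default_outcome_specs)
    ampm_misreport_rate: float = 0.01
    one_code_rate: float = 0.05
    window_violation_rate: float = 0.05
    background_code_rate: float = 0.8
    junk_code_rate: float = 0.01
    unmapped_code_rate: float = 0.02
    related_pair_fraction: float = 0.05
    survey_response_rate: float = 1.0
    window_years: int = 5
    seed: int = 0

    def validate(self):
        if self.n_participants < 2:
            raise ValueError("n_participants must be >= 2")
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        lo, hi = self.allele_freq_range
        if not (0 < lo <= hi < 1):
            raise ValueError("allele_freq_range must lie in (0, 1)")
        for name in ("ampm_misreport_rate", "one_code_rate",
                     "window_violation_rate", "junk_code_rate",
                     "unmapped_code_rate", "related_pair_fraction",
                     "survey_response_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be a proportion in [0, 1]")
        for spec in self.outcome_specs:
            if not 0 < spec.prevalence < 1:
                raise ValueError(f"prevalence for {spec.phecode_id} must be in (0, 1)")
            if spec.or_per_sd_prs <= 0 or spec.or_per_index_unit <= 0:
                raise ValueError(f"odds ratios for {spec.phecode_id} must be positive")
        return self

    def to_dict(self):
        d = dataclasses.asdict(self)
        d["outcome_specs"] = [dataclasses.asdict(s) if dataclasses.is_dataclass(s)
                              else dict(s) for s in self.outcome_specs]
        d["allele_freq_range"] = list(self.allele_freq_range)
        return d


@dataclass
class SyntheticCohort:
    participants: pd.DataFrame
    survey: pd.DataFrame
    dosages: pd.DataFrame
    weights: pd.DataFrame
    icd_events: pd.DataFrame
    med_events: pd.DataFrame
    kinship_pairs: pd.DataFrame
    truth: dict


# --------------------------------------------------------------------------
# clock-time realization: pick grid times that score to the wanted states

_TIB_GRID = np.arange(5.0, 12.01, 0.5)


def _tib_pair_classes():
    """(adequate, regular) -> list of (tib_weekday, tib_weekend) grid pairs."""
    classes = {(a, r): [] for a in (0, 1) for r in (0, 1)}
    for a in _TIB_GRID:
        for b in _TIB_GRID:
            if abs(a - b) > 3.0:
                continue  # keep irregularity realistic (< 3 h)
            w = float(sleep_index.weighted_time_in_bed(a, b))
            adequate = int(sleep_index.ADEQUATE_TIB_HOURS[0] <= w
                           <= sleep_index.ADEQUATE_TIB_HOURS[1])
            regular = int(abs(a - b) < sleep_index.REGULAR_TIB_MAX_HOURS)
            classes[(adequate, regular)].append((float(a), float(b)))
    return {k: np.array(v) for k, v in classes.items()}


_PAIR_CLASSES = _tib_pair_classes()

_QUARTER = 0.25


def _grid(lo, hi):
    return np.round(np.arange(lo, hi + 1e-9, _QUARTER), 2)

# weekend-midpoint candidates (hours), favorable = closed [2, 4] window
_MID_FAV = _grid(2.0, 4.0)
_MID_UNFAV = np.concatenate([_grid(0.5, 1.75), _grid(4.25, 5.75)])
# social-jetlag offsets (hours), favorable strictly < 2
_JET_FAV = _grid(0.0, 1.75)
_JET_UNFAV = _grid(2.0, 4.0)


def _choose_aligned(rng, candidates, need_quarter_offset):
    """Pick one candidate per row whose phase mod 0.5 h matches the request."""
    out = np.empty(need_quarter_offset.shape, dtype=float)
    for offset, mask in ((0.0, ~need_quarter_offset), (0.25, need_quarter_offset)):
        pool = candidates[np.mod(candidates, 0.5) == offset]
        k = int(mask.sum())
        if k:
            out[mask] = pool[rng.integers(0, len(pool), size=k)]
    return out


def _realize_survey_times(rng, comp):
    """Bed/wake clock times (minutes) reproducing the behavioral components.

    ``comp`` holds 0/1 columns for the four behavioral components.  Returns
    arrays (weekday_bed, weekday_wake, weekend_bed, weekend_wake) in minutes
    since midnight, all on the 30-minute grid, none falling in the cleaning
    windows, and scoring back to exactly the requested component states.
    """
    n = len(comp)
    t_wd = np.empty(n)
    t_we = np.empty(n)
    for (a, r), pairs in _PAIR_CLASSES.items():
        mask = (comp["adequate_tib"] == a) & (comp["regular_tib"] == r)
        k = int(mask.sum())
        if k:
            picks = pairs[rng.integers(0, len(pairs), size=k)]
            t_wd[mask.to_numpy()] = picks[:, 0]
            t_we[mask.to_numpy()] = picks[:, 1]

    # weekend midpoint: phase must keep bed/wake on the half-hour grid
    need_q_we = np.mod(t_we / 2.0, 0.5) == 0.25
    m_we = np.empty(n)
    for fav, cands in ((1, _MID_FAV), (0, _MID_UNFAV)):
        mask = (comp["healthy_midpoint"] == fav).to_numpy()
        if mask.any():
            m_we[mask] = _choose_aligned(rng, cands, need_q_we[mask])

    # weekday midpoint = weekend midpoint + jetlag offset, phase-aligned to t_wd
    need_q_wd = np.mod((t_wd / 2.0 - m_we), 0.5) == 0.25
    j = np.empty(n)
    for fav, cands in ((1, _JET_FAV), (0, _JET_UNFAV)):
        mask = (comp["low_social_jetlag"] == fav).to_numpy()
        if mask.any():
            j[mask] = _choose_aligned(rng, cands, need_q_wd[mask])
    m_wd = m_we + j

    weekend_bed = np.mod(m_we - t_we / 2.0, 24.0) * 60.0
    weekend_wake = np.mod(m_we + t_we / 2.0, 24.0) * 60.0
    weekday_bed = np.mod(m_wd - t_wd / 2.0, 24.0) * 60.0
    weekday_wake = np.mod(m_wd + t_wd / 2.0, 24.0) * 60.0
    return weekday_bed, weekday_wake, weekend_bed, weekend_wake


def _apply_ampm_misreports(rng, survey, rate):
    """Shift a fraction of bedtimes 12 h into the implausible morning window."""
    lo, hi = sleep_index.BEDTIME_INVALID
    for col in ("weekday_bed", "weekend_bed"):
        hit = rng.random(len(survey)) < rate
        shifted = np.mod(survey[col].to_numpy() + 12 * 60, 24 * 60)
        shifted = np.clip(shifted, lo, hi)          # stay inside the window
        shifted = np.round(shifted / 30.0) * 30.0   # keep the half-hour grid
        survey.loc[hit, col] = shifted[hit]
        survey.attrs.setdefault("n_misreported", {})[col] = int(hit.sum())
    return survey


# --------------------------------------------------------------------------
# covariates, genetics, outcomes

_EMPLOYMENT = np.array(["employed", "not_employed"])
_EDUCATION = np.array(["high_school", "college", "graduate"])
_EXERCISE = np.array(["low", "moderate", "high"])
_SMOKING = np.array(["never", "former", "current"])
_ALCOHOL = np.array(["none", "moderate", "heavy"])


def _simulate_participants(rng, n, survey_response_rate):
    ids = np.array([f"P{i:06d}" for i in range(1, n + 1)])
    age = np.clip(rng.normal(54.4, 16.3, n), 20.0, 90.0).round(1)
    sex = np.where(rng.random(n) < 0.586, "F", "M")
    enrollment = SURVEY_EPOCH - pd.to_timedelta(
        rng.integers(180, 6 * 365, n), unit="D")
    survey_offset = rng.integers(-2 * 365, 2 * 365, n)
    survey_date = SURVEY_EPOCH + pd.to_timedelta(survey_offset, unit="D")
    responded = rng.random(n) < survey_response_rate
    df = pd.DataFrame({
        "participant_id": ids,
        "age": age,
        "sex": sex,
        "array": np.where(rng.random(n) < 0.5, "GSA-A", "GSA-B"),
        "batch": np.array([f"b{k}" for k in rng.integers(1, 5, n)]),
        "pc1": rng.normal(0, 1, n).round(4),
        "pc2": rng.normal(0, 1, n).round(4),
        "pc3": rng.normal(0, 1, n).round(4),
        "pc4": rng.normal(0, 1, n).round(4),
        "employment": _EMPLOYMENT[rng.integers(0, 2, n)],
        "education": _EDUCATION[rng.integers(0, 3, n)],
        "exercise": _EXERCISE[rng.integers(0, 3, n)],
        "smoking": _SMOKING[rng.integers(0, 3, n)],
        "alcohol": _ALCOHOL[rng.integers(0, 3, n)],
        "bmi": np.clip(rng.normal(27.5, 5.0, n), 16.0, 55.0).round(1),
        "charlson": rng.poisson(1.0, n),
        "enrollment_date": enrollment.normalize(),
        "survey_date": pd.Series(survey_date).where(responded, pd.NaT).dt.normalize(),
    })
    return df


_BASES = np.array(["A", "C", "G", "T"])


def _simulate_genetics(rng, ids, n_variants, freq_range):
    n = len(ids)
    freqs = rng.uniform(freq_range[0], freq_range[1], n_variants)
    pair_idx = rng.integers(0, 4, (n_variants, 2))
    pair_idx[:, 1] = (pair_idx[:, 0] + 1 + rng.integers(0, 3, n_variants)) % 4
    effect_allele = _BASES[pair_idx[:, 0]]
    other_allele = _BASES[pair_idx[:, 1]]
    weights = pd.DataFrame({
        "variant_id": [f"rs{100000 + i}" for i in range(n_variants)],
        "effect_allele": effect_allele,
        "other_allele": other_allele,
        "weight": rng.normal(0.0, 1.0 / np.sqrt(n_variants), n_variants).round(6),
    })
    dose_eff = rng.binomial(2, freqs, size=(n, n_variants)).astype(float)
    # a third of dosage columns count the *other* allele, to exercise the
    # harmonization flip downstream
    counted_is_other = rng.random(n_variants) < (1 / 3)
    stored = np.where(counted_is_other, 2.0 - dose_eff, dose_eff)
    counted_allele = np.where(counted_is_other, other_allele, effect_allele)
    columns = [f"{vid}:{al}" for vid, al in zip(weights["variant_id"], counted_allele)]
    dosages = pd.DataFrame(stored, index=pd.Index(ids, name="participant_id"),
                           columns=columns)
    raw = dose_eff @ weights["weight"].to_numpy()
    sd = raw.std(ddof=1)
    prs_std = (raw - raw.mean()) / sd if sd > 0 else np.zeros(n)
    return weights, dosages, prs_std


def _solve_intercept(eta, prevalence, phecode_id):
    def gap(alpha):
        return float(expit(alpha + eta).mean() - prevalence)
    lo, hi = -20.0, 20.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise ValueError(
            f"outcome {phecode_id}: prevalence {prevalence} unreachable with the "
            f"planted effects (required intercept outside +/-20 on the logit scale)")
    return brentq(gap, lo, hi, xtol=1e-10)


def _draw_event_dates(rng, ref_dates, n_codes, inside_window, window_years):
    """Uniform day offsets, guaranteed inside (or outside) the calendar window."""
    total = int(n_codes.sum())
    max_in = window_years * 365 - 10          # safely inside +/-window_years
    min_out = window_years * 366 + 20         # safely outside
    offsets = np.empty(total)
    rep_inside = np.repeat(inside_window, n_codes)
    k_in = int(rep_inside.sum())
    offsets[rep_inside] = rng.integers(-max_in, max_in + 1, k_in)
    k_out = total - k_in
    sign = rng.choice([-1, 1], size=k_out)
    offsets[~rep_inside] = sign * rng.integers(min_out, min_out + 3 * 365, k_out)
    refs = np.repeat(ref_dates.to_numpy(), n_codes)
    return pd.Series(refs) + pd.to_timedelta(offsets, unit="D")


def _emit_codes(rng, pids, ref_dates, n_codes, inside, code_pool, window_years):
    """Event rows for the given participants; codes drawn uniformly from pool."""
    total = int(n_codes.sum())
    if total == 0:
        return pd.DataFrame(columns=["participant_id", "icd_version", "code", "date"])
    rows = code_pool.iloc[rng.integers(0, len(code_pool), total)]
    return pd.DataFrame({
        "participant_id": np.repeat(pids, n_codes),
        "icd_version": rows["icd_version"].to_numpy(),
        "code": rows["icd_code"].to_numpy(),
        "date": _draw_event_dates(rng, ref_dates, n_codes, inside, window_years)
        .dt.normalize().to_numpy(),
    })


def simulate_cohort(config: SimulationConfig,
                    phecode_map: pd.DataFrame | None = None,
                    classification: pd.DataFrame | None = None) -> SyntheticCohort:
    """Generate a full synthetic cohort under ``config``.

    Reproducible: the same config and seed yield identical tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    pmap = phecode_map if phecode_map is not None else maps.toy_phecode_map()
    cls = classification if classification is not None else maps.toy_sleep_classification()

    participants = _simulate_participants(rng, config.n_participants,
                                          config.survey_response_rate)
    ids = participants["participant_id"].to_numpy()
    n = len(ids)
    ref_dates = participants["survey_date"].fillna(participants["enrollment_date"])

    weights, dosages, prs_std = _simulate_genetics(
        rng, ids, config.n_variants, config.allele_freq_range)

    # --- planted index components ------------------------------------------
    age_z = (participants["age"] - participants["age"].mean()) / participants["age"].std(ddof=1)
    comp = pd.DataFrame(index=np.arange(n))
    for name, base in COMPONENT_BASE_RATES.items():
        p = base + (config.prs_index_beta / 8.0) * prs_std
        if name in sleep_index.BEHAVIOR_COMPONENTS:
            p = p + CONFOUND_AGE_PER_COMPONENT * age_z.to_numpy()
        comp[name] = (rng.random(n) < np.clip(p, 0.005, 0.995)).astype(int)
    index_true = comp.to_numpy().sum(axis=1)

    # --- survey table -------------------------------------------------------
    wd_bed, wd_wake, we_bed, we_wake = _realize_survey_times(rng, comp)
    survey = pd.DataFrame({
        "participant_id": ids,
        "weekday_bed": wd_bed,
        "weekday_wake": wd_wake,
        "weekend_bed": we_bed,
        "weekend_wake": we_wake,
        "completion_date": ref_dates.to_numpy(),
    })
    responded = participants["survey_date"].notna().to_numpy()
    survey = survey[responded].reset_index(drop=True)
    survey = _apply_ampm_misreports(rng, survey, config.ampm_misreport_rate)

    # --- EHR events ---------------------------------------------------------
    events = []
    alphas = {}
    outcome_status = {}
    for spec in config.outcome_specs:
        eta = (np.log(spec.or_per_sd_prs) * prs_std
               + np.log(spec.or_per_index_unit) * index_true
               + spec.interaction_log_or * prs_std * index_true
               + OUTCOME_COVARIATE_EFFECTS["age"]
               * (participants["age"] - participants["age"].mean()).to_numpy()
               + OUTCOME_COVARIATE_EFFECTS["sex_male"]
               * (participants["sex"] == "M").to_numpy()
               + OUTCOME_COVARIATE_EFFECTS["bmi"]
               * (participants["bmi"] - participants["bmi"].mean()).to_numpy()
               + OUTCOME_COVARIATE_EFFECTS["charlson"]
               * participants["charlson"].to_numpy())
        alpha = _solve_intercept(eta, spec.prevalence, spec.phecode_id)
        alphas[spec.phecode_id] = float(alpha)
        y = rng.random(n) < expit(alpha + eta)
        outcome_status[spec.phecode_id] = y.astype(int)

        pool = pmap[pmap["phecode_id"] == spec.phecode_id]
        if pool.empty:
            raise ValueError(f"outcome phecode {spec.phecode_id} absent from the map")
        case_ids = ids[y]
        case_refs = ref_dates[y]
        n_codes = 2 + rng.poisson(0.7, len(case_ids))
        u = rng.random(len(case_ids))
        one_code = u < config.one_code_rate
        violate = (u >= config.one_code_rate) & (
            u < config.one_code_rate + config.window_violation_rate)
        n_codes[one_code] = 1
        events.append(_emit_codes(rng, case_ids, case_refs, n_codes,
                                  ~violate, pool, config.window_years))

    # sleep-disorder diagnoses for unfavorable EHR components (2 codes on
    # 2 distinct days inside the window)
    cls_icd = cls[cls["code_type"].isin(["icd9", "icd10"])].copy()
    cls_icd["icd_version"] = cls_icd["code_type"].map({"icd9": 9, "icd10": 10})
    cls_icd = cls_icd.rename(columns={"code": "icd_code"})
    for comp_name, category in (("no_insomnia_disorder", "insomnia_disorder"),
                                ("no_breathing_disorder", "breathing_disorder"),
                                ("no_other_sleep_disorder", "other_sleep_disorder")):
        affected = comp[comp_name].to_numpy() == 0
        pool = cls_icd[cls_icd["category"] == category]
        aff_ids, aff_refs = ids[affected], ref_dates[affected]
        k = len(aff_ids)
        if k == 0:
            continue
        day1 = rng.integers(-1700, 0, k)
        day2 = day1 + rng.integers(30, 120, k)
        for days in (day1, day2):
            rows = pool.iloc[rng.integers(0, len(pool), k)]
            events.append(pd.DataFrame({
                "participant_id": aff_ids,
                "icd_version": rows["icd_version"].to_numpy(),
                "code": rows["icd_code"].to_numpy(),
                "date": (pd.Series(aff_refs.to_numpy())
                         + pd.to_timedelta(days, unit="D")).dt.normalize().to_numpy(),
            }))

    # medication events for unfavorable no_sleep_medication
    med_pool = cls.loc[(cls["code_type"] == "med"), "code"].to_numpy()
    med_users = comp["no_sleep_medication"].to_numpy() == 0
    mk = int(med_users.sum())
    med_events = pd.DataFrame({
        "participant_id": ids[med_users],
        "code": med_pool[rng.integers(0, len(med_pool), mk)],
        "date": (pd.Series(ref_dates[med_users].to_numpy())
                 + pd.to_timedelta(rng.integers(-1700, 1700, mk), unit="D"))
        .dt.normalize().to_numpy(),
    })

    # background codes from phecodes not planted and not sleep-classified
    outcome_codes = set(
        pmap.loc[pmap["phecode_id"].isin([s.phecode_id for s in config.outcome_specs]),
                 "icd_code"])
    class_codes = set(cls_icd["icd_code"])
    bg_pool = pmap[~pmap["icd_code"].isin(outcome_codes | class_codes)]
    bg_pool = bg_pool.drop_duplicates(["icd_version", "icd_code"])
    n_bg = rng.poisson(config.background_code_rate, n)
    if len(bg_pool) and n_bg.sum():
        bg = _emit_codes(rng, ids, ref_dates, n_bg,
                         np.ones(n, dtype=bool), bg_pool, config.window_years + 1)
        # duplicate a slice of background rows same-day to exercise dedup
        dup = bg.iloc[rng.random(len(bg)) < 0.05]
        events.extend([bg, dup])

    # junk (non-ICD) and unmapped codes
    for rate, version, code in ((config.junk_code_rate, 0, "JUNK-01"),
                                (config.unmapped_code_rate, 10, "R99")):
        hit = rng.random(n) < rate
        k = int(hit.sum())
        if k:
            events.append(pd.DataFrame({
                "participant_id": ids[hit],
                "icd_version": version,
                "code": code,
                "date": (pd.Series(ref_dates[hit].to_numpy())
                         + pd.to_timedelta(rng.integers(-1000, 1000, k), unit="D"))
                .dt.normalize().to_numpy(),
            }))

    if events:
        icd_events = (pd.concat(events, ignore_index=True)
                      .sort_values(["participant_id", "date", "code"], kind="stable")
                      .reset_index(drop=True))
    else:
        icd_events = pd.DataFrame({"participant_id": pd.Series(dtype=str),
                                   "icd_version": pd.Series(dtype=int),
                                   "code": pd.Series(dtype=str),
                                   "date": pd.Series(dtype="datetime64[ns]")})

    # --- kinship pairs ------------------------------------------------------
    n_rel = int(config.related_pair_fraction * n / 2)
    perm = rng.permutation(n)
    rel_a, rel_b = perm[:n_rel], perm[n_rel:2 * n_rel]
    unrel_a, unrel_b = perm[2 * n_rel:3 * n_rel], perm[3 * n_rel:4 * n_rel]
    kinship = pd.DataFrame({
        "id_a": np.concatenate([ids[rel_a], ids[unrel_a]]),
        "id_b": np.concatenate([ids[rel_b], ids[unrel_b]]),
        "coefficient": np.concatenate([np.full(len(rel_a), 0.25),
                                       np.full(len(unrel_a), 0.05)]),
    })

    truth = {
        "config": config.to_dict(),
        "component_base_rates": dict(COMPONENT_BASE_RATES),
        "outcome_covariate_effects": dict(OUTCOME_COVARIATE_EFFECTS),
        "confound_age_per_component": CONFOUND_AGE_PER_COMPONENT,
        "intercepts": alphas,
        "realized": {
            "mean_index": float(index_true.mean()),
            "prevalence": {k: float(v.mean()) for k, v in outcome_status.items()},
            "n_misreported_bedtimes": survey.attrs.get("n_misreported", {}),
        },
    }
    return SyntheticCohort(participants=participants, survey=survey,
                           dosages=dosages, weights=weights,
                           icd_events=icd_events, med_events=med_events,
                           kinship_pairs=kinship, truth=truth)
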