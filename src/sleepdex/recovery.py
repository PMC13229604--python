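"""Parameter-recovery experiments on the synthetic cohort.

Each experiment replays the full pipeline — simulate, phenotype, score,
prune, standardize, fit — on freshly generated cohorts with a known planted
effect and measures how the estimates behave across replicates: CI coverage
of the planted odds ratio, type-I error of the null interaction test, and
the family-wise false-positive count of an all-null Bonferroni scan.

The recovery configurations isolate estimation: the engineered data-defect
knobs (AM/PM misreports, one-code exclusions, window violations, junk and
unmapped codes, background noise) are held at zero here because each of
those has its own dedicated audit, and the quantity under study is the
sampling behavior of the estimators.  Replicate seeds are drawn from a
``numpy`` ``SeedSequence`` spawned from the experiment seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import association, genetics, maps, phenotypes, pipeline
from .simulate import OutcomeSpec, SimulationConfig, simulate_cohort

RECOVERY_N = 20_000
RECOVERY_VARIANTS = 30


def clean_config(seed: int, n: int = RECOVERY_N, outcome_specs=None,
                 **overrides) -> SimulationConfig:
    """A generator config with every engineered defect disabled."""
    cfg = SimulationConfig(
        n_participants=n, n_variants=RECOVERY_VARIANTS, seed=int(seed),
        ampm_misreport_rate=0.0, one_code_rate=0.0, window_violation_rate=0.0,
        background_code_rate=0.0, junk_code_rate=0.0, unmapped_code_rate=0.0,
        **overrides)
    if outcome_specs is not None:
        cfg.outcome_specs = outcome_specs
    return cfg


def _replicate_seeds(seed: int, n_reps: int):
    ss = np.random.SeedSequence(int(seed))
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n_reps)]


def _pipeline_frame(cohort, min_cases=100):
    """Phenotype calls + standardized PRS + covariates for one cohort."""
    refs = pipeline.reference_dates(cohort.participants)
    events = phenotypes.deduplicate_events(cohort.icd_events)
    calls, retained = phenotypes.call_phecodes(events, maps.toy_phecode_map(),
                                               refs, min_cases)
    raw = genetics.harmonize_and_score(cohort.weights, cohort.dosages)
    kept, _ = genetics.prune_related(cohort.kinship_pairs,
                                     all_ids=raw["participant_id"])
    prs = genetics.standardize(raw, sample_ids=kept)
    base = cohort.participants.set_index("participant_id")
    prs_std = prs.set_index("participant_id")["standardized"].rename("prs_std")
    return calls, retained, base, prs_std


def _recovered_index(cohort, classification=None):
    cls = classification if classification is not None else maps.toy_sleep_classification()
    refs = pipeline.reference_dates(cohort.participants)
    events = phenotypes.deduplicate_events(cohort.icd_events)
    flags = phenotypes.derive_sleep_flags(events, cohort.med_events, cls, refs)
    from . import sleep_index
    _, index_table = sleep_index.build_sleep_index(cohort.survey, flags)
    return index_table.set_index("participant_id")["index"].rename("index")


def prs_or_coverage(n_reps: int = 300, seed: int = 101, n: int = RECOVERY_N,
                    prevalence: float = 0.2, or_per_sd: float = 0.85) -> dict:
    """CI coverage of a planted per-SD polygenic OR through the PheWAS path."""
    phecode = "296.2"
    covered, estimates = [], []
    for rep_seed in _replicate_seeds(seed, n_reps):
        cfg = clean_config(rep_seed, n, [OutcomeSpec(phecode, prevalence, or_per_sd)])
        cohort = simulate_cohort(cfg)
        calls, _, base, prs_std = _pipeline_frame(cohort)
        scan = association.run_phewas(prs_std, calls, [phecode], base,
                                      association.PRIMARY_PRS_COVARIATES)
        r = scan.results.iloc[0]
        covered.append(bool(r["ci_low"] <= or_per_sd <= r["ci_high"]))
        estimates.append(float(r["estimate"]))
    return {"coverage": float(np.mean(covered)), "n_reps": n_reps,
            "mean_or": float(np.mean(estimates)), "truth": or_per_sd, "n": n}


def index_or_coverage(n_reps: int = 300, seed: int = 202, n: int = RECOVERY_N,
                      prevalence: float = 0.2, or_per_unit: float = 0.85) -> dict:
    """CI coverage of a planted per-index-unit OR through the index scan path."""
    phecode = "296.2"
    covered, estimates = [], []
    for rep_seed in _replicate_seeds(seed, n_reps):
        cfg = clean_config(rep_seed, n,
                           [OutcomeSpec(phecode, prevalence, 1.0, or_per_unit)])
        cohort = simulate_cohort(cfg)
        calls, _, base, _ = _pipeline_frame(cohort)
        index_s = _recovered_index(cohort)
        scan = association.run_phewas(index_s, calls, [phecode], base,
                                      association.INDEX_SCAN_COVARIATES,
                                      label="index")
        r = scan.results.iloc[0]
        covered.append(bool(r["ci_low"] <= or_per_unit <= r["ci_high"]))
        estimates.append(float(r["estimate"]))
    return {"coverage": float(np.mean(covered)), "n_reps": n_reps,
            "mean_or": float(np.mean(estimates)), "truth": or_per_unit, "n": n}


def interaction_type1(n_reps: int = 600, seed: int = 303, n: int = 4000,
                      alpha: float = 0.05) -> dict:
    """Type-I error of the PRS x index interaction test when none is planted.

    Main effects stay on (per-SD OR 0.90, per-unit OR 0.85) so the null
    applies to the product term only, the realistic setting for the test.
    """
    phecode = "296.2"
    rejections, ps = [], []
    for rep_seed in _replicate_seeds(seed, n_reps):
        cfg = clean_config(rep_seed, n,
                           [OutcomeSpec(phecode, 0.2, 0.90, 0.85, 0.0)])
        cohort = simulate_cohort(cfg)
        calls, _, base, prs_std = _pipeline_frame(cohort, min_cases=50)
        index_s = _recovered_index(cohort)
        df = base.copy()
        df["prs_std"] = prs_std.reindex(df.index)
        df["index"] = index_s.reindex(df.index)
        df["_y"] = association._case_control_frame(calls, phecode).reindex(df.index)
        res = association.test_interaction(df, "_y",
                                           association.PRIMARY_PRS_COVARIATES)
        if res.converged:
            ps.append(res.p)
            rejections.append(res.p < alpha)
    return {"type1_error": float(np.mean(rejections)), "n_reps": len(rejections),
            "alpha": alpha, "mean_p": float(np.mean(ps))}


def interaction_recovery(seed: int = 99, n: int = RECOVERY_N,
                         interaction_or: float = 1.3) -> dict:
    """One-shot check that a planted interaction OR is inside its Wald CI."""
    phecode = "296.2"
    cfg = clean_config(seed, n, [OutcomeSpec(phecode, 0.2, 0.90, 0.85,
                                             float(np.log(interaction_or)))])
    cohort = simulate_cohort(cfg)
    calls, _, base, prs_std = _pipeline_frame(cohort)
    df = base.copy()
    df["prs_std"] = prs_std.reindex(df.index)
    df["index"] = _recovered_index(cohort).reindex(df.index)
    df["_y"] = association._case_control_frame(calls, phecode).reindex(df.index)
    res = association.test_interaction(df, "_y", association.PRIMARY_PRS_COVARIATES)
    return {"estimate": res.estimate, "ci_low": res.ci_low,
            "ci_high": res.ci_high, "truth": interaction_or,
            "covered": bool(res.ci_low <= interaction_or <= res.ci_high)}


def prs_index_beta_recovery(seed: int = 55, n: int = 15_000,
                            beta: float = 0.05) -> dict:
    """Recover the planted per-SD PRS effect on the 0-8 index (linear model)."""
    cfg = clean_config(seed, n, prs_index_beta=beta)
    cohort = simulate_cohort(cfg)
    _, _, base, prs_std = _pipeline_frame(cohort)
    df = base.reset_index()
    df["prs_std"] = prs_std.reindex(base.index).to_numpy()
    df["index"] = _recovered_index(cohort).reindex(base.index).to_numpy()
    res = association.index_prs_association(
        df, covariates=association.FULL_PRS_COVARIATES, label="fully_adjusted")[0]
    return {"estimate": res.estimate, "ci_low": res.ci_low,
            "ci_high": res.ci_high, "truth": beta,
            "covered": bool(res.ci_low <= beta <= res.ci_high)}


def _null_scan_map(n_outcomes: int) -> pd.DataFrame:
    rows = []
    for i in range(n_outcomes):
        pid = f"N{i:03d}"
        rows.append((10, f"X{i:03d}.0", pid, f"Null outcome {i}", "synthetic"))
        rows.append((9, f"x{i:03d}.9", pid, f"Null outcome {i}", "synthetic"))
    return pd.DataFrame(rows, columns=["icd_version", "icd_code", "phecode_id",
                                       "phecode_label", "disease_group"])


def null_scan_false_positives(n_reps: int = 100, seed: int = 404,
                              n_outcomes: int = 100, n: int = 500,
                              prevalence: float = 0.3, alpha: float = 0.05) -> dict:
    """Mean Bonferroni-significant count per replicate in an all-null scan.

    With ``n_outcomes`` independent null outcomes, the family-wise expected
    count of p < alpha/n_outcomes hits is about alpha per replicate.
    """
    pmap = _null_scan_map(n_outcomes)
    specs = [OutcomeSpec(f"N{i:03d}", prevalence) for i in range(n_outcomes)]
    counts = []
    for rep_seed in _replicate_seeds(seed, n_reps):
        cfg = clean_config(rep_seed, n, specs)
        cohort = simulate_cohort(cfg, phecode_map=pmap)
        refs = pipeline.reference_dates(cohort.participants)
        events = phenotypes.deduplicate_events(cohort.icd_events)
        calls, retained = phenotypes.call_phecodes(events, pmap, refs, 100)
        raw = genetics.harmonize_and_score(cohort.weights, cohort.dosages)
        kept, _ = genetics.prune_related(cohort.kinship_pairs,
                                         all_ids=raw["participant_id"])
        prs = genetics.standardize(raw, sample_ids=kept)
        base = cohort.participants.set_index("participant_id")
        prs_std = prs.set_index("participant_id")["standardized"].rename("prs_std")
        scan = association.run_phewas(prs_std, calls, retained, base,
                                      ["age", "sex"], alpha=alpha)
        counts.append(scan.n_significant)
    return {"mean_significant": float(np.mean(counts)), "n_reps": n_reps,
            "n_outcomes": n_outcomes, "max_significant": int(np.max(counts))}
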