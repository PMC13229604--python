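"""End-to-end orchestration: simulate/load -> phenotype -> score -> scan -> report.

``run_pipeline`` sequences the stages on a cohort (synthetic or read from
disk), writes every stage's table under the output directory, and returns a
:class:`RunReport` with cohort descriptives (trait means +/- SD and ranges,
component prevalences, the 0-8 index histogram), the two phenome-wide scan
summaries, the PRS->index validation estimates, and the exploratory
interaction table.  Every number in the report is recomputable from the
emitted files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, genetics, io, maps, phenotypes, simulate, sleep_index

logger = logging.getLogger(__name__)

INDEX_RANGE = 8


def percent(numerator: float, denominator: float, decimals: int | None = None) -> float:
    """Sample fraction as a percentage, optionally rounded to printed precision."""
    if denominator == 0:
        raise ZeroDivisionError("percent() with zero denominator")
    value = 100.0 * numerator / denominator
    return round(value, decimals) if decimals is not None else value


def index_units_to_percent(beta: float, index_range: int = INDEX_RANGE) -> float:
    """Convert an index-unit effect to percent of the 0-8 index range."""
    return 100.0 * beta / index_range


@dataclass
class PipelineConfig:
    """All knobs of a run; defaults are the analysis' standard constants."""
    out_dir: str = "sleepdex_run"
    input_dir: str | None = None          # read a written cohort; None -> simulate
    window_years: int = 5
    min_cases: int = 100
    kinship_threshold: float = 0.0625
    alpha: float = 0.05
    model: str = "primary"                # covariate set for the PRS PheWAS
    seed: int = 0
    simulation: simulate.SimulationConfig | None = None
    interaction_outcomes: list | None = None   # fixed list overrides top-5 selection
    n_interaction_outcomes: int = 5

    @classmethod
    def from_yaml(cls, path):
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            outcomes = [simulate.OutcomeSpec(**o) for o in sim.pop("outcome_specs", [])]
            sim_cfg = simulate.SimulationConfig(**sim)
            if outcomes:
                sim_cfg.outcome_specs = outcomes
            cfg.simulation = sim_cfg
        return cfg


@dataclass
class RunReport:
    n_participants: int
    n_complete_index: int
    trait_summary: dict
    component_prevalence: dict
    flag_prevalence: dict
    index_histogram: dict
    pct_all_eight: float
    prs_index: list
    scans: dict
    interactions: list
    config: dict

    def to_json(self, path=None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, default=str)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_text(self) -> str:
        lines = [f"cohort n = {self.n_participants} "
                 f"(complete index: {self.n_complete_index})"]
        for trait, s in self.trait_summary.items():
            lines.append(f"  {trait}: {s['mean']:.2f} +/- {s['sd']:.2f} "
                         f"(range {s['min']:.2f}-{s['max']:.2f})")
        lines.append(f"  all eight favorable: {self.pct_all_eight:.2f}%")
        hist = " ".join(f"{k}:{v}" for k, v in self.index_histogram.items())
        lines.append(f"  index histogram: {hist}")
        for name, s in self.scans.items():
            lines.append(f"scan [{name}]: {s['n_tests']} tests, "
                         f"alpha_corrected = {s['alpha_corrected']:.3g}, "
                         f"{s['n_significant']} significant")
        for r in self.prs_index:
            lines.append(f"PRS->index [{r['model']}] {r['outcome']}: "
                         f"{r['estimate']:.4g} ({r['ci_low']:.4g}, {r['ci_high']:.4g})")
        for r in self.interactions:
            lines.append(f"interaction [{r['model']}] {r['outcome']}: "
                         f"OR {r['estimate']:.3f} ({r['ci_low']:.3f}, "
                         f"{r['ci_high']:.3f}), p = {r['p']:.3f}")
        return "\n".join(lines)


def reference_dates(participants: pd.DataFrame) -> pd.Series:
    """Survey completion date, falling back to the enrollment date."""
    refs = participants.set_index("participant_id")["survey_date"]
    if "enrollment_date" in participants.columns:
        refs = refs.fillna(participants.set_index("participant_id")["enrollment_date"])
    return refs


def describe_cohort(traits: pd.DataFrame, index_table: pd.DataFrame,
                    flags: pd.DataFrame) -> dict:
    """Cohort descriptives: trait moments, prevalences, index histogram."""
    trait_cols = {"tib_weighted": 1.0, "tib_irregularity": 1.0,
                  "midpoint_weekend": 1 / 60.0, "social_jetlag": 1.0}
    summary = {}
    for col, scale in trait_cols.items():
        v = traits[col].to_numpy(dtype=float) * scale
        v = v[~np.isnan(v)]
        summary[col] = {"mean": float(v.mean()) if len(v) else np.nan,
                        "sd": float(v.std(ddof=1)) if len(v) > 1 else np.nan,
                        "min": float(v.min()) if len(v) else np.nan,
                        "max": float(v.max()) if len(v) else np.nan,
                        "n": int(len(v))}
    comp_prev = {}
    for col in sleep_index.COMPONENTS:
        v = index_table[col].to_numpy(dtype=float)
        comp_prev[col] = float(np.nanmean(v)) if np.isfinite(v).any() else np.nan
    flag_prev = {}
    for col in phenotypes.FLAG_CATEGORIES:
        flag_prev[col] = float((flags[col] == "present").mean())
    flag_prev["sleep_medication"] = float(flags["sleep_medication"].mean())

    idx = index_table["index"].to_numpy(dtype=float)
    complete = idx[~np.isnan(idx)]
    histogram = {int(k): int((complete == k).sum()) for k in range(INDEX_RANGE + 1)}
    pct_all8 = percent((complete == INDEX_RANGE).sum(), len(complete)) if len(complete) else np.nan
    return {"trait_summary": summary, "component_prevalence": comp_prev,
            "flag_prevalence": flag_prev, "index_histogram": histogram,
            "pct_all_eight": pct_all8, "n_complete_index": int(len(complete))}


def _select_interaction_outcomes(prs_scan, index_scan, groups, k):
    """Smallest-p mental-disorder phecodes significant in *both* scans."""
    mental = set(groups.loc[groups["disease_group"] == maps.MENTAL, "phecode_id"])
    sig_prs = prs_scan.results[prs_scan.results["significant"]]
    sig_idx = index_scan.results[index_scan.results["significant"]]
    both = set(sig_prs["outcome"]) & set(sig_idx["outcome"]) & mental
    ranked = sig_idx[sig_idx["outcome"].isin(both)].sort_values("p")
    return ranked["outcome"].head(k).tolist()


def run_pipeline(config: PipelineConfig,
                 phecode_map: pd.DataFrame | None = None,
                 classification: pd.DataFrame | None = None) -> RunReport:
    """Run every stage and write all artifacts under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pmap = phecode_map if phecode_map is not None else maps.toy_phecode_map()
    cls = classification if classification is not None else maps.toy_sleep_classification()
    groups = maps.phecode_groups(pmap)

    stage = "input"
    try:
        if config.input_dir is not None:
            cohort = io.read_cohort(config.input_dir)
        else:
            sim = config.simulation or simulate.SimulationConfig(seed=config.seed)
            cohort = simulate.simulate_cohort(sim, pmap, cls)
            io.write_cohort(cohort, out / "cohort")
        refs = reference_dates(cohort.participants)

        stage = "phenotypes"
        events = phenotypes.deduplicate_events(cohort.icd_events)
        flags = phenotypes.derive_sleep_flags(events, cohort.med_events, cls,
                                              refs, config.window_years)
        calls, retained = phenotypes.call_phecodes(events, pmap, refs,
                                                   config.min_cases,
                                                   config.window_years)
        io.write_tsv(flags, out / "sleep_flags.tsv")
        io.write_tsv(calls, out / "phenotype_calls.tsv")

        stage = "sleep_index"
        survey = cohort.survey.rename(columns={"completion_date": "completion_date"})
        traits, index_table = sleep_index.build_sleep_index(survey, flags)
        io.write_tsv(traits, out / "sleep_traits.tsv")
        io.write_components(index_table, out / "sleep_index.tsv")

        stage = "genetics"
        raw = genetics.harmonize_and_score(cohort.weights, cohort.dosages)
        kept, removed = genetics.prune_related(
            cohort.kinship_pairs, config.kinship_threshold,
            all_ids=raw["participant_id"])
        prs = genetics.standardize(raw, sample_ids=kept)
        io.write_tsv(prs, out / "prs.tsv")
        io.write_tsv(pd.DataFrame({"participant_id": removed,
                                   "reason": "kinship"}), out / "prune_report.tsv")

        stage = "association"
        base = cohort.participants.set_index("participant_id")
        prs_std = prs.set_index("participant_id")["standardized"].rename("prs_std")
        index_s = index_table.set_index("participant_id")["index"]
        frame = base.copy()
        frame["prs_std"] = prs_std.reindex(frame.index)
        frame["index"] = index_s.reindex(frame.index)
        for comp in sleep_index.COMPONENTS:
            frame[comp] = index_table.set_index("participant_id")[comp].reindex(frame.index)

        prs_index_results = []
        for label, covs in (("primary", association.PRIMARY_PRS_COVARIATES),
                            ("fully_adjusted", association.FULL_PRS_COVARIATES)):
            prs_index_results += association.index_prs_association(
                frame.reset_index(), component_cols=sleep_index.COMPONENTS,
                label=label, covariates=covs)
        io.write_tsv(pd.DataFrame([r.to_dict() for r in prs_index_results]),
                     out / "association_results.tsv")

        scan_covs = {"primary": association.PRIMARY_PRS_COVARIATES,
                     "fully_adjusted": association.FULL_PRS_COVARIATES}[config.model]
        prs_scan = association.run_phewas(
            prs_std, calls, retained, base, scan_covs,
            phecode_groups=groups, alpha=config.alpha, label=config.model)
        index_scan = association.run_phewas(
            index_s.rename("index"), calls, retained, base,
            association.INDEX_SCAN_COVARIATES, phecode_groups=groups,
            alpha=config.alpha, label="index")
        io.write_tsv(prs_scan.results, out / "phewas_prs.tsv")
        io.write_tsv(index_scan.results, out / "phewas_index.tsv")
        io.write_tsv(prs_scan.manhattan, out / "manhattan_prs.tsv")
        io.write_tsv(index_scan.manhattan, out / "manhattan_index.tsv")
        miami = pd.concat([prs_scan.manhattan.assign(panel="prs"),
                           index_scan.manhattan.assign(panel="index")],
                          ignore_index=True)
        io.write_tsv(miami, out / "miami_table.tsv")

        targets = config.interaction_outcomes or _select_interaction_outcomes(
            prs_scan, index_scan, groups, config.n_interaction_outcomes)
        interactions = []
        for phecode in targets:
            y = association._case_control_frame(calls, phecode)
            df = frame.copy()
            df["_y"] = y.reindex(df.index)
            for label, covs in (("primary", association.PRIMARY_PRS_COVARIATES),
                                ("fully_adjusted", association.FULL_PRS_COVARIATES)):
                res = association.test_interaction(df, "_y", covs, label=label)
                res.outcome = str(phecode)
                interactions.append(res)
        io.write_tsv(pd.DataFrame([r.to_dict() for r in interactions]),
                     out / "interaction_results.tsv")
    except Exception:
        logger.error("pipeline failed during stage %r (partial outputs kept in %s)",
                     stage, out)
        raise

    desc = describe_cohort(traits, index_table, flags)
    report = RunReport(
        n_participants=len(cohort.participants),
        n_complete_index=desc["n_complete_index"],
        trait_summary=desc["trait_summary"],
        component_prevalence=desc["component_prevalence"],
        flag_prevalence=desc["flag_prevalence"],
        index_histogram=desc["index_histogram"],
        pct_all_eight=desc["pct_all_eight"],
        prs_index=[r.to_dict() for r in prs_index_results],
        scans={
            "prs": {"n_tests": prs_scan.n_tests,
                    "alpha_corrected": prs_scan.alpha_corrected,
                    "n_significant": prs_scan.n_significant},
            "index": {"n_tests": index_scan.n_tests,
                      "alpha_corrected": index_scan.alpha_corrected,
                      "n_significant": index_scan.n_significant},
        },
        interactions=[r.to_dict() for r in interactions],
        config={**dataclasses.asdict(config),
                "simulation": (config.simulation.to_dict()
                               if config.simulation else None)},
    )
    report.to_json(out / "report.json")
    (out / "report.txt").write_text(report.to_text() + "\n")
    return report
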