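"""Regression models for the sleep-health scans.

Three families of analysis share one fitting core:

* index <-> PRS validation: a linear model of the 0-8 lifestyle index on the
  standardized polygenic score (beta per SD), plus one logistic model per
  favorable-component indicator;
* phenome-wide scans: one logistic regression per retained phecode, exposure
  either the polygenic score or the lifestyle index, with Bonferroni
  significance at alpha / n_tests;
* exploratory gene-lifestyle interaction: logistic models with PRS, index,
  and their product, reported as the interaction odds ratio.

Two covariate sets mirror common biobank practice: the *primary* model for
genetic exposures adjusts for age, sex, genotyping array, batch and ancestry
principal components; the *fully adjusted* model adds employment, education,
exercise, smoking, alcohol, BMI and a comorbidity index.  Index-exposure
scans use the lifestyle covariate set (no genotyping technical covariates).

Inference is Wald throughout: CI = estimate +/- 1.96 * SE (exponentiated for
logistic models) and two-sided normal p-values, matching standard PheWAS
reporting.  Fits that do not converge, show separation (|coefficient| > 15
on the logit scale) or have too few cases are flagged ``converged=False``
with NaN statistics but still count toward the number of tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

PC_COLUMNS = ["pc1", "pc2", "pc3", "pc4"]
PRIMARY_PRS_COVARIATES = ["age", "sex", "array", "batch", *PC_COLUMNS]
LIFESTYLE_COVARIATES = ["employment", "education", "exercise", "smoking",
                        "alcohol", "bmi", "charlson"]
FULL_PRS_COVARIATES = PRIMARY_PRS_COVARIATES + LIFESTYLE_COVARIATES
INDEX_SCAN_COVARIATES = ["age", "sex", *LIFESTYLE_COVARIATES]

WALD_Z = 1.96
SEPARATION_COEF = 15.0
MAX_ITER = 100
LOGLIKE_TOL = 1e-8


@dataclass
class ModelSpec:
    """One regression to run: exposure, outcome, covariates, family, label."""
    exposure: str
    outcome: str
    covariates: list
    family: str = "logistic"            # or "linear"
    label: str = "primary"              # or "fully_adjusted"


@dataclass
class AssociationResult:
    outcome: str
    exposure: str
    estimate: float                      # beta (linear) or OR (logistic)
    ci_low: float
    ci_high: float
    p: float
    n: int
    n_cases: int
    model: str
    converged: bool
    significant: bool = False

    def to_dict(self):
        return dict(outcome=self.outcome, exposure=self.exposure,
                    estimate=self.estimate, ci_low=self.ci_low,
                    ci_high=self.ci_high, p=self.p, n=self.n,
                    n_cases=self.n_cases, model=self.model,
                    significant=self.significant, converged=self.converged)


@dataclass
class ScanSummary:
    """A full phenome-wide scan: per-phecode results plus the Bonferroni bookkeeping."""
    exposure: str
    n_tests: int
    alpha_corrected: float
    n_significant: int
    results: pd.DataFrame                # sorted by p, NaN last
    manhattan: pd.DataFrame = field(default=None, repr=False)


def build_design(data: pd.DataFrame, columns) -> pd.DataFrame:
    """Design matrix with intercept; categorical columns dummy-coded.

    Object/categorical columns are expanded with the lexicographically first
    level as reference (deterministic level ordering); numeric columns pass
    through.  Booleans are treated as numeric 0/1.
    """
    pieces = [pd.Series(1.0, index=data.index, name="const")]
    for col in columns:
        s = data[col]
        if s.dtype == bool or pd.api.types.is_numeric_dtype(s):
            pieces.append(s.astype(float))
        else:
            cat = pd.Categorical(s, categories=sorted(pd.unique(s.dropna())))
            dummies = pd.get_dummies(cat, prefix=col, drop_first=True, dtype=float)
            dummies.index = data.index
            pieces.append(dummies)
    return pd.concat(pieces, axis=1)


def _wald(est, se, exponentiate):
    lo, hi = est - WALD_Z * se, est + WALD_Z * se
    p = 2.0 * stats.norm.sf(abs(est) / se) if se > 0 else np.nan
    p = min(float(p), 1.0) if np.isfinite(p) else np.nan
    if exponentiate:
        return float(np.exp(est)), float(np.exp(lo)), float(np.exp(hi)), p
    return float(est), float(lo), float(hi), p


def _failed(spec, n, n_cases):
    return AssociationResult(outcome=spec.outcome, exposure=spec.exposure,
                             estimate=np.nan, ci_low=np.nan, ci_high=np.nan,
                             p=np.nan, n=n, n_cases=n_cases, model=spec.label,
                             converged=False)


def fit_model(spec: ModelSpec, data: pd.DataFrame,
              term: str | None = None) -> AssociationResult:
    """Fit one model and report the Wald summary for the term of interest.

    ``data`` must contain ``spec.outcome``, ``spec.exposure`` and the
    covariates; rows with any missing value among them are dropped
    (complete case).  For logistic models the outcome must already be coded
    0/1 (excluded participants dropped upstream).  ``term`` selects which
    design column to report (defaults to the exposure; used for interaction
    products).
    """
    cols = [spec.outcome, spec.exposure] + [c for c in spec.covariates
                                            if c != spec.exposure]
    if term is not None and term not in cols:
        cols.append(term)
    rows = data[cols].dropna()
    y = rows[spec.outcome].astype(float)
    n = len(rows)
    n_cases = int(y.sum()) if spec.family == "logistic" else 0
    report = term or spec.exposure

    exog_cols = [c for c in cols if c != spec.outcome]
    X = build_design(rows, exog_cols)
    if spec.family == "logistic" and min(n_cases, n - n_cases) < X.shape[1]:
        return _failed(spec, n, n_cases)
    if X.shape[1] >= n or report not in X.columns:
        return _failed(spec, n, n_cases)

    try:
        if spec.family == "logistic":
            fit = sm.Logit(y, X).fit(disp=0, maxiter=MAX_ITER, method="newton",
                                     tol=LOGLIKE_TOL, warn_convergence=False)
        else:
            fit = sm.OLS(y, X).fit()
    except (np.linalg.LinAlgError, PerfectSeparationError, ValueError):
        return _failed(spec, n, n_cases)

    est = float(fit.params[report])
    se = float(fit.bse[report])
    converged = bool(getattr(fit, "mle_retvals", {"converged": True}).get("converged", True))
    if spec.family == "logistic" and np.abs(fit.params.to_numpy()).max() > SEPARATION_COEF:
        converged = False
    if not np.isfinite(est) or not np.isfinite(se) or se == 0 or not converged:
        return _failed(spec, n, n_cases)

    estimate, lo, hi, p = _wald(est, se, exponentiate=spec.family == "logistic")
    return AssociationResult(outcome=spec.outcome, exposure=spec.exposure,
                             estimate=estimate, ci_low=lo, ci_high=hi, p=p,
                             n=n, n_cases=n_cases, model=spec.label,
                             converged=True)


def _case_control_frame(calls: pd.DataFrame, phecode: str) -> pd.Series:
    """0/1 outcome per participant for one phecode; excluded -> NaN."""
    sub = calls[calls["phecode_id"] == phecode]
    y = pd.Series(np.nan, index=sub["participant_id"].to_numpy(), name="y")
    y[sub.loc[sub["status"] == "case", "participant_id"].to_numpy()] = 1.0
    y[sub.loc[sub["status"] == "control", "participant_id"].to_numpy()] = 0.0
    return y


def run_phewas(exposure: pd.Series, calls: pd.DataFrame, retained,
               covariate_data: pd.DataFrame, covariates,
               phecode_groups: pd.DataFrame | None = None,
               alpha: float = 0.05, label: str = "primary") -> ScanSummary:
    """One logistic regression per retained phecode against a single exposure.

    Parameters
    ----------
    exposure : Series indexed by participant_id (standardized PRS or index);
        its ``.name`` labels the exposure in the output.
    calls : phenotype-call table from :func:`sleepdex.phenotypes.call_phecodes`.
    retained : phecodes to test (the >= min_cases list).  ``n_tests`` is the
        length of this list; non-converged fits still count toward it, so the
        Bonferroni threshold is alpha / n_tests regardless of fit failures.
    covariate_data : participant-indexed covariate table.
    phecode_groups : optional (phecode_id, phecode_label, disease_group)
        lookup used to annotate the plot-ready table.
    """
    retained = list(retained)
    if not retained:
        raise ValueError("empty retained phecode list: nothing to scan")
    exposure_name = exposure.name or "exposure"

    results = []
    for phecode in retained:
        y = _case_control_frame(calls, phecode)
        df = covariate_data.copy()
        df[exposure_name] = exposure.reindex(df.index)
        df["_y"] = y.reindex(df.index)
        spec = ModelSpec(exposure=exposure_name, outcome="_y",
                         covariates=list(covariates), family="logistic",
                         label=label)
        res = fit_model(spec, df)
        res.outcome = str(phecode)
        results.append(res)

    n_tests = len(retained)
    alpha_corrected = alpha / n_tests
    for r in results:
        r.significant = bool(np.isfinite(r.p) and r.p < alpha_corrected)
    table = pd.DataFrame([r.to_dict() for r in results])
    table["exposure"] = exposure_name
    table = table.sort_values("p", na_position="last").reset_index(drop=True)

    manhattan = table[["outcome", "p", "estimate", "significant"]].copy()
    manhattan["neg_log10_p"] = -np.log10(manhattan["p"])
    manhattan["direction"] = np.where(manhattan["estimate"] >= 1.0, "+", "-")
    if phecode_groups is not None:
        lookup = phecode_groups.drop_duplicates("phecode_id").set_index("phecode_id")
        manhattan["disease_group"] = lookup["disease_group"].reindex(
            manhattan["outcome"]).to_numpy()
        manhattan["phecode_label"] = lookup["phecode_label"].reindex(
            manhattan["outcome"]).to_numpy()

    return ScanSummary(exposure=exposure_name, n_tests=n_tests,
                       alpha_corrected=alpha_corrected,
                       n_significant=int(table["significant"].sum()),
                       results=table, manhattan=manhattan)


def test_interaction(data: pd.DataFrame, outcome: str, covariates,
                     prs_col: str = "prs_std", index_col: str = "index",
                     label: str = "primary") -> AssociationResult:
    """Interaction OR for PRS x index on one case/control outcome.

    Fits ``logit(y) ~ prs + index + prs:index + covariates`` and reports the
    product term.  A constant product column (no index variation in the
    analytic subsample) is flagged unfit rather than raised.
    """
    df = data.copy()
    product = f"{prs_col}_x_{index_col}"
    df[product] = df[prs_col] * df[index_col]
    if df[[prs_col, index_col, product, outcome]].dropna()[product].nunique() <= 1:
        spec = ModelSpec(exposure=product, outcome=outcome,
                         covariates=list(covariates), label=label)
        return _failed(spec, 0, 0)
    spec = ModelSpec(exposure=prs_col, outcome=outcome,
                     covariates=[index_col, product] + list(covariates),
                     family="logistic", label=label)
    res = fit_model(spec, df, term=product)
    res.exposure = product
    return res


def index_prs_association(data: pd.DataFrame, prs_col: str = "prs_std",
                          index_col: str = "index",
                          component_cols=(), label: str = "primary",
                          covariates=PRIMARY_PRS_COVARIATES):
    """PRS -> lifestyle-index validation models.

    Returns a list of :class:`AssociationResult`: a linear model of the
    composite index on the standardized PRS (beta per SD) followed by one
    logistic model per favorable-component indicator.
    """
    out = []
    spec = ModelSpec(exposure=prs_col, outcome=index_col,
                     covariates=list(covariates), family="linear", label=label)
    out.append(fit_model(spec, data))
    for comp in component_cols:
        spec = ModelSpec(exposure=prs_col, outcome=comp,
                         covariates=list(covariates), family="logistic",
                         label=label)
        out.append(fit_model(spec, data))
    return out
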