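"""Relative-risk estimation for EHR-defined diabetes remission.

The primary model is a log-binomial GLM (binomial likelihood, log link), so
exponentiated coefficients are relative risks.  When the log-binomial fit
fails to converge — a well-known instability of the log link near fitted
probabilities of 1 — the model is refit as a Poisson rate model with robust
(HC0) variance and flagged in the output.

BMI has nontrivial missingness; it is multiply imputed (default m = 10) with
a normal linear model on all adjustment covariates plus the outcome, using
posterior-predictive draws (parameter draw plus residual noise), the BMI
category re-derived per completed table, and estimates pooled by Rubin's
rules (total variance = within-imputation mean + (1 + 1/m) x between).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .config import DiagnosticThresholds, ModelSpec
from .covariates import AGE_BINS, BMI_BINS, A1C_BINS, ERA_MONTHS, _categorize, derive_rows
from .dataset import EhrDataset
from .phenotype import build_cohort
from .remission import classify_cohort

logger = logging.getLogger("remitehr")

Z95 = scipy.stats.norm.ppf(0.975)


class EstimationError(ValueError):
    """Raised when a model cannot be estimated on the given data."""


@dataclass(frozen=True)
class RRResult:
    """One regression term's relative risk with 95% CI."""

    term: str
    rr: float
    ci_low: float
    ci_high: float
    se_log_rr: float
    n: int
    converged: bool = True
    model_used: str = "log_binomial"

    def to_dict(self) -> dict:
        return {
            "term": self.term,
            "rr": self.rr,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "se_log_rr": self.se_log_rr,
            "n": self.n,
            "converged": self.converged,
            "model_used": self.model_used,
        }


@dataclass
class ImputationSet:
    """Completed tables and per-imputation estimates for BMI imputation."""

    m: int
    tables: list[pd.DataFrame]
    estimates: list[list[RRResult]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

_LEVELS = {
    "age_cat": [lab for _, _, lab in AGE_BINS],
    "bmi_cat": [lab for _, _, lab in BMI_BINS] + ["missing"],
    "era": [label for label, _, _ in ERA_MONTHS],
    "vaccine_cat": ["0", "1", ">=2"],
    "region": ["Midwest", "Southeast", "South", "West", "Other"],
}
_RACE_COLS = ["race_black", "race_latinx", "race_white", "race_other"]


def build_design(rows: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Intercept, exposure and adjustment-term columns as a numeric frame.

    Categorical terms are dummy-coded against the spec's reference levels;
    race/ethnicity enters as four non-exclusive indicators; Charlson index
    and the prior-year HbA1c count enter as continuous linear terms.  Levels
    absent from the data are dropped.
    """
    X = pd.DataFrame(index=rows.index)
    X["intercept"] = 1.0
    X[spec.exposure] = rows[spec.exposure].astype(float)
    for term in spec.adjustment:
        if term == "female":
            X["female"] = rows["female"].astype(float)
        elif term == "race_flags":
            for c in _RACE_COLS:
                X[c] = rows[c].astype(float)
        elif term in ("charlson", "n_a1c_prior_year"):
            X[term] = rows[term].astype(float)
        elif term in _LEVELS:
            ref = spec.reference_levels.get(term)
            present = set(rows[term].unique())
            for level in _LEVELS[term]:
                if level == ref or level not in present:
                    continue
                X[f"{term}[{level}]"] = (rows[term] == level).astype(float)
        else:
            X[term] = rows[term].astype(float)
    return X


def _prune_rank_deficient(X: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Drop collinear columns (rank-revealing QR); keep intercept + exposure."""
    import scipy.linalg

    arr = X.to_numpy(dtype=float)
    _, R, piv = scipy.linalg.qr(arr, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = (diag.max() if len(diag) else 0.0) * max(arr.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    keep = sorted(piv[:rank])
    if len(keep) < X.shape[1]:
        dropped = [X.columns[i] for i in range(X.shape[1]) if i not in keep]
        if "intercept" in dropped or spec.exposure in dropped:
            raise EstimationError(
                "design matrix is rank deficient in the exposure or intercept"
            )
        logger.info("dropping collinear design columns: %s", dropped)
        X = X.iloc[:, keep]
    return X


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------

def fit_log_binomial(
    rows: pd.DataFrame, spec: ModelSpec | None = None
) -> list[RRResult]:
    """Fit the remission model and return one RRResult per non-intercept term.

    Raises :class:`EstimationError` on an empty exposure-outcome cell or a
    degenerate (constant) outcome.
    """
    spec = spec or ModelSpec()
    y = rows[spec.outcome].astype(int).to_numpy()
    e = rows[spec.exposure].astype(int).to_numpy()
    n = len(rows)
    for ev in (0, 1):
        for yv in (0, 1):
            if not np.any((e == ev) & (y == yv)):
                raise EstimationError(
                    f"empty cell: {spec.exposure}={ev}, {spec.outcome}={yv} "
                    "has no observations"
                )
    X = build_design(rows, spec)
    X = _prune_rank_deficient(X, spec)
    # if a categorical term's reference cell has no events its rate is not
    # estimable and the intercept diverges; re-reference to the level with
    # the most events
    for term in spec.adjustment:
        if term not in _LEVELS:
            continue
        cols = [c for c in X.columns if c.startswith(f"{term}[")]
        if not cols:
            continue
        in_ref = X[cols].sum(axis=1).to_numpy() == 0
        if in_ref.any() and y[in_ref].sum() == 0:
            events = {c: int(y[X[c].to_numpy() == 1].sum()) for c in cols}
            new_ref = max(events, key=lambda c: events[c])
            if events[new_ref] == 0:
                continue  # entire term separated; handled below
            old_ref = f"{term}[{spec.reference_levels.get(term)}]"
            logger.info("re-referencing %s to %s (empty reference cell)",
                        term, new_ref)
            X[old_ref] = in_ref.astype(float)
            X = X.drop(columns=new_ref)
    # drop separated indicator columns (all or no events in the level): their
    # log-RR is unbounded and would destroy the fit
    drop = []
    for c in X.columns:
        if c in ("intercept", spec.exposure):
            continue
        col = X[c].to_numpy()
        if set(np.unique(col)) <= {0.0, 1.0} and col.sum() > 0:
            events = y[col == 1].sum()
            if events == 0 or events == col.sum():
                drop.append(c)
    if drop:
        logger.info("dropping separated design columns: %s", drop)
        X = X.drop(columns=drop)
    start = np.zeros(X.shape[1])
    start[0] = np.log(max(y.mean(), 1e-6))

    converged = True
    model_used = "log_binomial"
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=sm.families.Binomial(sm.families.links.Log())).fit(
                start_params=start, maxiter=200, tol=1e-12
            )
        params, bse = res.params, res.bse
        converged = bool(res.converged) and np.isfinite(bse.to_numpy()).all()
        mu_ok = np.all(res.mu < 1 - 1e-10)
        if not (converged and mu_ok):
            raise ValueError("log-binomial fit did not converge")
    except Exception:  # fall back to a rate model with robust variance
        converged = False
        model_used = "poisson_robust_fallback"
        res = sm.GLM(y, X, family=sm.families.Poisson()).fit(cov_type="HC0")
        params, bse = res.params, res.bse
        if not np.isfinite(bse.to_numpy()).all():
            raise EstimationError("fallback rate model produced non-finite variance")
        converged = bool(res.converged)

    out = []
    for term in X.columns:
        if term == "intercept":
            continue
        b, se = float(params[term]), float(bse[term])
        out.append(
            RRResult(
                term=term,
                rr=float(np.exp(b)),
                ci_low=float(np.exp(b - Z95 * se)),
                ci_high=float(np.exp(b + Z95 * se)),
                se_log_rr=se,
                n=n,
                converged=converged,
                model_used=model_used,
            )
        )
    return out


# ---------------------------------------------------------------------------
# multiple imputation of BMI
# ---------------------------------------------------------------------------

def impute_bmi(rows: pd.DataFrame, m: int = 10, seed: int = 0,
               spec: ModelSpec | None = None) -> ImputationSet:
    """Multiply impute continuous BMI, re-deriving the BMI category.

    A normal linear regression of BMI on all model covariates plus the
    outcome is fit to the observed rows; each imputation draws regression
    parameters from their posterior and adds residual noise, truncating to
    the plausible range [12, 80] kg/m^2.  With no missing values the m
    completed tables equal the input.
    """
    spec = spec or ModelSpec()
    missing = rows["bmi"].isna().to_numpy()
    if missing.all():
        raise EstimationError("BMI is missing for every row; cannot impute")
    if not missing.any():
        return ImputationSet(m=m, tables=[rows] * m)

    rng = np.random.default_rng(seed)
    imp_spec = ModelSpec(
        outcome=spec.outcome,
        exposure=spec.exposure,
        adjustment=tuple(t for t in spec.adjustment if t != "bmi_cat"),
        reference_levels=spec.reference_levels,
    )
    X = build_design(rows, imp_spec)
    X[spec.outcome] = rows[spec.outcome].astype(float)
    Xo = X.loc[~missing].to_numpy(dtype=float)
    yo = rows.loc[~missing, "bmi"].to_numpy(dtype=float)
    Xm = X.loc[missing].to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(Xo, yo, rcond=None)
    resid = yo - Xo @ beta
    df = max(len(yo) - Xo.shape[1], 1)
    sse = float(resid @ resid)
    xtx_inv = np.linalg.pinv(Xo.T @ Xo)
    chol = np.linalg.cholesky(xtx_inv + 1e-12 * np.eye(len(beta)))

    tables = []
    for _ in range(m):
        sigma2 = sse / rng.chisquare(df)
        beta_draw = beta + np.sqrt(sigma2) * (chol @ rng.standard_normal(len(beta)))
        draw = Xm @ beta_draw + rng.normal(0.0, np.sqrt(sigma2), Xm.shape[0])
        completed = rows.copy()
        completed.loc[missing, "bmi"] = np.clip(draw, 12.0, 80.0)
        completed["bmi_cat"] = _categorize(
            completed["bmi"].to_numpy(), BMI_BINS, "missing"
        )
        tables.append(completed)
    return ImputationSet(m=m, tables=tables)


def pool_rubin(per_imputation: list[tuple[float, float]], term: str = "exposed",
               n: int = 0) -> RRResult:
    """Pool one term's (log RR, SE) pairs across imputations by Rubin's rules."""
    ests = np.array([b for b, _ in per_imputation], dtype=float)
    ses = np.array([s for _, s in per_imputation], dtype=float)
    m = len(ests)
    qbar = ests.mean()
    within = float((ses**2).mean())
    between = float(ests.var(ddof=1)) if m > 1 else 0.0
    total = within + (1 + 1 / m) * between
    se = np.sqrt(total)
    with np.errstate(over="ignore"):  # an unbounded CI limit is reported as inf
        return RRResult(
            term=term,
            rr=float(np.exp(qbar)),
            ci_low=float(np.exp(qbar - Z95 * se)),
            ci_high=float(np.exp(qbar + Z95 * se)),
            se_log_rr=float(se),
            n=n,
        )


def fit_pooled(rows: pd.DataFrame, spec: ModelSpec | None = None, m: int = 10,
               seed: int = 0) -> list[RRResult]:
    """Impute BMI m times, fit the model per completed table, pool per term."""
    spec = spec or ModelSpec()
    if not rows["bmi"].isna().any():
        # degenerate MI: all completed tables equal the input, pooled
        # estimates equal the complete-data fit
        return fit_log_binomial(rows, spec)
    imp = impute_bmi(rows, m=m, seed=seed, spec=spec)
    per_term: dict[str, list[tuple[float, float]]] = {}
    fallback = False
    for table in imp.tables:
        results = fit_log_binomial(table, spec)
        imp.estimates.append(results)
        for r in results:
            per_term.setdefault(r.term, []).append((np.log(r.rr), r.se_log_rr))
            fallback = fallback or r.model_used != "log_binomial"
    pooled = []
    for term, pairs in per_term.items():
        if len(pairs) != imp.m:  # level absent in some completed tables
            continue
        r = pool_rubin(pairs, term=term, n=len(rows))
        if fallback:
            r = RRResult(**{**r.to_dict(), "model_used": "poisson_robust_fallback",
                            "converged": False})
        pooled.append(r)
    return pooled


# ---------------------------------------------------------------------------
# descriptive table
# ---------------------------------------------------------------------------

def percent(count: int, denom: int) -> int:
    """Integer percentage as printed in the descriptive table."""
    if denom == 0:
        return 0
    return int(round(100.0 * count / denom))


CONTINUOUS_VARS = (
    "follow_up_days", "age_years", "bmi", "charlson", "n_visits_prior_year",
    "n_vitals_prior_year", "n_glucose_prior_year", "n_a1c_prior_year",
)
CATEGORICAL_VARS = (
    "remission", "age_cat", "female", "race_black", "race_latinx", "race_white",
    "race_other", "bmi_cat", "smoking", "hospitalized", "vaccine_cat",
    "early_a1c_cat", "era",
)


def descriptive_table(rows: pd.DataFrame, by: str = "exposed") -> pd.DataFrame:
    """Stratified descriptive summary (mean +/- SD; n, %) with group tests.

    Continuous variables use an unequal-variance (Welch) t test; categorical
    variables a chi-square test without continuity correction.  Percentages
    are rounded to integers.
    """
    g1 = rows[rows[by].astype(bool)]
    g0 = rows[~rows[by].astype(bool)]
    recs = []

    def add(var, level, overall, a, b, p):
        recs.append({"variable": var, "level": level, "overall": overall,
                     "unexposed": a, "exposed": b, "p_value": p})

    add("n", "", f"{len(rows)}", f"{len(g0)}", f"{len(g1)}", np.nan)
    for var in CONTINUOUS_VARS:
        x0 = g0[var].dropna().astype(float)
        x1 = g1[var].dropna().astype(float)
        if len(x0) > 1 and len(x1) > 1 and (x0.var() + x1.var()) > 0:
            p = float(scipy.stats.ttest_ind(x0, x1, equal_var=False).pvalue)
        else:
            p = 1.0
        fmt = lambda x: f"{x.mean():.1f} ± {x.std(ddof=1):.1f}" if len(x) > 1 else "-"
        add(var, "", fmt(rows[var].dropna().astype(float)), fmt(x0), fmt(x1), p)
    for var in CATEGORICAL_VARS:
        levels = sorted(rows[var].astype(str).unique())
        table = np.array(
            [[(g[var].astype(str) == lv).sum() for lv in levels] for g in (g0, g1)]
        )
        nz = table.sum(axis=0) > 0
        if nz.sum() > 1 and len(g0) and len(g1):
            p = float(scipy.stats.chi2_contingency(table[:, nz], correction=False)[1])
        else:
            p = 1.0
        for j, lv in enumerate(levels):
            tot = int(table[:, j].sum())
            add(var, lv,
                f"{tot} ({percent(tot, len(rows))}%)",
                f"{table[0, j]} ({percent(int(table[0, j]), len(g0))}%)",
                f"{table[1, j]} ({percent(int(table[1, j]), len(g1))}%)",
                p)
    return pd.DataFrame(recs)


# ---------------------------------------------------------------------------
# end-to-end analysis of one dataset
# ---------------------------------------------------------------------------

@dataclass
class AnalysisResult:
    cohort_id: int
    rows: pd.DataFrame
    remission: pd.DataFrame
    results: list[RRResult]
    gate_counts: dict
    exclusions: pd.DataFrame
    table1: pd.DataFrame


def analyze_dataset(
    ds: EhrDataset,
    cohort_id: int = 1,
    flavor: str = "any_lab",
    th: DiagnosticThresholds | None = None,
    spec: ModelSpec | None = None,
    m: int = 10,
    seed: int = 0,
    subset_non_hospitalized: bool = False,
) -> AnalysisResult:
    """Cohort construction, remission classification, covariates and the
    pooled adjusted model for one dataset."""
    th = th or DiagnosticThresholds()
    spec = spec or ModelSpec()
    build = build_cohort(ds, cohort_id=cohort_id, flavor=flavor, th=th, seed=seed)
    rem = classify_cohort(ds, build.cohort, th=th)
    rows = derive_rows(ds, build.cohort, rem, th=th)
    if subset_non_hospitalized:
        rows = rows[~rows["hospitalized"]].reset_index(drop=True)
    results = fit_pooled(rows, spec=spec, m=m, seed=seed)
    return AnalysisResult(
        cohort_id=cohort_id,
        rows=rows,
        remission=rem,
        results=results,
        gate_counts=build.gate_counts,
        exclusions=build.exclusions,
        table1=descriptive_table(rows),
    )


def run_sensitivity(
    ds: EhrDataset,
    which: str,
    cohort_id: int = 1,
    th: DiagnosticThresholds | None = None,
    spec: ModelSpec | None = None,
    m: int = 10,
    seed: int = 0,
) -> AnalysisResult:
    """The study's sensitivity analyses.

    * ``threshold_5_7`` — remission defined at HbA1c < 5.7%;
    * ``non_hospitalized`` — restrict to patients not hospitalized around
      the index date before fitting;
    * ``negative_swab_comparator`` — rebuild the unexposed arm from patients
      with a prior negative swab (index months among negative-swab months).
    """
    th = th or DiagnosticThresholds()
    if which == "threshold_5_7":
        return analyze_dataset(
            ds, cohort_id, th=th.with_remission_threshold(5.7), spec=spec, m=m,
            seed=seed,
        )
    if which == "non_hospitalized":
        return analyze_dataset(
            ds, cohort_id, th=th, spec=spec, m=m, seed=seed,
            subset_non_hospitalized=True,
        )
    if which == "negative_swab_comparator":
        return analyze_dataset(
            ds, cohort_id, flavor="negative_swab", th=th, spec=spec, m=m, seed=seed
        )
    raise ValueError(f"unknown sensitivity analysis: {which!r}")
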