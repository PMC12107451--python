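"""Risks and risk ratios of adverse outcomes by weight-gain Z-score group.

The exposure is the weight-gain-for-gestational-age Z-score quartile
group (G1 <= 25th percentile ... G4 > 75th, reference G3 = 51st-75th),
and analyses are stratified by baseline BMI group.  Binary outcomes are
modelled with *modified Poisson regression*: a log-link Poisson working
model on the 0/1 outcome whose coefficients are log risk ratios, with a
robust (sandwich) variance to repair the misspecified Poisson variance.
On a saturated design this reproduces the closed-form ratio of
proportions exactly.

Adjusted risks are obtained by marginal standardization: average the
model's predicted risk over the stratum's observed covariate
distribution with the exposure group set counterfactually; confidence
intervals by the delta method.  Continuous adjustment covariates enter
through restricted quadratic splines with three equally spaced knots.

Dose-response curves use marginal logistic regression (GEE with an
independence working correlation, one record per pregnancy) with the
continuous Z-score splined, followed by a locally weighted scatterplot
smoother of the predicted probabilities against Z.  Associations between
baseline characteristics and Z-scores use marginal linear models with
cluster-robust standard errors, clustering on study cohort.

``run_primary_analysis`` orchestrates the full pipeline: visit
validation, population selection, chart fitting on the reference
subpopulation, Z-scoring, multiple imputation, per-imputation modified
Poisson fits, and Rubin's-rules pooling (log scale for risk ratios).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .splines import equally_spaced_knots, rqs_basis
from .filtering import validate_visits, select_study_population, select_reference_subpopulation
from .reference import gwg_observations, build_reference_charts, transform_gwg
from .zscores import zscore_group, compute_total_gwg, zscore_percentile
from .imputation import impute, rubin_pool

__all__ = [
    "OutcomeSpec",
    "OUTCOME_SPECS",
    "modified_poisson_rr",
    "marginal_adjusted_risk",
    "gee_dose_response",
    "baseline_assoc",
    "run_primary_analysis",
]

Z_GROUPS = ("G1", "G2", "G3", "G4")
REFERENCE_GROUP = "G3"

DEFAULT_COVARIATES = (
    "maternal_age_years",
    "enrol_ga_weeks",
    "height_cm",
    "bmi_kg_m2",
    "parous",
    "prior_preterm",
)


@dataclass(frozen=True)
class OutcomeSpec:
    """A named binary outcome defined as a predicate over outcome records."""

    name: str
    predicate: callable
    primary: bool = True

    def flags(self, outcomes: pd.DataFrame) -> pd.Series:
        return self.predicate(outcomes).astype(float)


OUTCOME_SPECS = {
    "preterm37": OutcomeSpec("preterm37", lambda t: t["delivery_ga_weeks"] < 37),
    "preterm32": OutcomeSpec("preterm32", lambda t: t["delivery_ga_weeks"] < 32, primary=False),
    "lbw": OutcomeSpec("lbw", lambda t: t["birth_weight_g"] < 2500),
    "vlbw": OutcomeSpec("vlbw", lambda t: t["birth_weight_g"] < 1500, primary=False),
    "sga10": OutcomeSpec("sga10", lambda t: t["newborn_centile"] < 10),
    "sga3": OutcomeSpec("sga3", lambda t: t["newborn_centile"] < 3),
    "stillbirth": OutcomeSpec("stillbirth", lambda t: t["stillbirth"].astype(bool), primary=False),
    "caesarean": OutcomeSpec("caesarean", lambda t: t["caesarean"].astype(bool), primary=False),
}


def _covariate_columns(df: pd.DataFrame, covariates) -> pd.DataFrame:
    """Adjustment design: binaries as 0/1, continuous as 3-knot RQS bases."""
    cols = {}
    for c in covariates:
        x = df[c]
        if x.dropna().nunique() <= 1:
            continue  # constant within stratum/subset: no information, would be collinear
        if x.dtype == bool or x.dropna().nunique() <= 2:
            cols[c] = x.astype(float).to_numpy()
        else:
            vals = x.to_numpy(dtype=float)
            knots = equally_spaced_knots(vals, k=3)
            basis = rqs_basis(vals, knots)
            cols[c] = basis[:, 0]
            for j in range(1, basis.shape[1]):
                cols[f"{c}_rqs{j}"] = basis[:, j]
    return pd.DataFrame(cols, index=df.index)


def _group_dummies(groups: pd.Series, levels=Z_GROUPS, ref=REFERENCE_GROUP) -> pd.DataFrame:
    out = {}
    for g in levels:
        if g == ref:
            continue
        out[f"group[{g}]"] = (groups == g).astype(float).to_numpy()
    return pd.DataFrame(out, index=groups.index)


@dataclass
class RiskTableRows:
    """Modified-Poisson results for one (outcome, BMI stratum)."""

    table: pd.DataFrame          # per group: events, N, crude/adjusted risk, RR, CIs
    log_rr: dict                 # group -> log RR point estimate
    log_rr_var: dict             # group -> robust variance of log RR
    adj_risk: dict               # group -> marginal standardized risk
    adj_risk_var: dict
    diagnostics: list = field(default_factory=list)


def marginal_adjusted_risk(result, X: pd.DataFrame, group_cols, level_col):
    """Standardized risk with the exposure set counterfactually.

    Sets every row's group indicators to the requested level, averages
    the log-link predictions over the observed covariate distribution,
    and returns ``(risk, variance)`` with the variance by the delta
    method through the robust coefficient covariance.
    """
    Xc = X.copy()
    for c in group_cols:
        Xc[c] = 1.0 if c == level_col else 0.0
    M = Xc.to_numpy()
    beta = np.asarray(result.params)
    eta = M @ beta
    mu = np.exp(eta)
    risk = float(np.mean(mu))
    grad = (mu[:, None] * M).mean(axis=0)
    V = np.asarray(result.cov_params())
    var = float(grad @ V @ grad)
    return risk, var


def modified_poisson_rr(
    df: pd.DataFrame,
    outcome_col: str,
    group_col: str = "z_group",
    covariates=(),
    ref: str = REFERENCE_GROUP,
    levels=Z_GROUPS,
) -> RiskTableRows:
    """Fit the modified Poisson model within one stratum.

    ``df`` holds one row per pregnancy with a 0/1 ``outcome_col`` and the
    exposure ``group_col``.  Returns per-group counts, crude risk,
    marginal standardized adjusted risk with 95% CI, and adjusted risk
    ratio versus ``ref`` with Wald 95% CI from the sandwich variance.
    Groups with zero events get an undefined RR and a diagnostic instead
    of a degenerate fit.
    """
    import statsmodels.api as sm

    y = df[outcome_col].astype(float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError(f"{outcome_col!r} must be binary 0/1")
    groups = df[group_col]
    if not (groups == ref).any():
        raise ValueError(f"reference group {ref!r} absent from stratum")

    counts = {
        g: (int(y[groups == g].sum()), int((groups == g).sum())) for g in levels
    }
    diagnostics = []
    absent = [g for g in levels if g != ref and counts[g][1] == 0]
    zero_events = [g for g in levels if g != ref and counts[g][1] > 0 and counts[g][0] == 0]
    degenerate = absent + zero_events
    usable = df.index[~groups.isin(degenerate)]
    if zero_events:
        diagnostics.append(
            f"zero events in group(s) {zero_events}; RR undefined there"
        )

    sub = df.loc[usable]
    gd = _group_dummies(sub[group_col], levels=levels, ref=ref)
    gd = gd[[c for c in gd.columns if c not in [f"group[{g}]" for g in degenerate]]]
    parts = [pd.DataFrame({"intercept": np.ones(len(sub))}, index=sub.index), gd]
    if covariates:
        parts.append(_covariate_columns(sub, covariates))
    X = pd.concat(parts, axis=1)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(sub[outcome_col].astype(float), X, family=sm.families.Poisson()).fit(
            cov_type="HC1"
        )

    group_cols = [c for c in X.columns if c.startswith("group[")]
    zq = stats.norm.ppf(0.975)
    rows, log_rr, log_rr_var, adj_risk, adj_risk_var = [], {}, {}, {}, {}
    for g in levels:
        events, N = counts[g]
        crude = 100.0 * events / N if N else np.nan
        col = f"group[{g}]"
        if g == ref:
            lr, lv = 0.0, 0.0
        elif g in degenerate or N == 0:
            lr, lv = np.nan, np.nan
        else:
            lr = float(res.params[col])
            lv = float(res.cov_params().loc[col, col])
        if N and g not in degenerate:
            r, rv = marginal_adjusted_risk(res, X, group_cols, col if g != ref else None)
            if r > 1.0:
                diagnostics.append(f"standardized risk > 1 in group {g} ({r:.3f})")
        else:
            r, rv = np.nan, np.nan
        log_rr[g], log_rr_var[g] = lr, lv
        adj_risk[g], adj_risk_var[g] = r, rv
        rr = 1.0 if g == ref else (np.exp(lr) if np.isfinite(lr) else np.nan)
        half = zq * np.sqrt(lv) if np.isfinite(lv) else np.nan
        risk_half = zq * np.sqrt(rv) if np.isfinite(rv) else np.nan
        rows.append(
            {
                "group": g,
                "events": events,
                "N": N,
                "crude_risk_pct": crude,
                "adj_risk_pct": 100.0 * r if np.isfinite(r) else np.nan,
                "adj_risk_lo_pct": 100.0 * (r - risk_half) if np.isfinite(rv) else np.nan,
                "adj_risk_hi_pct": 100.0 * (r + risk_half) if np.isfinite(rv) else np.nan,
                "rr": rr,
                "rr_lo": np.exp(lr - half) if g != ref and np.isfinite(lv) else (1.0 if g == ref else np.nan),
                "rr_hi": np.exp(lr + half) if g != ref and np.isfinite(lv) else (1.0 if g == ref else np.nan),
            }
        )
    return RiskTableRows(pd.DataFrame(rows), log_rr, log_rr_var, adj_risk, adj_risk_var, diagnostics)


def gee_dose_response(
    df: pd.DataFrame,
    outcome_col: str,
    z_col: str = "z",
    covariates=(),
    bmi_col: str = "bmi_group",
    id_col: str = "participant_id",
    z_grid=None,
    lowess_frac: float = 0.4,
) -> pd.DataFrame:
    """Smoothed predicted-probability curve of an outcome against Z.

    Per BMI stratum: marginal logistic model (GEE, independence working
    correlation, one cluster per pregnancy) with the Z-score entered as a
    3-equally-spaced-knot restricted quadratic spline plus covariates;
    per-participant predicted probabilities are then smoothed against Z
    with a locally weighted regression and evaluated on a fixed grid.
    Returns tidy rows (bmi_group, z, prob).
    """
    import statsmodels.api as sm
    from statsmodels.nonparametric.smoothers_lowess import lowess

    if z_grid is None:
        z_grid = np.linspace(-3.0, 3.0, 61)
    out_rows = []
    for g, sub in df.groupby(bmi_col, observed=True):
        zvals = sub[z_col].to_numpy(dtype=float)
        knots = equally_spaced_knots(zvals, k=3)
        basis = rqs_basis(zvals, knots)
        parts = {"intercept": np.ones(len(sub)), "z": basis[:, 0]}
        for j in range(1, basis.shape[1]):
            parts[f"z_rqs{j}"] = basis[:, j]
        X = pd.DataFrame(parts, index=sub.index)
        if covariates:
            X = pd.concat([X, _covariate_columns(sub, covariates)], axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GEE(
                sub[outcome_col].astype(float), X, groups=sub[id_col],
                family=sm.families.Binomial(),
                cov_struct=sm.cov_struct.Independence(),
            ).fit()
        pred = np.asarray(res.predict(X))
        lo, hi = zvals.min(), zvals.max()
        grid = z_grid[(z_grid >= lo) & (z_grid <= hi)]
        smooth = lowess(pred, zvals, frac=lowess_frac, xvals=grid)
        for zv, pv in zip(grid, smooth):
            out_rows.append({"bmi_group": g, "z": zv, "prob": pv})
    return pd.DataFrame(out_rows)


def baseline_assoc(
    df: pd.DataFrame,
    z_col: str,
    characteristic: str,
    cohort_col: str = "cohort",
) -> pd.DataFrame:
    """Mean Z-score difference per category of a baseline characteristic.

    Marginal linear (identity-link) model of Z on category indicators
    with cluster-robust standard errors, clustering on study cohort; the
    first category is the reference.  With a single cohort the variance
    falls back to a heteroscedasticity-robust estimator with a warning.
    """
    import statsmodels.api as sm

    cats = pd.Categorical(df[characteristic])
    levels = list(cats.categories)
    X = pd.DataFrame({"intercept": np.ones(len(df))}, index=df.index)
    for lv in levels[1:]:
        X[f"{characteristic}[{lv}]"] = (cats == lv).astype(float)
    y = df[z_col].astype(float)

    n_cohorts = df[cohort_col].nunique()
    if n_cohorts >= 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GEE(
                y, X, groups=df[cohort_col], family=sm.families.Gaussian(),
                cov_struct=sm.cov_struct.Independence(),
            ).fit()
        params, cov = np.asarray(res.params), np.asarray(res.cov_params())
    else:
        warnings.warn("single cohort: using heteroscedasticity-robust SEs")
        res = sm.OLS(y, X).fit(cov_type="HC1")
        params, cov = np.asarray(res.params), np.asarray(res.cov_params())

    zq = stats.norm.ppf(0.975)
    rows = []
    for i, name in enumerate(X.columns):
        if name == "intercept":
            continue
        se = float(np.sqrt(cov[i, i]))
        rows.append(
            {
                "category": name.split("[", 1)[1].rstrip("]"),
                "estimate": float(params[i]),
                "se": se,
                "ci_lo": float(params[i] - zq * se),
                "ci_hi": float(params[i] + zq * se),
            }
        )
    return pd.DataFrame(rows)


def _zscore_against_chart(tot: pd.DataFrame, charts: pd.DataFrame) -> pd.Series:
    """Vectorized transformed-scale Z-scores (nearest-week chart lookup)."""
    t = tot.copy()
    t["ga_week"] = t["ga_last_weeks"].round().astype(int)
    merged = t.merge(
        charts[["cohort", "bmi_group", "ga_week", "mu_log", "sd_log"]],
        on=["cohort", "bmi_group", "ga_week"],
        how="left",
    )
    if merged["mu_log"].isna().any():
        missing = merged.loc[merged["mu_log"].isna(), ["cohort", "bmi_group", "ga_week"]]
        raise ValueError(
            f"{len(missing)} pregnancies standardized at weeks outside the "
            f"chart support, e.g.\n{missing.drop_duplicates().head()}"
        )
    y = transform_gwg(merged["total_gwg_kg"].to_numpy())
    z = (y - merged["mu_log"].to_numpy()) / merged["sd_log"].to_numpy()
    return pd.Series(z, index=tot.index)


def build_analysis_table(visits, baselines, outcomes, charts, ids) -> pd.DataFrame:
    """One row per pregnancy: Z-score, group, covariates, outcome flags."""
    sub_v = visits[visits["participant_id"].isin(ids)]
    sub_b = baselines[baselines["participant_id"].isin(ids)]
    sub_o = outcomes[outcomes["participant_id"].isin(ids)]
    tot = compute_total_gwg(sub_v, sub_b, sub_o)
    tot["z"] = _zscore_against_chart(tot, charts)
    tab = tot.merge(sub_b.drop(columns=["cohort", "bmi_group"]), on="participant_id")
    tab = tab.merge(sub_o, on="participant_id")
    for name, spec in OUTCOME_SPECS.items():
        missing_inputs = tab[_outcome_inputs(name)].isna().any(axis=1)
        flags = spec.flags(tab).astype(float)
        flags[missing_inputs] = np.nan
        tab[name] = flags
    return tab


def _outcome_inputs(name: str):
    return {
        "preterm37": ["delivery_ga_weeks"],
        "preterm32": ["delivery_ga_weeks"],
        "lbw": ["birth_weight_g"],
        "vlbw": ["birth_weight_g"],
        "sga10": ["newborn_centile"],
        "sga3": ["newborn_centile"],
        "stillbirth": ["stillbirth"],
        "caesarean": ["caesarean"],
    }[name]


@dataclass
class PrimaryAnalysisResult:
    flow: dict
    charts: pd.DataFrame
    risk_tables: dict          # (outcome, bmi_group) -> pooled RiskTable DataFrame
    m: int
    sensitivity: dict = field(default_factory=dict)

    def table_report(self) -> str:
        """Plain-text block of all pooled risk tables."""
        blocks = []
        for (outcome, stratum), tab in self.risk_tables.items():
            blocks.append(f"== {outcome} | {stratum} ==")
            blocks.append(tab.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
        return "\n".join(blocks)


def _pool_stratum(per_imp: list[RiskTableRows], m: int) -> pd.DataFrame:
    """Rubin-pool per-imputation stratum fits (log scale for RRs)."""
    zq = stats.norm.ppf(0.975)
    rows = []
    for g in Z_GROUPS:
        events = int(round(np.mean([r.table.set_index("group").loc[g, "events"] for r in per_imp])))
        N = int(round(np.mean([r.table.set_index("group").loc[g, "N"] for r in per_imp])))
        lrs = np.array([r.log_rr[g] for r in per_imp], dtype=float)
        lvs = np.array([r.log_rr_var[g] for r in per_imp], dtype=float)
        ars = np.array([r.adj_risk[g] for r in per_imp], dtype=float)
        avs = np.array([r.adj_risk_var[g] for r in per_imp], dtype=float)
        if m == 1:
            lr, lse = lrs[0], np.sqrt(lvs[0])
            ar, ase = ars[0], np.sqrt(avs[0])
        elif np.any(~np.isfinite(lrs)):
            lr = lse = ar = ase = np.nan
        else:
            p = rubin_pool(lrs, lvs)
            lr, lse = p.point, p.se
            pr = rubin_pool(ars, avs)
            ar, ase = pr.point, pr.se
        if g == REFERENCE_GROUP:
            rr, rr_lo, rr_hi = 1.0, 1.0, 1.0
        else:
            rr = np.exp(lr) if np.isfinite(lr) else np.nan
            rr_lo = np.exp(lr - zq * lse) if np.isfinite(lr) else np.nan
            rr_hi = np.exp(lr + zq * lse) if np.isfinite(lr) else np.nan
        rows.append(
            {
                "group": g,
                "events": events,
                "N": N,
                "adj_risk_pct": 100 * ar,
                "adj_risk_lo_pct": 100 * (ar - zq * ase),
                "adj_risk_hi_pct": 100 * (ar + zq * ase),
                "rr": rr,
                "rr_lo": rr_lo,
                "rr_hi": rr_hi,
            }
        )
    return pd.DataFrame(rows)


def run_primary_analysis(
    visits: pd.DataFrame,
    baselines: pd.DataFrame,
    outcomes: pd.DataFrame,
    outcome_names=("preterm37", "lbw", "sga10", "sga3"),
    covariates=DEFAULT_COVARIATES,
    m: int = 5,
    iterations: int = 3,
    seed: int = 0,
    bmi_strata=("underweight", "normal", "overweight", "obese"),
    exclude_prior_preterm: bool = False,
    by_cohort: bool = False,
) -> PrimaryAnalysisResult:
    """End-to-end pipeline from raw tables to pooled risk tables.

    Charts are fitted on the reference subpopulation; Z-scores, quartile
    groups and modified-Poisson fits are computed on each of the ``m``
    imputed copies of the analysis table and pooled by Rubin's rules.
    With complete data the pipeline collapses to a single fit (m = 1,
    between-imputation variance zero).  Sensitivity reruns (per-cohort,
    or excluding pregnancies with a previous preterm birth) reuse the
    same charts.
    """
    v = validate_visits(visits, baselines)
    study_ids, flow1 = select_study_population(v, baselines, outcomes)
    ref_ids, flow2 = select_reference_subpopulation(study_ids, v, outcomes)
    flow = {**flow1, **flow2}

    obs = gwg_observations(v[v["participant_id"].isin(ref_ids)], baselines)
    charts = build_reference_charts(obs)

    tab = build_analysis_table(v, baselines, outcomes, charts, study_ids)

    analysis_cols = list(covariates) + ["z"] + [n for n in outcome_names]
    has_missing = tab[analysis_cols].isna().any().any()
    if has_missing:
        imp = impute(tab, variables=None, m=m, iterations=iterations, seed=seed)
        copies = imp.tables
    else:
        copies = [tab]
    m_eff = len(copies)

    def fit_tables(selector=None):
        risk_tables = {}
        for outcome in outcome_names:
            for stratum in bmi_strata:
                per_imp = []
                for copy in copies:
                    sub = copy[copy["bmi_group"] == stratum]
                    if selector is not None:
                        sub = sub[selector(sub)]
                    if sub.empty or not (zscore_group(sub["z"].to_numpy()) == REFERENCE_GROUP).any():
                        per_imp = []
                        break
                    sub = sub.copy()
                    sub["z_group"] = zscore_group(sub["z"].to_numpy())
                    sub[outcome] = (sub[outcome].astype(float) > 0.5).astype(float)
                    per_imp.append(
                        modified_poisson_rr(sub, outcome, covariates=covariates)
                    )
                if per_imp:
                    risk_tables[(outcome, stratum)] = _pool_stratum(per_imp, m_eff)
        return risk_tables

    result = PrimaryAnalysisResult(
        flow=flow, charts=charts, risk_tables=fit_tables(), m=m_eff
    )
    if exclude_prior_preterm:
        sel = lambda sub: ~(sub["prior_preterm"].astype(float) > 0.5)
        tables = fit_tables(sel)
        result.sensitivity["no_prior_preterm"] = {
            "n": int((~(copies[0]["prior_preterm"].astype(float) > 0.5)).sum()),
            "risk_tables": tables,
        }
    if by_cohort:
        for c in sorted(copies[0]["cohort"].unique()):
            sel = lambda sub, c=c: sub["cohort"] == c
            result.sensitivity[f"cohort:{c}"] = {
                "n": int((copies[0]["cohort"] == c).sum()),
                "risk_tables": fit_tables(sel),
            }
    return result
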