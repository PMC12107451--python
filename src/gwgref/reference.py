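"""Longitudinal reference model for gestational weight gain (GWG).

Weight gain at each antenatal visit is ``gwg = visit weight - baseline
weight`` (kg).  Gains can be negative early in pregnancy, so before
modelling they are shifted by +5 kg and log-transformed:

    y = ln(gwg + 5)

which removes the left skew of raw gains.  On this scale a linear mixed
model is fitted separately per cohort, restricted to the reference
subpopulation (term livebirths with an early baseline weight):

    y_ij = f(t_ij) + gamma_g + delta_g * t_ij + b_i + e_ij

where ``f`` is a restricted quadratic spline in gestational age ``t``
(four knots at the 5th/35th/65th/95th percentiles of visit gestational
ages, cohort-specific), ``gamma_g`` are BMI-group main effects,
``delta_g`` are BMI-group-by-linear-gestational-age interactions,
``b_i ~ N(0, sigma_b^2)`` is a participant random intercept and
``e_ij ~ N(0, sigma_e^2)`` the residual.  Estimation is by REML so the
variance components — which set the chart SD — are unbiased.

From a converged fit, :func:`chart_from_model` evaluates the fixed-effect
mean ``mu_log(t, g)`` on an integer grid of gestational weeks and combines
it with ``sd_log = sqrt(sigma_b^2 + sigma_e^2)`` into reference
percentiles on the kg scale, assuming normality of ``y``:

    P_p(t, g) = exp(mu_log + z_p * sd_log) - 5.

The default SD is constant across gestational age because the fitted
variance components are homoscedastic; the chart still carries an SD
column per week so heteroscedastic variants can slot in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .splines import KnotSet, percentile_knots, rqs_basis

__all__ = [
    "transform_gwg",
    "inverse_transform",
    "gwg_observations",
    "ReferenceModelFit",
    "fit_reference_model",
    "chart_from_model",
    "build_reference_charts",
    "CHART_PERCENTILES",
]

#: shift (kg) applied before the natural-log transform of weight gain
LOG_SHIFT_KG = 5.0

#: percentiles published in a reference chart row
CHART_PERCENTILES = (3, 5, 10, 25, 50, 75, 90, 95, 97)

GA_GRID_MIN, GA_GRID_MAX = 8, 42

BMI_GROUPS = ("underweight", "normal", "overweight", "obese")


def transform_gwg(gwg_kg):
    """Transformed gain ``y = ln(gwg + 5)``; defined for gains > -5 kg."""
    gwg_kg = np.asarray(gwg_kg, dtype=float)
    if np.any(gwg_kg <= -LOG_SHIFT_KG):
        bad = np.atleast_1d(gwg_kg)[np.atleast_1d(gwg_kg) <= -LOG_SHIFT_KG]
        raise ValueError(
            f"weight gain <= -{LOG_SHIFT_KG} kg is outside the transform's "
            f"domain (offending values: {bad[:5]})"
        )
    out = np.log(gwg_kg + LOG_SHIFT_KG)
    return float(out) if out.ndim == 0 else out

def inverse_transform(y):
    """Back-transform ``gwg = exp(y) - 5``; exact inverse of :func:`transform_gwg`."""
    y = np.asarray(y, dtype=float)
    out = np.exp(y) - LOG_SHIFT_KG
    return float(out) if out.ndim == 0 else out


def gwg_observations(visits: pd.DataFrame, baselines: pd.DataFrame) -> pd.DataFrame:
    """Join valid visits to baselines and compute transformed gains.

    Expects a ``valid`` flag on visits (see ``gwgref.filtering``); rows
    flagged invalid are dropped.  Returns one row per retained visit with
    columns ``participant_id, cohort, bmi_group, ga_weeks, gwg_kg, y``.
    """
    v = visits
    if "valid" in v.columns:
        v = v[v["valid"]]
    base = baselines.set_index("participant_id")
    obs = v.merge(
        base[["baseline_weight_kg", "bmi_group"]],
        left_on="participant_id",
        right_index=True,
        how="inner",
    ).copy()
    obs["gwg_kg"] = obs["weight_kg"] - obs["baseline_weight_kg"]
    obs["y"] = transform_gwg(obs["gwg_kg"].to_numpy())
    return obs[["participant_id", "cohort", "bmi_group", "ga_weeks", "gwg_kg", "y"]]


@dataclass
class ReferenceModelFit:
    """Fitted per-cohort mixed model on the transformed-gain scale."""

    cohort: str
    params: pd.Series              # fixed effects, indexed by design-column name
    knots: KnotSet                 # gestational-age spline knots
    bmi_groups: tuple[str, ...]    # groups present, first is the reference level
    sigma_b2: float                # between-participant variance
    sigma_e2: float                # residual variance
    converged: bool
    n_participants: int
    n_observations: int
    method: str = "reml"

    @property
    def sd_log(self) -> float:
        return float(np.sqrt(self.sigma_b2 + self.sigma_e2))

    def design_matrix(self, ga_weeks, bmi_group) -> pd.DataFrame:
        """Fixed-effect design rows for gestational ages and BMI group(s)."""
        ga = np.atleast_1d(np.asarray(ga_weeks, dtype=float))
        if np.isscalar(bmi_group) or isinstance(bmi_group, str):
            bmi = np.full(ga.shape, bmi_group, dtype=object)
        else:
            bmi = np.asarray(bmi_group, dtype=object)
        X = {"intercept": np.ones_like(ga)}
        spline = rqs_basis(ga, self.knots)
        X["ga"] = spline[:, 0]
        for j in range(1, spline.shape[1]):
            X[f"ga_rqs{j}"] = spline[:, j]
        for g in self.bmi_groups[1:]:
            ind = (bmi == g).astype(float)
            X[f"bmi[{g}]"] = ind
            X[f"bmi[{g}]:ga"] = ind * ga
        return pd.DataFrame(X)

    def predict_mu(self, ga_weeks, bmi_group) -> np.ndarray:
        """Fixed-effect mean of transformed gain, ``mu_log(t, g)``."""
        X = self.design_matrix(ga_weeks, bmi_group)
        return X[self.params.index].to_numpy() @ self.params.to_numpy()


def _mixedlm_fit(y, X, groups):
    import statsmodels.api as sm

    model = sm.MixedLM(y, X, groups=groups)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=True, method=["lbfgs", "bfgs"])
    return res


def fit_reference_model(
    observations: pd.DataFrame,
    cohort: str,
    knot_probs=(5, 35, 65, 95),
) -> ReferenceModelFit:
    """Fit the per-cohort random-intercept model of transformed gain.

    ``observations`` is the output of :func:`gwg_observations` restricted
    to the reference subpopulation.  Gestational-age spline knots are
    placed at cohort-specific percentiles of the visit gestational ages.

    A BMI group absent from the cohort is dropped from the design (its
    main effect and interaction) with a warning rather than producing a
    singular fit.  When the data are noise-free (residual variance
    numerically zero) the mixed model is degenerate; the fixed effects are
    then recovered by least squares and both variance components reported
    as zero.
    """
    obs = observations[observations["cohort"] == cohort]
    if obs.empty:
        raise ValueError(f"no observations for cohort {cohort!r}")

    knots = percentile_knots(obs["ga_weeks"].to_numpy(), probs=knot_probs)
    present = [g for g in BMI_GROUPS if (obs["bmi_group"] == g).any()]
    missing = set(BMI_GROUPS) - set(present)
    if missing:
        warnings.warn(
            f"cohort {cohort!r}: BMI group(s) {sorted(missing)} absent; "
            "their effects are dropped from the design"
        )

    shell = ReferenceModelFit(
        cohort=cohort, params=pd.Series(dtype=float), knots=knots,
        bmi_groups=tuple(present), sigma_b2=0.0, sigma_e2=0.0,
        converged=False, n_participants=obs["participant_id"].nunique(),
        n_observations=len(obs),
    )
    X = shell.design_matrix(obs["ga_weeks"].to_numpy(), obs["bmi_group"].to_numpy())
    y = obs["y"].to_numpy()

    # noise-free degenerate path: OLS reproduces the curve, variances ~ 0
    beta_ols, *_ = np.linalg.lstsq(X.to_numpy(), y, rcond=None)
    resid = y - X.to_numpy() @ beta_ols
    if float(np.mean(resid**2)) < 1e-16:
        shell.params = pd.Series(beta_ols, index=X.columns)
        shell.converged = True
        shell.method = "ols-degenerate"
        return shell

    res = _mixedlm_fit(y, X, groups=obs["participant_id"].to_numpy())
    converged = bool(getattr(res, "converged", True))
    if not converged:
        raise RuntimeError(
            f"mixed model for cohort {cohort!r} failed to converge "
            f"(n={len(obs)}); inspect the data or knot placement"
        )
    shell.params = pd.Series(res.fe_params, index=X.columns)
    shell.sigma_b2 = float(np.asarray(res.cov_re)[0, 0])
    shell.sigma_e2 = float(res.scale)
    shell.converged = True
    return shell


def chart_from_model(
    fit: ReferenceModelFit,
    ga_grid=None,
    bmi_groups=None,
) -> pd.DataFrame:
    """Tabulate the reference chart from a converged fit.

    One row per (cohort, BMI group, integer gestational week) with the
    transformed-scale mean and SD and back-transformed percentiles in kg.
    The grid must lie within [8, 42] weeks; extrapolation outside the
    gestational support is refused.
    """
    if not fit.converged:
        raise ValueError("refusing to tabulate a chart from a non-converged fit")
    if ga_grid is None:
        ga_grid = np.arange(GA_GRID_MIN, GA_GRID_MAX + 1)
    ga_grid = np.asarray(ga_grid)
    if ga_grid.min() < GA_GRID_MIN or ga_grid.max() > GA_GRID_MAX:
        raise ValueError(
            f"chart grid must lie within [{GA_GRID_MIN}, {GA_GRID_MAX}] weeks"
        )
    if bmi_groups is None:
        bmi_groups = fit.bmi_groups
    z = stats.norm.ppf(np.asarray(CHART_PERCENTILES) / 100.0)
    rows = []
    for g in bmi_groups:
        mu = fit.predict_mu(ga_grid, g)
        for t, m in zip(ga_grid, mu):
            row = {
                "cohort": fit.cohort,
                "bmi_group": g,
                "ga_week": int(t),
                "mu_log": m,
                "sd_log": fit.sd_log,
            }
            for p, zp in zip(CHART_PERCENTILES, z):
                row[f"p{p}"] = inverse_transform(m + zp * fit.sd_log)
            rows.append(row)
    return pd.DataFrame(rows)


def build_reference_charts(
    observations: pd.DataFrame,
    cohorts=None,
    ga_grid=None,
) -> pd.DataFrame:
    """Fit per-cohort models and stack their charts into one table."""
    if cohorts is None:
        cohorts = sorted(observations["cohort"].unique())
    charts = []
    for c in cohorts:
        fit = fit_reference_model(observations, c)
        charts.append(chart_from_model(fit, ga_grid=ga_grid))
    return pd.concat(charts, ignore_index=True)


def export_chart(chart: pd.DataFrame, path, decimals: int | None = 2) -> None:
    """Write a chart as CSV; ``decimals=None`` keeps full precision."""
    out = chart.copy()
    if decimals is not None:
        pcols = [c for c in out.columns if c.startswith("p")]
        out[pcols] = out[pcols].round(decimals)
    out.to_csv(path, index=False)
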