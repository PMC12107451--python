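"""Multiple imputation by chained equations and Rubin's-rules pooling.

Missing covariates and outcomes are imputed ``m`` times (default 50) by
fully-conditional specification: each incomplete variable is regressed on
the other variables in the imputation model, parameters are drawn from
their approximate posterior, and missing entries are replaced by draws
from the resulting predictive distribution — normal linear models for
continuous variables, logistic models for binaries — cycling through the
variables for a fixed number of iterations.  Observed cells are never
altered and are identical across the m completed copies.

Downstream estimates computed on each completed copy are combined with
Rubin's rules: the pooled point estimate is the mean of the per-copy
estimates; the total variance is

    T = W + (1 + 1/m) B

with W the mean within-copy variance and B the between-copy sample
variance of the estimates.  Ratio-type estimates (risk ratios) should be
pooled on the log scale, where the normal approximation underlying the
rules is accurate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ImputationSet", "impute", "PooledEstimate", "rubin_pool"]


@dataclass
class ImputationSet:
    """m completed copies of an analysis table plus provenance."""

    tables: list[pd.DataFrame]
    variables: list[str]
    seed: int
    iterations: int

    @property
    def m(self) -> int:
        return len(self.tables)

    def write(self, directory) -> None:
        """Serialize as m indexed CSV files plus a JSON manifest."""
        import json
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for i, t in enumerate(self.tables):
            t.to_csv(directory / f"imputation_{i:03d}.csv", index=False)
        manifest = {
            "m": self.m,
            "seed": self.seed,
            "iterations": self.iterations,
            "variables": self.variables,
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _is_binary(series: pd.Series) -> bool:
    obs = series.dropna().unique()
    return len(obs) <= 2


def _encode(df: pd.DataFrame, variables) -> pd.DataFrame:
    """Numeric working copy: booleans/two-level categoricals to 0/1 floats."""
    work = pd.DataFrame(index=df.index)
    for v in variables:
        col = df[v]
        if col.dtype == bool or col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            codes, _ = pd.factorize(col, use_na_sentinel=True)
            work[v] = np.where(codes < 0, np.nan, codes).astype(float)
        else:
            work[v] = col.astype(float)
    return work


def _draw_linear(rng, X_obs, y_obs, X_mis):
    """Posterior-predictive draw from a normal linear model."""
    n, p = X_obs.shape
    beta_hat, _, rank, _ = np.linalg.lstsq(X_obs, y_obs, rcond=None)
    resid = y_obs - X_obs @ beta_hat
    dof = max(n - rank, 1)
    sigma2_hat = float(resid @ resid) / dof
    sigma2 = sigma2_hat * dof / rng.chisquare(dof)
    XtX = X_obs.T @ X_obs
    cov = sigma2 * np.linalg.pinv(XtX)
    beta = rng.multivariate_normal(beta_hat, cov, method="svd")
    mu = X_mis @ beta
    return mu + rng.normal(0.0, np.sqrt(sigma2), size=len(X_mis))


def _draw_logistic(rng, X_obs, y_obs, X_mis):
    """Bernoulli draw from a logistic model with parameter uncertainty.

    Falls back to observed-frequency draws when the likelihood cannot be
    maximized (separation, constant outcome).
    """
    import statsmodels.api as sm

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y_obs, X_obs).fit(disp=0, maxiter=50)
        if not res.mle_retvals.get("converged", False):
            raise RuntimeError("logistic sub-model did not converge")
        beta = rng.multivariate_normal(
            np.asarray(res.params), np.asarray(res.cov_params()), method="svd"
        )
        p = 1.0 / (1.0 + np.exp(-(X_mis @ beta)))
    except Exception:
        warnings.warn("logistic imputation sub-model failed; using observed-frequency draws")
        p = np.full(len(X_mis), float(np.mean(y_obs)))
    return (rng.random(len(X_mis)) < p).astype(float)


def impute(
    table: pd.DataFrame,
    variables: list[str] | None = None,
    m: int = 50,
    iterations: int = 5,
    seed: int = 0,
) -> ImputationSet:
    """Chained-equations multiple imputation of an analysis table.

    ``variables`` are the columns participating in the imputation model
    (both as targets and predictors); defaults to every column with at
    least one missing value plus every complete numeric column.  Each of
    the m copies runs an independent chain initialized by random draws
    from the observed margins.  Deterministic given ``seed``.
    """
    if variables is None:
        incomplete = [c for c in table.columns if table[c].isna().any()]
        complete_num = [
            c for c in table.columns
            if not table[c].isna().any() and pd.api.types.is_numeric_dtype(table[c])
        ]
        variables = complete_num + incomplete
    missing_vars = [v for v in variables if table[v].isna().any()]
    for v in missing_vars:
        if table[v].notna().sum() == 0:
            raise ValueError(f"variable {v!r} has no observed values to learn from")

    work0 = _encode(table, variables)
    binary = {v: _is_binary(work0[v]) for v in variables}
    rng_root = np.random.default_rng(seed)

    completed: list[pd.DataFrame] = []
    for _ in range(m):
        rng = np.random.default_rng(rng_root.integers(2**31 - 1))
        work = work0.copy()
        # initialize chains from the observed margins
        for v in missing_vars:
            mask = work[v].isna()
            obs = work.loc[~mask, v].to_numpy()
            work.loc[mask, v] = rng.choice(obs, size=int(mask.sum()), replace=True)
        for _ in range(iterations if missing_vars else 0):
            for v in missing_vars:
                mask = work0[v].isna().to_numpy()
                preds = [u for u in variables if u != v]
                X = np.column_stack(
                    [np.ones(len(work))] + [work[u].to_numpy() for u in preds]
                )
                y = work[v].to_numpy()
                if binary[v]:
                    draws = _draw_logistic(rng, X[~mask], y[~mask], X[mask])
                else:
                    draws = _draw_linear(rng, X[~mask], y[~mask], X[mask])
                col = work[v].to_numpy()
                col[mask] = draws
                work[v] = col
        out = table.copy()
        for v in missing_vars:
            mask = table[v].isna()
            filled = work.loc[mask, v]
            if binary[v] and table[v].dropna().nunique() <= 2:
                # map 0/1 codes back to the original two levels
                levels = pd.factorize(table[v], use_na_sentinel=True)[1]
                if len(levels) == 2:
                    filled = filled.map({0.0: levels[0], 1.0: levels[1]})
                elif len(levels) == 1:
                    filled = filled.map({0.0: levels[0], 1.0: levels[0]})
            out.loc[mask, v] = filled
            out[v] = out[v].astype(table[v].dtype, errors="ignore")
        completed.append(out)
    return ImputationSet(completed, list(variables), seed, iterations)


@dataclass(frozen=True)
class PooledEstimate:
    """Rubin's-rules combination of m per-imputation estimates."""

    point: float
    within: float        # W: mean within-imputation variance
    between: float       # B: between-imputation sample variance
    total: float         # T = W + (1 + 1/m) B
    m: int

    @property
    def se(self) -> float:
        return float(np.sqrt(self.total))

    @property
    def df(self) -> float:
        """Rubin small-sample degrees of freedom (inf when B = 0)."""
        if self.between == 0:
            return np.inf
        r = (1 + 1 / self.m) * self.between / self.within if self.within > 0 else np.inf
        return (self.m - 1) * (1 + 1 / r) ** 2 if np.isfinite(r) else float(self.m - 1)

    def ci(self, level: float = 0.95, small_sample: bool = False):
        alpha = 1 - level
        if small_sample and np.isfinite(self.df):
            q = stats.t.ppf(1 - alpha / 2, self.df)
        else:
            q = stats.norm.ppf(1 - alpha / 2)
        return (self.point - q * self.se, self.point + q * self.se)


def rubin_pool(estimates, variances) -> PooledEstimate:
    """Pool per-imputation estimates and variances by Rubin's rules."""
    est = np.asarray(estimates, dtype=float)
    var = np.asarray(variances, dtype=float)
    if est.shape != var.shape or est.ndim != 1:
        raise ValueError("estimates and variances must be equal-length vectors")
    m = len(est)
    if m < 2:
        raise ValueError("Rubin pooling requires m >= 2 imputations")
    if np.any(var < 0):
        raise ValueError("variances must be non-negative")
    point = float(np.mean(est))
    W = float(np.mean(var))
    B = float(np.var(est, ddof=1))
    T = W + (1 + 1 / m) * B
    return PooledEstimate(point, W, B, float(T), m)
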