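"""Synthetic multi-cohort longitudinal pregnancy data.

The generator emulates the data structure of multi-site antenatal
follow-up studies in low-resource settings: several cohorts, each woman
enrolled before 25 weeks' gestation, weighed at enrolment and then at
roughly 4-6 week intervals until delivery, with a baseline table of
maternal characteristics and a delivery-outcome table.

Weight gain is generated on the transformed scale on which the reference
model operates.  For woman ``i`` at gestational age ``t_ij``:

    y_ij = mu*(t_ij) + b_i + e_ij,
    gain_ij = exp(y_ij) - 5,
    weight_ij = baseline_weight_i + gain_ij,

with ``b_i ~ N(0, sigma_b^2)`` a woman-level intercept and
``e_ij ~ N(0, sigma_e^2)`` visit noise.  ``mu*(t)`` is the true mean
curve per (cohort, BMI group), by default a gently decelerating quadratic
calibrated so the median total gain at 39 weeks is about 7 kg — a
realistic figure for the South Asian / Sub-Saharan African populations
the structure mimics.  Because generation happens on the transformed
scale, ``gain > -5`` kg holds by construction and the log-shift transform
is always invertible.

Adverse outcomes are tied to a latent standardized gain

    Z_i = (b_i + e*_i) / sqrt(sigma_b^2 + sigma_e^2)

where ``e*_i`` is the residual reserved for the woman's final visit, so
the realized weight-gain-for-gestational-age Z-score computed downstream
estimates ``Z_i`` directly.  Risks are log-linear in ``Z_i`` (or, when a
group-risk table is configured, piecewise-constant in its quartile
group).  Every generating parameter is retained in a
:class:`SyntheticTruth` so recovery tests never re-derive the truth from
the data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .splines import KnotSet, rqs_basis
from .zscores import zscore_group

__all__ = [
    "CurveSpec",
    "OutcomeParams",
    "SimulationConfig",
    "SyntheticTruth",
    "default_config",
    "generate_cohort",
    "inject_missingness",
    "engineered_flow_cohort",
]

BMI_GROUPS = ("underweight", "normal", "overweight", "obese")
BMI_RANGES = {
    "underweight": (16.0, 18.4),
    "normal": (18.5, 24.9),
    "overweight": (25.0, 29.9),
    "obese": (30.0, 38.0),
}


@dataclass(frozen=True)
class CurveSpec:
    """True mean transformed-gain curve ``mu*(t)``.

    ``kind="quadratic"``: coefs (c0, c1, c2), mu = c0 + c1 t + c2 t^2.
    ``kind="rqs"``: coefs are (intercept, then one coefficient per column
    of the restricted-quadratic-spline basis at ``knots``) — a curve that
    lies exactly inside the reference model's fixed-effect family, used
    for exact-recovery tests.
    """

    kind: str
    coefs: tuple[float, ...]
    knots: tuple[float, ...] | None = None

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        if self.kind == "quadratic":
            c0, c1, c2 = self.coefs
            return c0 + c1 * t + c2 * t**2
        if self.kind == "rqs":
            X = rqs_basis(t, KnotSet(self.knots))
            coefs = np.asarray(self.coefs)
            return coefs[0] + X @ coefs[1:]
        raise ValueError(f"unknown curve kind {self.kind!r}")

    def shifted(self, d_intercept: float = 0.0, d_slope: float = 0.0) -> "CurveSpec":
        """Curve with intercept/linear-slope offsets (BMI, cohort effects)."""
        c = list(self.coefs)
        c[0] += d_intercept
        c[1] += d_slope
        return CurveSpec(self.kind, tuple(c), self.knots)


@dataclass(frozen=True)
class OutcomeParams:
    """Risk models for delivery outcomes, all conditional on latent Z."""

    preterm_base: float = 0.12          # marginal-ish risk at Z = 0
    preterm_log_rr_per_z: float = -0.20
    stillbirth_base: float = 0.025
    stillbirth_log_rr_per_z: float = -0.10
    bw_mean_g: float = 2900.0           # mean birth weight at 39 weeks, Z = 0
    bw_ga_slope_g_per_week: float = 140.0
    bw_z_effect_g: float = 150.0
    bw_sd_g: float = 330.0
    caesarean_risk: float = 0.25
    spontaneous_labour_risk: float = 0.78
    # optional direct per-quartile-group risks, e.g. {"lbw": {"G1": .43, ...}}
    group_risks: dict = field(default_factory=dict)


@dataclass
class SimulationConfig:
    n_per_cohort: int
    cohorts: tuple[str, ...]
    bmi_group_probs: tuple[float, float, float, float]
    enrol_ga_mean: float = 13.5
    enrol_ga_sd: float = 3.5
    enrol_ga_range: tuple[float, float] = (6.0, 24.0)
    visit_gap_weeks: tuple[float, float] = (4.0, 6.0)
    curves: dict = field(default_factory=dict)  # (cohort, bmi_group) -> CurveSpec
    sigma_b: float = 0.10
    sigma_e: float = 0.08
    outcome_params: OutcomeParams = field(default_factory=OutcomeParams)
    missing_rates: dict = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_cohort <= 0:
            raise ValueError("n_per_cohort must be positive")
        probs = np.asarray(self.bmi_group_probs, dtype=float)
        if abs(probs.sum() - 1.0) > 1e-12 or np.any(probs < 0):
            raise ValueError("bmi_group_probs must be a probability vector (sum 1)")
        if self.sigma_b < 0 or self.sigma_e < 0:
            raise ValueError("variance components must be non-negative")
        lo, hi = self.enrol_ga_range
        if not (4.0 <= lo < hi < 25.0):
            raise ValueError("enrolment GA support must lie within [4, 25) weeks")
        grid = np.linspace(8.0, 42.0, 200)
        for key, curve in self.curves.items():
            mu = curve(grid)
            if np.any(np.diff(mu) < -1e-9):
                raise ValueError(f"mean curve for {key} is decreasing on [8, 42]")

    def curve_for(self, cohort: str, bmi_group: str) -> CurveSpec:
        try:
            return self.curves[(cohort, bmi_group)]
        except KeyError:
            raise KeyError(f"no curve configured for ({cohort!r}, {bmi_group!r})")


# default quadratic: ln(5) at t=0, reaches ln(12) (total gain 7 kg) at 39 weeks,
# still increasing at 42 weeks
_BASE_COEFS = (float(np.log(5.0)), 0.0302479, -0.0002)

# BMI-group offsets on the transformed scale: heavier groups gain slightly
# less relative weight, leaner slightly more, expressed as intercept/slope shifts
_BMI_OFFSETS = {
    "underweight": (0.0, 0.0012),
    "normal": (0.0, 0.0),
    "overweight": (0.01, -0.0012),
    "obese": (0.02, -0.0022),
}


def default_config(
    n_per_cohort: int = 1000,
    cohorts: tuple[str, ...] = ("C1", "C2", "C3", "C4", "C5"),
    seed: int = 0,
    sigma_b: float = 0.10,
    sigma_e: float = 0.08,
    outcome_params: OutcomeParams | None = None,
    missing_rates: dict | None = None,
) -> SimulationConfig:
    """Study-scale defaults: five cohorts, BMI mix dominated by normal and
    underweight groups, median total gain ~7 kg at 39 weeks."""
    base = CurveSpec("quadratic", _BASE_COEFS)
    curves = {}
    for i, c in enumerate(cohorts):
        cohort_shift = 0.008 * (i - (len(cohorts) - 1) / 2)  # mild between-site spread
        for g in BMI_GROUPS:
            di, ds = _BMI_OFFSETS[g]
            curves[(c, g)] = base.shifted(di + cohort_shift, ds)
    cfg = SimulationConfig(
        n_per_cohort=n_per_cohort,
        cohorts=tuple(cohorts),
        bmi_group_probs=(0.23, 0.60, 0.134, 0.036),
        curves=curves,
        sigma_b=sigma_b,
        sigma_e=sigma_e,
        outcome_params=outcome_params or OutcomeParams(),
        missing_rates=missing_rates or {},
        seed=seed,
    )
    cfg.validate()
    return cfg


@dataclass
class SyntheticTruth:
    """Generating parameters plus per-woman latents, for recovery tests."""

    config: SimulationConfig
    latents: pd.DataFrame  # participant_id, b, eps_star, z, z_group

    def to_json(self, path) -> None:
        payload = {
            "config": _config_to_jsonable(self.config),
            "latents": self.latents.to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def _config_to_jsonable(cfg: SimulationConfig) -> dict:
    d = asdict(cfg)
    d["curves"] = {
        f"{c}|{g}": {"kind": spec.kind, "coefs": list(spec.coefs),
                     "knots": list(spec.knots) if spec.knots else None}
        for (c, g), spec in cfg.curves.items()
    }
    d["missing_rates"] = dict(cfg.missing_rates)
    return d


_MAX_VISITS = 10


def generate_cohort(config: SimulationConfig):
    """Simulate (visits, baselines, outcomes, truth); deterministic per seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_per_cohort * len(config.cohorts)

    cohort = np.repeat(np.asarray(config.cohorts, dtype=object), config.n_per_cohort)
    pid = np.array([f"{c}-{i:06d}" for i, c in enumerate(cohort)], dtype=object)

    bmi_group = rng.choice(np.array(BMI_GROUPS, dtype=object), size=n,
                           p=config.bmi_group_probs)
    height_cm = np.clip(rng.normal(152.5, 5.5, n), 138.0, 176.0)
    bmi = np.empty(n)
    for g, (lo, hi) in BMI_RANGES.items():
        mask = bmi_group == g
        bmi[mask] = rng.uniform(lo, hi, int(mask.sum()))
    baseline_weight = bmi * (height_cm / 100.0) ** 2

    age = np.clip(rng.normal(25.0, 4.5, n), 15.0, 45.0)
    parous = rng.random(n) < 0.60
    prior_preterm = np.where(parous, rng.random(n) < 0.11, False)
    prior_stillbirth = np.where(parous, rng.random(n) < 0.08, False)
    education = rng.integers(0, 16, n).astype(float)
    chronic_htn = rng.random(n) < 0.02
    diabetes = rng.random(n) < 0.005

    lo, hi = config.enrol_ga_range
    a = (lo - config.enrol_ga_mean) / config.enrol_ga_sd
    b_tr = (hi - config.enrol_ga_mean) / config.enrol_ga_sd
    enrol_ga = stats.truncnorm.rvs(
        a, b_tr, loc=config.enrol_ga_mean, scale=config.enrol_ga_sd,
        size=n, random_state=rng,
    )

    b_i = rng.normal(0.0, config.sigma_b, n) if config.sigma_b > 0 else np.zeros(n)
    eps_star = rng.normal(0.0, config.sigma_e, n) if config.sigma_e > 0 else np.zeros(n)
    sd_tot = np.sqrt(config.sigma_b**2 + config.sigma_e**2)
    z = (b_i + eps_star) / sd_tot if sd_tot > 0 else np.zeros(n)
    z_grp = zscore_group(z) if sd_tot > 0 else np.full(n, "G2", dtype=object)

    op = config.outcome_params

    def risk_from(base, log_rr, outcome_name):
        if outcome_name in op.group_risks:
            table = op.group_risks[outcome_name]
            return np.array([table[g] for g in z_grp])
        return np.clip(base * np.exp(log_rr * z), 0.0, 0.99)

    preterm = rng.random(n) < risk_from(op.preterm_base, op.preterm_log_rr_per_z, "preterm")
    delivery_ga = np.where(
        preterm,
        rng.uniform(28.0, 36.99, n),
        stats.truncnorm.rvs(
            (37.0 - 39.2) / 1.2, (42.0 - 39.2) / 1.2, loc=39.2, scale=1.2,
            size=n, random_state=rng,
        ),
    )
    stillbirth = rng.random(n) < risk_from(
        op.stillbirth_base, op.stillbirth_log_rr_per_z, "stillbirth"
    )

    # visit schedule: enrolment then stochastic 4-6 week gaps, truncated at delivery
    gaps = rng.uniform(*config.visit_gap_weeks, size=(n, _MAX_VISITS - 1))
    times = np.concatenate(
        [enrol_ga[:, None], enrol_ga[:, None] + np.cumsum(gaps, axis=1)], axis=1
    )
    scheduled = times <= delivery_ga[:, None]  # col 0 always True (enrol < 25 <= delivery)
    eps = rng.normal(0.0, config.sigma_e, (n, _MAX_VISITS)) if config.sigma_e > 0 else np.zeros((n, _MAX_VISITS))
    last_idx = scheduled.sum(axis=1) - 1
    eps[np.arange(n), last_idx] = eps_star  # the reserved final-visit residual

    mu = np.empty((n, _MAX_VISITS))
    for c in config.cohorts:
        for g in BMI_GROUPS:
            mask = (cohort == c) & (bmi_group == g)
            if mask.any():
                mu[mask] = config.curve_for(c, g)(times[mask])
    y = mu + b_i[:, None] + eps
    gain = np.exp(y) - 5.0
    weight = baseline_weight[:, None] + gain
    if not np.all(np.isfinite(weight[scheduled])) or np.any(weight[scheduled] <= 0):
        raise RuntimeError("simulated weights left the physiological range")

    rows = np.repeat(np.arange(n), _MAX_VISITS).reshape(n, _MAX_VISITS)[scheduled]
    visits = pd.DataFrame(
        {
            "participant_id": pid[rows],
            "cohort": cohort[rows],
            "ga_weeks": times[scheduled],
            "weight_kg": weight[scheduled],
        }
    )

    baselines = pd.DataFrame(
        {
            "participant_id": pid,
            "cohort": cohort,
            "maternal_age_years": age,
            "enrol_ga_weeks": enrol_ga,
            "height_cm": height_cm,
            "baseline_weight_kg": baseline_weight,
            "bmi_kg_m2": bmi,
            "bmi_group": bmi_group,
            "parous": parous,
            "prior_preterm": prior_preterm,
            "prior_stillbirth": prior_stillbirth,
            "education_years": education,
            "chronic_htn": chronic_htn,
            "diabetes": diabetes,
        }
    )

    # birth weight and newborn size
    bw_mean = (
        op.bw_mean_g
        + op.bw_ga_slope_g_per_week * (delivery_ga - 39.0)
        + op.bw_z_effect_g * z
    )
    birth_weight = rng.normal(bw_mean, op.bw_sd_g)
    # synthetic birth-weight-for-GA standard: the Z-marginal generating distribution
    std_mean = op.bw_mean_g + op.bw_ga_slope_g_per_week * (delivery_ga - 39.0)
    std_sd = np.sqrt(op.bw_sd_g**2 + op.bw_z_effect_g**2)
    centile = stats.norm.cdf((birth_weight - std_mean) / std_sd) * 100.0

    if "lbw" in op.group_risks:
        flag = rng.random(n) < risk_from(None, None, "lbw")
        birth_weight = np.where(
            flag,
            2500.0 - np.abs(rng.normal(300.0, 150.0, n)),
            2500.0 + np.abs(rng.normal(350.0, 200.0, n)),
        )
        centile = stats.norm.cdf((birth_weight - std_mean) / std_sd) * 100.0
    if "sga10" in op.group_risks:
        flag = rng.random(n) < risk_from(None, None, "sga10")
        centile = np.where(flag, rng.uniform(0.5, 9.99, n), rng.uniform(10.01, 99.5, n))

    outcomes = pd.DataFrame(
        {
            "participant_id": pid,
            "delivery_ga_weeks": delivery_ga,
            "birth_weight_g": birth_weight,
            "stillbirth": stillbirth,
            "newborn_centile": np.clip(centile, 1e-3, 100 - 1e-3),
            "caesarean": rng.random(n) < op.caesarean_risk,
            "spontaneous_labour": rng.random(n) < op.spontaneous_labour_risk,
            "infant_sex": np.where(rng.random(n) < 0.514, "M", "F"),
        }
    )

    truth = SyntheticTruth(
        config=config,
        latents=pd.DataFrame(
            {"participant_id": pid, "b": b_i, "eps_star": eps_star, "z": z,
             "z_group": z_grp}
        ),
    )
    return visits, baselines, outcomes, truth


def write_tables(directory, visits, baselines, outcomes, truth=None) -> None:
    """Emit the three delimited tables (and optional truth sidecar)."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    visits.to_csv(directory / "visits.csv", index=False)
    baselines.to_csv(directory / "baseline.csv", index=False)
    outcomes.to_csv(directory / "outcomes.csv", index=False)
    if truth is not None:
        truth.to_json(directory / "truth.json")


def inject_missingness(
    tables: dict,
    missing_rates: dict,
    mechanism: str = "MCAR",
    seed: int = 0,
    mar_driver: str = "maternal_age_years",
):
    """Mask entries of the simulated tables at configured rates.

    ``missing_rates`` maps ``"table.column"`` to a rate in [0, 1].
    Mechanisms: ``"MCAR"`` masks uniformly; ``"MAR"`` (missing at random
    on observables) scales each row's masking probability by a logistic
    function of the driver column (taken from the same table, or joined
    from the baseline table via participant id), renormalized so the
    marginal rate matches the target.  Returns ``(masked tables,
    originals)`` where originals maps each key to the pre-masking values
    (indexed by row) for imputation-quality checks.
    """
    if mechanism not in ("MCAR", "MAR"):
        raise ValueError(f"unknown missingness mechanism {mechanism!r}")
    rng = np.random.default_rng(seed)
    out = {k: v.copy() for k, v in tables.items()}
    originals: dict[str, pd.Series] = {}
    for key, rate in missing_rates.items():
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"rate for {key} must be in [0, 1]")
        table_name, col = key.split(".", 1)
        df = out[table_name]
        if rate == 0.0:
            continue
        if mechanism == "MCAR":
            p = np.full(len(df), rate)
        else:
            if mar_driver in df.columns:
                x = df[mar_driver].to_numpy(dtype=float)
            else:
                base = tables["baseline"].set_index("participant_id")[mar_driver]
                x = base.reindex(df["participant_id"]).to_numpy(dtype=float)
            xs = (x - np.nanmean(x)) / (np.nanstd(x) + 1e-12)
            w = 1.0 / (1.0 + np.exp(-xs))
            p = np.clip(rate * w / np.mean(w), 0.0, 1.0)
        mask = rng.random(len(df)) < p
        originals[key] = df.loc[mask, col].copy()
        df[col] = df[col].astype(object) if df[col].dtype == bool else df[col]
        df.loc[mask, col] = np.nan
    return out, originals


def engineered_flow_cohort(
    n_eligible: int = 15533,
    n_fewer_than_2: int = 1797,
    n_unknown_status: int = 247,
    n_late_baseline: int = 115,
    n_preterm: int = 1783,
    n_stillbirth: int = 393,
):
    """Deterministic dataset realizing specified selection-flow counts.

    Builds minimal visit/baseline/outcome tables in which exactly the
    requested number of pregnancies violates each selection rule (one
    rule per pregnancy, in the hierarchy's order), so the selection
    operations can be exercised against known flow arithmetic.
    """
    n = n_eligible + n_fewer_than_2
    pid = np.array([f"P{i:06d}" for i in range(n)], dtype=object)
    baselines = pd.DataFrame(
        {
            "participant_id": pid,
            "cohort": "C1",
            "baseline_weight_kg": 50.0,
            "bmi_group": "normal",
        }
    )

    # category layout among the eligible block
    i_unknown = slice(0, n_unknown_status)
    i_late = slice(n_unknown_status, n_unknown_status + n_late_baseline)
    i_pre = slice(i_late.stop, i_late.stop + n_preterm)
    i_still = slice(i_pre.stop, i_pre.stop + n_stillbirth)

    first_ga = np.full(n, 12.0)
    first_ga[i_late] = 21.0  # baseline weight measured after 20 weeks
    second_ga = first_ga + 10.0

    n_visits_first = np.where(np.arange(n) < n_eligible, 2, 1)
    visits = pd.DataFrame(
        {
            "participant_id": np.concatenate([pid, pid[: n_eligible]]),
            "cohort": "C1",
            "ga_weeks": np.concatenate([first_ga, second_ga[:n_eligible]]),
            "weight_kg": np.concatenate(
                [np.full(n, 52.0), np.full(n_eligible, 55.0)]
            ),
        }
    )
    del n_visits_first

    delivery = np.full(n, 39.0)
    delivery[i_pre] = 34.0
    stillbirth = np.zeros(n, dtype=object)
    stillbirth[:] = False
    stillbirth[i_unknown] = np.nan  # unknown neonatal vital status
    stillbirth[i_still] = True
    outcomes = pd.DataFrame(
        {
            "participant_id": pid,
            "delivery_ga_weeks": delivery,
            "birth_weight_g": 2800.0,
            "stillbirth": stillbirth,
            "newborn_centile": 50.0,
            "caesarean": False,
            "spontaneous_labour": True,
            "infant_sex": "F",
        }
    )
    return visits, baselines, outcomes
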