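"""Eligibility, visit-validity and reference-subpopulation selection.

Three nested selections structure the analysis:

1. *Visit validity.*  A weight measurement is implausible when the change
   from baseline is more extreme than -4 kg or +19 kg (roughly the 1st
   and 99th percentiles of observed changes in multi-cohort antenatal
   data).  Exactly -4 or +19 is still valid — "more extreme than" is a
   strict exceedance.  Only the visit is invalidated, not the
   participant.

2. *Study population.*  Pregnancies with at least two valid weight
   measurements, a known birth outcome (non-missing delivery gestational
   age), known neonatal vital status (non-missing stillbirth flag),
   singleton gestation, and delivery at <= 42 weeks; the first pregnancy
   per participant when several are recorded.

3. *Reference subpopulation* (used to fit the growth charts): excludes,
   hierarchically in this order so each pregnancy is counted once,
   (a) first valid weight measured after 20 weeks, (b) preterm delivery
   (< 37 weeks), (c) stillbirth.

Each selection returns the surviving participant ids together with a
flow report (counts per rule) that can be rendered as plain text or JSON.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

__all__ = [
    "validate_visits",
    "select_study_population",
    "select_reference_subpopulation",
    "flow_report_text",
]

MIN_VALID_CHANGE_KG = -4.0
MAX_VALID_CHANGE_KG = 19.0
REFERENCE_BASELINE_GA_MAX = 20.0
TERM_WEEKS = 37.0
MAX_DELIVERY_WEEKS = 42.0


def validate_visits(visits: pd.DataFrame, baselines: pd.DataFrame) -> pd.DataFrame:
    """Flag visits whose weight change from baseline is implausible.

    Returns a copy of ``visits`` with a boolean ``valid`` column: invalid
    iff (weight - baseline weight) < -4 kg or > +19 kg, boundaries
    inclusive-valid.  Visits that do not join to a baseline are an error.
    """
    base = baselines.set_index("participant_id")["baseline_weight_kg"]
    orphans = set(visits["participant_id"]) - set(base.index)
    if orphans:
        shown = sorted(orphans)[:10]
        raise ValueError(
            f"{len(orphans)} visit participant id(s) have no baseline row: {shown}"
        )
    out = visits.copy()
    change = out["weight_kg"].to_numpy() - base.reindex(out["participant_id"]).to_numpy()
    out["valid"] = (change >= MIN_VALID_CHANGE_KG) & (change <= MAX_VALID_CHANGE_KG)
    return out


def select_study_population(
    visits: pd.DataFrame,
    baselines: pd.DataFrame,
    outcomes: pd.DataFrame,
) -> tuple[pd.Index, dict]:
    """Apply the study eligibility rules; returns (eligible ids, flow report).

    ``visits`` must already carry validity flags.  Rules are applied
    sequentially, so the report counts each exclusion against the first
    rule a pregnancy fails:

    - fewer than two valid weight measurements;
    - unknown birth outcome (missing delivery gestational age) or unknown
      neonatal vital status (missing stillbirth flag) or multiple
      gestation (``multiple_gestation`` column, when present);
    - delivery after 42 weeks;
    - not the first recorded pregnancy (``pregnancy_index`` column, when
      present).
    """
    if "valid" in visits.columns:
        valid_counts = visits[visits["valid"]].groupby("participant_id").size()
    else:
        valid_counts = visits.groupby("participant_id").size()

    ids = pd.Index(baselines["participant_id"].unique())
    report: dict = {"initial": int(len(ids))}

    if "pregnancy_index" in baselines.columns:
        first = baselines.sort_values("pregnancy_index").drop_duplicates("participant_id")
        keep = pd.Index(first["participant_id"])
        report["later_pregnancy"] = int(len(ids) - len(keep))
        ids = ids.intersection(keep)

    keep = ids[valid_counts.reindex(ids).fillna(0).to_numpy() >= 2]
    report["fewer_than_2_valid_weights"] = int(len(ids) - len(keep))
    ids = keep

    oc = outcomes.set_index("participant_id").reindex(ids)
    known = oc["delivery_ga_weeks"].notna() & oc["stillbirth"].notna()
    if "multiple_gestation" in oc.columns:
        known &= ~oc["multiple_gestation"].fillna(False).astype(bool)
    report["unknown_outcome_or_multiple"] = int((~known).sum())
    ids = ids[known.to_numpy()]

    oc = oc.loc[ids]
    in_range = oc["delivery_ga_weeks"] <= MAX_DELIVERY_WEEKS
    report["delivery_after_42_weeks"] = int((~in_range).sum())
    ids = ids[in_range.to_numpy()]

    report["study_population"] = int(len(ids))
    # exclusion fraction among pregnancies that met the 2-valid-weights rule
    denom = report["initial"] - report.get("later_pregnancy", 0) - report["fewer_than_2_valid_weights"]
    report["excluded_fraction_pct"] = round(
        100.0 * (denom - report["study_population"]) / denom, 1
    ) if denom else 0.0
    return ids, report


def select_reference_subpopulation(
    study_ids: pd.Index,
    visits: pd.DataFrame,
    outcomes: pd.DataFrame,
) -> tuple[pd.Index, dict]:
    """Select the chart-fitting subset from the study population.

    Excludes, hierarchically (each pregnancy attributed to the first rule
    it fails): baseline (first valid) weight measured after 20 weeks;
    preterm delivery (< 37 weeks); stillbirth.
    """
    v = visits[visits["valid"]] if "valid" in visits.columns else visits
    first_ga = v.groupby("participant_id")["ga_weeks"].min()
    oc = outcomes.set_index("participant_id").reindex(study_ids)

    late = first_ga.reindex(study_ids).to_numpy() > REFERENCE_BASELINE_GA_MAX
    preterm = (oc["delivery_ga_weeks"].to_numpy() < TERM_WEEKS) & ~late
    still = (oc["stillbirth"] == True).to_numpy(dtype=bool) & ~late & ~preterm  # noqa: E712 (column may be object-typed with NaN)

    report = {
        "study_population": int(len(study_ids)),
        "baseline_weight_after_20_weeks": int(np.sum(late)),
        "preterm_delivery": int(np.sum(preterm)),
        "stillbirth": int(np.sum(still)),
    }
    keep = ~(late | preterm | still)
    ids = study_ids[keep]
    report["reference_subpopulation"] = int(len(ids))
    return ids, report


def flow_report_text(report: dict) -> str:
    """Render a flow report dict as an aligned plain-text block."""
    width = max(len(k) for k in report)
    lines = [f"{k.replace('_', ' '):<{width + 2}}{v}" for k, v in report.items()]
    return "\n".join(lines)


def flow_report_json(report: dict) -> str:
    return json.dumps(report, indent=2)
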