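import numpy as np
import pandas as pd
import pytest

import gwgref
from gwgref.outcomes import build_analysis_table


@pytest.fixture(scope="session")
def study_sim():
    """Study-scale simulated multi-cohort dataset (5 cohorts x 800 women).

    Shared across tests that need a realistic cohort; tests must not
    mutate the returned frames.
    """
    cfg = gwgref.default_config(n_per_cohort=800, seed=0)
    visits, baselines, outcomes, truth = gwgref.generate_cohort(cfg)
    return {
        "config": cfg,
        "visits": visits,
        "baselines": baselines,
        "outcomes": outcomes,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def study_pipeline(study_sim):
    """Validated visits, selected populations and fitted charts."""
    v = gwgref.validate_visits(study_sim["visits"], study_sim["baselines"])
    study_ids, flow1 = gwgref.select_study_population(
        v, study_sim["baselines"], study_sim["outcomes"]
    )
    ref_ids, flow2 = gwgref.select_reference_subpopulation(
        study_ids, v, study_sim["outcomes"]
    )
    obs = gwgref.gwg_observations(
        v[v["participant_id"].isin(ref_ids)], study_sim["baselines"]
    )
    charts = gwgref.build_reference_charts(obs)
    table = build_analysis_table(
        v, study_sim["baselines"], study_sim["outcomes"], charts, study_ids
    )
    return {
        "visits": v,
        "study_ids": study_ids,
        "ref_ids": ref_ids,
        "flow": {**flow1, **flow2},
        "observations": obs,
        "charts": charts,
        "analysis_table": table,
        **study_sim,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(0)
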