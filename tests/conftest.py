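import numpy as np
import pandas as pd
import pytest

from malnupred import synthetic_data as syn


@pytest.fixture(scope="session")
def lms_ref():
    return syn.synthetic_lms_reference()


@pytest.fixture(scope="session")
def small_region():
    return syn.generate_geography(3, 3, seed=1)


@pytest.fixture(scope="session")
def small_scenario():
    return syn.ScenarioConfig(
        seed=7,
        strata_per_county=2,
        clusters_per_stratum=4,
        children_per_cluster=15,
        survey_months=("2016-06", "2017-02", "2017-10"),
    )


@pytest.fixture(scope="session")
def small_study(small_region, small_scenario, lms_ref):
    """Region + predictors + surface + surveys, generated once per session."""
    predictors_long = syn.generate_predictors(small_region, small_scenario)
    surface = syn.build_true_surface(small_region, predictors_long, small_scenario)
    children, calendar = syn.generate_surveys(
        small_region, surface, small_scenario, lms_ref
    )
    return {
        "region": small_region,
        "scenario": small_scenario,
        "predictors": predictors_long,
        "surface": surface,
        "children": children,
        "calendar": calendar,
    }
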