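"""Shared fixtures: small seeded datasets from the synthetic generators."""

import numpy as np
import pandas as pd
import pytest

from symbiofit import presets
from symbiofit.synthetic_data import (
    BioassayDesign,
    LifeTableDesign,
    RadrDesign,
    gen_bioassay,
    gen_lifetable,
    gen_ratings,
)


@pytest.fixture
def basic_bioassay_design():
    return BioassayDesign(
        strain_name="LF",
        hadv2_status="negative",
        true_log10_lc50=0.0,
        probit_slope=2.0,
        doses=tuple(10.0**x for x in np.linspace(-1.25, 1.25, 6)),
        n_per_dose=72,
    )


@pytest.fixture
def bioassay_table(basic_bioassay_design):
    return gen_bioassay(basic_bioassay_design, seed=12345)


@pytest.fixture
def degenerate_lifetable():
    """All rates one, constant fecundity 100, half female: R0 = 50 exactly."""
    n = 20
    female = np.array([1, 0] * (n // 2))
    return pd.DataFrame(
        {
            "strain": "LF",
            "hadv2": "negative",
            "replicate": 1,
            "individual_id": np.arange(1, n + 1),
            "surv_l1_l5": 1,
            "surv_l5_pupa": 1,
            "larval_duration": 16.0,
            "pupal_weight": 320.0,
            "female": female,
            "female_pupal_duration": np.where(female == 1, 11.0, np.nan),
            "male_pupal_duration": np.where(female == 0, 12.0, np.nan),
            "emerged": 1,
            "copulated": 1,
            "female_longevity": np.where(female == 1, 10.0, np.nan),
            "male_longevity": np.where(female == 0, 9.0, np.nan),
            "fecundity": np.where(female == 1, 100.0, np.nan),
            "hatch_rate": np.where(female == 1, 1.0, np.nan),
        }
    )


@pytest.fixture
def field_ratings():
    return gen_ratings(presets.FIELD_RADR_DESIGN, seed=2015)
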