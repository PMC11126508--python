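import numpy as np
import pandas as pd
import pytest

from growthmsm.growth import GrowthReference
from growthmsm.survey import SurveyDesign


def make_panel(rows, extra_cols=None):
    """Build a small panel frame from (child_id, age, state, weight) tuples."""
    df = pd.DataFrame(rows, columns=["child_id", "age_years", "state", "weight"])
    df["stratum"] = "s0"
    df["psu"] = "c" + (df["child_id"] % 2).astype(str)
    if extra_cols:
        for k, v in extra_cols.items():
            df[k] = v
    return df


@pytest.fixture
def flat_reference():
    """Two-knot-per-sex LMS table with constant parameters (easy oracles)."""
    rows = []
    for sex in ("M", "F"):
        for age in (24.0, 216.0):
            rows.append((sex, age, 1.0, 16.0, 0.10))
    return GrowthReference(pd.DataFrame(
        rows, columns=["sex", "age_months", "L", "M", "S"]))


@pytest.fixture
def small_design():
    """1 stratum-pair design: 3 strata x 4 clusters, 60 children."""
    rng = np.random.default_rng(42)
    rows = []
    for i in range(60):
        h = i % 3
        rows.append((i, f"s{h}", f"s{h}_c{rng.integers(0, 4)}", 1.0))
    df = pd.DataFrame(rows, columns=["child_id", "stratum", "psu", "weight"])
    return SurveyDesign(df)
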