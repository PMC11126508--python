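"""Long-format interval-censored panel data: schema, validation, I/O.

A panel is a pandas DataFrame with one row per child per measurement
occasion.  Core columns: ``child_id``, ``age_years`` (exact decimal age at
measurement), ``state`` (ordinal 1-4), ``weight`` (survey design weight),
``stratum`` and ``psu`` (first-stage cluster).  Optional columns: ``wave``
(nominal wave index or age), ``bmi``, ``zscore``, ``multiple_birth`` and
any number of coded covariate columns.  States are observed only at the
recorded ages; transition times in between are censored.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import FormatError
from .structure import STATE_CODES

CORE_COLUMNS = ["child_id", "age_years", "state", "weight", "stratum", "psu"]


def validate_panel(df: pd.DataFrame, require_two_obs: bool = True) -> pd.DataFrame:
    """Validate panel invariants; return the frame sorted by child then age.

    Checks: required columns present, valid state codes, positive weights,
    strictly increasing ages within child and (optionally) at least two
    observations per child.
    """
    missing = [c for c in CORE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"panel missing required columns: {missing}")
    out = df.sort_values(["child_id", "age_years"], kind="stable").reset_index(drop=True)
    state = out["state"].to_numpy()
    if not np.isin(state, STATE_CODES).all():
        bad = sorted(set(state) - set(STATE_CODES))
        raise FormatError(f"invalid state codes in panel: {bad}")
    w = out["weight"].to_numpy(dtype=float)
    if np.any(~np.isfinite(w)) or np.any(w <= 0):
        raise FormatError("panel weights must be positive and finite")
    grp = out.groupby("child_id", sort=False)
    if (grp["age_years"].diff().dropna() <= 0).any():
        raise FormatError("ages must be strictly increasing within each child")
    if require_two_obs and (grp.size() < 2).any():
        n1 = int((grp.size() < 2).sum())
        raise FormatError(
            f"{n1} children have fewer than two observations; "
            "filter them before building a panel"
        )
    return out


def read_panel(path_or_buf, require_two_obs: bool = True) -> pd.DataFrame:
    """Read a long-format panel CSV and validate it."""
    df = pd.read_csv(path_or_buf)
    return validate_panel(df, require_two_obs=require_two_obs)


def write_panel(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def drop_single_observation_children(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Remove children with fewer than two observations.

    Returns the filtered frame and the number of children removed.
    """
    sizes = df.groupby("child_id")["child_id"].transform("size")
    keep = sizes >= 2
    n_dropped = df.loc[~keep, "child_id"].nunique()
    return df.loc[keep].reset_index(drop=True), int(n_dropped)


def baseline_rows(df: pd.DataFrame) -> pd.DataFrame:
    """First observation per child (the earliest age)."""
    out = df.sort_values(["child_id", "age_years"], kind="stable")
    return out.groupby("child_id", sort=False).head(1).reset_index(drop=True)
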