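"""LMS growth-reference z-scores and weight-status classification.

BMI is age- and sex-standardised with the LMS (lambda-mu-sigma) method: a
reference table supplies, for each sex and age, a Box-Cox power L, a median
M (kg/m^2) and a coefficient of variation S, and the z-score of a measured
BMI ``y`` is ``((y/M)**L - 1) / (L*S)`` (or ``log(y/M)/S`` when L = 0).
Children are then classified into four weight states either by the UK
population-monitoring centile cut-offs on the British 1990 (UK90) reference
(2nd / 85th / 95th centiles) or by the WHO z-score cut-offs, which differ
for children up to 60 months and from 61 months of age.

The package does not ship the licensed UK90 tables; :func:`synthetic_growth_reference`
builds a synthetic stand-in with realistic shapes for testing, and any
user-supplied table in the same CSV layout is accepted at run time.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import FormatError, InvalidMeasurementError, OutOfRangeError

__all__ = [
    "Sex",
    "WeightState",
    "GrowthReference",
    "lms_zscore",
    "lms_bmi",
    "classify_uk90",
    "classify_who",
    "read_growth_reference",
    "synthetic_growth_reference",
    "UK90_CENTILE_BOUNDS",
    "DEFAULT_IMPLAUSIBLE_Z",
]

#: |z| above this is flagged as an implausible record (configurable in callers).
DEFAULT_IMPLAUSIBLE_Z = 5.0

#: Centiles defining underweight / overweight / obesity under UK population
#: monitoring; the z-boundaries are derived from the normal quantile function,
#: never hard-coded decimals.
UK90_CENTILE_BOUNDS = (0.02, 0.85, 0.95)

_Z_UNDER, _Z_OVER, _Z_OBESE = norm.ppf(UK90_CENTILE_BOUNDS)


class Sex(str, enum.Enum):
    male = "M"
    female = "F"


class WeightState(enum.IntEnum):
    """Ordinal weight-status codes; adjacent categories differ by 1."""

    underweight = 1
    healthy = 2
    overweight = 3
    obesity = 4


_REQUIRED_COLS = ["sex", "age_months", "L", "M", "S"]


@dataclass(frozen=True)
class GrowthReference:
    """LMS reference: one row per (sex, age in months), ages strictly increasing."""

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        missing = [c for c in _REQUIRED_COLS if c not in t.columns]
        if missing:
            raise FormatError(f"growth reference missing columns: {missing}")
        sexes = set(t["sex"].unique())
        if sexes != {"M", "F"}:
            raise FormatError(f"growth reference must contain both sexes, got {sexes}")
        for sex, grp in t.groupby("sex"):
            ages = grp["age_months"].to_numpy(dtype=float)
            if np.any(np.diff(ages) <= 0):
                raise FormatError(f"ages not strictly increasing for sex={sex}")
            for col, name in (("M", "M"), ("S", "S")):
                bad = grp.index[grp[col] <= 0]
                if len(bad):
                    raise FormatError(
                        f"non-positive {name} in growth reference at row {bad[0]} (sex={sex})"
                    )

    def age_range(self, sex) -> tuple[float, float]:
        sub = self.table[self.table["sex"] == _sex_code(sex)]
        ages = sub["age_months"].to_numpy(dtype=float)
        return float(ages[0]), float(ages[-1])

    def lms_at(self, age_months: float, sex) -> tuple[float, float, float]:
        """Linearly interpolate (L, M, S) at an exact age for one sex."""
        sub = self.table[self.table["sex"] == _sex_code(sex)]
        ages = sub["age_months"].to_numpy(dtype=float)
        if age_months < ages[0] or age_months > ages[-1]:
            raise OutOfRangeError(
                f"age {age_months} months outside reference range "
                f"[{ages[0]}, {ages[-1]}] for sex={_sex_code(sex)}"
            )
        out = tuple(
            float(np.interp(age_months, ages, sub[c].to_numpy(dtype=float)))
            for c in ("L", "M", "S")
        )
        return out


def _sex_code(sex) -> str:
    if isinstance(sex, Sex):
        return sex.value
    s = str(sex).strip().upper()
    if s in ("M", "MALE", "BOY", "1"):
        return "M"
    if s in ("F", "FEMALE", "GIRL", "2", "0"):
        return "F"
    raise FormatError(f"unrecognised sex code: {sex!r}")


def lms_zscore(bmi: float, age_months: float, sex, ref: GrowthReference) -> float:
    """BMI z-score via the LMS transform at an exact age.

    Uses ``((bmi/M)**L - 1)/(L*S)`` for L != 0 and ``log(bmi/M)/S`` for L = 0,
    with L, M, S linearly interpolated in age within the given sex.
    """
    if not np.isfinite(bmi) or bmi <= 0:
        raise InvalidMeasurementError(f"BMI must be positive and finite, got {bmi}")
    L, M, S = ref.lms_at(age_months, sex)
    if L == 0.0:
        return float(np.log(bmi / M) / S)
    return float(((bmi / M) ** L - 1.0) / (L * S))


def lms_bmi(z: float, age_months: float, sex, ref: GrowthReference) -> float:
    """Invert the LMS transform: the BMI whose z-score is ``z`` at this age/sex."""
    if not np.isfinite(z):
        raise InvalidMeasurementError("z must be finite")
    L, M, S = ref.lms_at(age_months, sex)
    if L == 0.0:
        return float(M * np.exp(S * z))
    return float(M * (1.0 + L * S * z) ** (1.0 / L))


def classify_uk90(z: float) -> WeightState:
    """Classify a BMI z-score under UK population-monitoring centile cut-offs.

    Centile <= 2nd: underweight; < 85th: healthy weight; < 95th: overweight;
    >= 95th: obesity.  Boundaries are the standard normal quantiles at 0.02,
    0.85 and 0.95, with boundary inclusion as stated.
    """
    if not np.isfinite(z):
        raise InvalidMeasurementError(f"z-score must be finite, got {z}")
    if z <= _Z_UNDER:
        return WeightState.underweight
    if z < _Z_OVER:
        return WeightState.healthy
    if z < _Z_OBESE:
        return WeightState.overweight
    return WeightState.obesity


def classify_who(z: float, age_months: float) -> WeightState:
    """Classify a BMI z-score under WHO cut-offs, which change at 60 months.

    Up to and including 60 months: thinness z < -2, healthy -2 <= z <= 2,
    overweight 2 < z <= 3, obesity z > 3.  From 61 months: healthy up to
    z <= 1, overweight 1 < z <= 2, obesity z > 2.
    """
    if not np.isfinite(z):
        raise InvalidMeasurementError(f"z-score must be finite, got {z}")
    if age_months < 0:
        raise InvalidMeasurementError("age must be non-negative")
    if z < -2.0:
        return WeightState.underweight
    over, obese = (2.0, 3.0) if age_months <= 60 else (1.0, 2.0)
    if z <= over:
        return WeightState.healthy
    if z <= obese:
        return WeightState.overweight
    return WeightState.obesity


def read_growth_reference(path_or_buf) -> GrowthReference:
    """Read and validate an LMS reference CSV with columns sex,age_months,L,M,S."""
    df = pd.read_csv(path_or_buf)
    missing = [c for c in _REQUIRED_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"growth reference CSV missing columns: {missing}")
    df = df[_REQUIRED_COLS].copy()
    df["sex"] = [_sex_code(s) for s in df["sex"]]
    df = df.sort_values(["sex", "age_months"], kind="stable").reset_index(drop=True)
    return GrowthReference(df)


def write_growth_reference(ref: GrowthReference, path) -> None:
    ref.table.to_csv(path, index=False)


def synthetic_growth_reference(age_min_months: int = 24,
                               age_max_months: int = 216,
                               step_months: int = 1) -> GrowthReference:
    """A synthetic LMS table with realistic childhood BMI shapes (not UK90).

    Median BMI dips to its adiposity-rebound minimum around age 5-6 and
    rises through adolescence; S grows modestly with age; L is negative
    (right-skewed BMI).  Values are smooth inventions for testing and demos,
    not a licensed reference.
    """
    ages = np.arange(age_min_months, age_max_months + 1, step_months, dtype=float)
    years = ages / 12.0
    rows = []
    for sex, m_shift, s_scale in (("M", 0.0, 1.00), ("F", -0.15, 1.05)):
        # rebound dip near 5.5y plus a logistic adolescent rise
        M = (15.8 + m_shift
             + 0.55 * ((years - 5.5) / 4.0) ** 2 * (years < 5.5)
             + 5.6 / (1.0 + np.exp(-(years - 12.5) / 2.2)))
        S = s_scale * (0.085 + 0.04 / (1.0 + np.exp(-(years - 9.0) / 2.0)))
        L = -1.4 - 0.4 / (1.0 + np.exp(-(years - 8.0) / 3.0))
        for a, l, m, s in zip(ages, L, M, S):
            rows.append((sex, a, l, m, s))
    df = pd.DataFrame(rows, columns=_REQUIRED_COLS)
    return GrowthReference(df)
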