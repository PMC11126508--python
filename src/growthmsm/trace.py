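"""Markov cohort traces, validation-cohort expansion and model comparison.

A Markov trace projects a cohort's state-occupancy distribution forward in
annual cycles: occupancy[k+1] = occupancy[k] @ P_annual(age_k), where the
annual matrix comes from a piecewise schedule of age bands.  Validation
compares the traced (predicted) prevalence with the observed survey-weighted
prevalence at each wave, and scenario comparison ranks alternative
schedules by mean absolute prevalence error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ScheduleError
from .structure import N_STATES, STATE_NAMES

logger = logging.getLogger(__name__)

__all__ = [
    "MatrixSchedule",
    "MarkovTrace",
    "markov_trace",
    "expand_validation_cohort",
    "observed_prevalence",
    "predicted_vs_observed",
    "compare_scenarios",
]


class MatrixSchedule:
    """Contiguous age bands, each with an annual transition matrix.

    ``entries`` is a list of (age_from, age_to, P_annual); bands must be
    contiguous and non-overlapping and every matrix row-stochastic within
    1e-8.
    """

    def __init__(self, entries):
        entries = sorted(((float(a0), float(a1), np.asarray(P, dtype=float))
                          for a0, a1, P in entries), key=lambda e: e[0])
        if not entries:
            raise ScheduleError("schedule is empty")
        for a0, a1, P in entries:
            if a1 <= a0:
                raise ScheduleError(f"band ({a0}, {a1}) is empty")
            if P.shape != (N_STATES, N_STATES):
                raise ScheduleError("annual matrices must be 4x4")
            if np.any(P < -1e-12) or np.any(np.abs(P.sum(axis=1) - 1) > 1e-8):
                raise ScheduleError(
                    f"matrix for band ({a0}, {a1}) is not row-stochastic")
        for (_, a1, _), (b0, _, _) in zip(entries, entries[1:]):
            if abs(a1 - b0) > 1e-12:
                raise ScheduleError(f"gap or overlap between bands at age {a1}")
        self.entries = entries

    @property
    def age_min(self) -> float:
        return self.entries[0][0]

    @property
    def age_max(self) -> float:
        return self.entries[-1][1]

    def matrix_at(self, age: float, extend: bool = True) -> np.ndarray:
        """Annual matrix for the cycle starting at ``age``.

        Ages at or beyond the last band's end reuse the last band's matrix
        when ``extend`` is true (logged), mirroring projection one year
        past the final fitted band.
        """
        for a0, a1, P in self.entries:
            if a0 <= age < a1:
                return P
        if extend and age >= self.age_max:
            logger.info("extending final band matrix to cover age %.2f", age)
            return self.entries[-1][2]
        raise ScheduleError(f"no band covers age {age}")


@dataclass
class MarkovTrace:
    """State occupancy by age: occupancy[k] is the distribution at ages[k]."""

    ages: np.ndarray
    occupancy: np.ndarray  # (cycles+1, 4)

    def to_frame(self) -> pd.DataFrame:
        cols = ["p_underweight", "p_healthy", "p_overweight", "p_obesity"]
        df = pd.DataFrame(self.occupancy, columns=cols)
        df.insert(0, "age", self.ages)
        return df

    def at_age(self, age: float) -> np.ndarray:
        i = int(np.argmin(np.abs(self.ages - age)))
        if abs(self.ages[i] - age) > 1e-9:
            raise ScheduleError(f"trace has no cycle at age {age}")
        return self.occupancy[i]


def markov_trace(baseline, schedule: MatrixSchedule, start_age: float,
                 end_age: float) -> MarkovTrace:
    """Run annual cycles from ``start_age`` to ``end_age``.

    ``baseline`` is the 4-vector of state proportions at ``start_age`` (must
    sum to 1).  One cycle per year; the band containing the cycle's start
    age supplies the matrix, with the final band extended if the horizon
    runs past it.
    """
    v = np.asarray(baseline, dtype=float)
    if v.shape != (N_STATES,) or abs(v.sum() - 1.0) > 1e-8 or np.any(v < 0):
        raise ScheduleError("baseline must be 4 non-negative proportions summing to 1")
    n_cycles = int(round(end_age - start_age))
    if n_cycles < 0:
        raise ScheduleError("end_age must not precede start_age")
    occ = np.empty((n_cycles + 1, N_STATES))
    occ[0] = v
    for k in range(n_cycles):
        P = schedule.matrix_at(start_age + k)
        occ[k + 1] = occ[k] @ P
    ages = start_age + np.arange(n_cycles + 1, dtype=float)
    return MarkovTrace(ages=ages, occupancy=occ)


def expand_validation_cohort(panel_baseline: pd.DataFrame, factor: int):
    """Weight-proportional replication of the validation cohort.

    Each child is replicated round(factor * w_i / mean(w)) times (half away
    from zero), so the expanded head-count distribution matches the
    weighted distribution.  Returns (per-child replication counts, expanded
    baseline state distribution, total expanded count).
    """
    if factor < 1:
        raise ScheduleError("expansion factor must be >= 1")
    w = panel_baseline["weight"].to_numpy(dtype=float)
    mult = factor * w / w.mean()
    counts = np.floor(mult + 0.5).astype(int)  # round half away from zero (w > 0)
    states = panel_baseline["state"].to_numpy()
    dist = np.array([counts[states == s].sum() for s in (1, 2, 3, 4)], dtype=float)
    total = int(counts.sum())
    return (pd.Series(counts, index=panel_baseline["child_id"].to_numpy()),
            dist / dist.sum(), total)


def observed_prevalence(panel: pd.DataFrame, wave_col: str = "wave",
                        weight_col: str = "weight") -> pd.DataFrame:
    """Survey-weighted state prevalence per wave (rows sum to 1)."""
    out = []
    for wv, grp in panel.groupby(wave_col):
        w = grp[weight_col].to_numpy(dtype=float)
        tot = w.sum()
        shares = [w[grp["state"].to_numpy() == s].sum() / tot for s in (1, 2, 3, 4)]
        out.append((wv, float(grp["age_years"].mean()), *shares))
    cols = ["wave", "mean_age", "p_underweight", "p_healthy",
            "p_overweight", "p_obesity"]
    return pd.DataFrame(out, columns=cols).sort_values("wave").reset_index(drop=True)


_PCOLS = ["p_underweight", "p_healthy", "p_overweight", "p_obesity"]


def predicted_vs_observed(trace: MarkovTrace, observed: pd.DataFrame,
                          age_col: str = "mean_age") -> pd.DataFrame:
    """Predicted/observed prevalence ratios per state and wave.

    The trace is read at the integer cycle age nearest each wave's mean
    age.  A zero observed prevalence yields NaN (undefined), never inf.
    """
    rows = []
    for _, obs in observed.iterrows():
        age = float(round(obs[age_col]))
        pred = trace.at_age(age)
        for s, col in enumerate(_PCOLS):
            o = float(obs[col])
            ratio = pred[s] / o if o > 0 else np.nan
            rows.append((obs.get("wave", age), age, STATE_NAMES[s],
                         pred[s], o, ratio))
    return pd.DataFrame(rows, columns=["wave", "age", "state", "predicted",
                                       "observed", "ratio"])


def compare_scenarios(base_trace: MarkovTrace, scenario_traces: dict,
                      observed: pd.DataFrame,
                      age_col: str = "mean_age") -> pd.DataFrame:
    """Mean absolute prevalence error per model across states and waves.

    Lower is better; the returned frame is sorted best-first and includes
    the base model under the name ``base``.
    """
    traces = {"base": base_trace, **scenario_traces}
    rows = []
    for name, tr in traces.items():
        errs = []
        for _, obs in observed.iterrows():
            pred = tr.at_age(float(round(obs[age_col])))
            for s, col in enumerate(_PCOLS):
                errs.append(abs(pred[s] - float(obs[col])))
        rows.append((name, float(np.mean(errs))))
    out = pd.DataFrame(rows, columns=["model", "mean_abs_error"])
    return out.sort_values("mean_abs_error", kind="stable").reset_index(drop=True)
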