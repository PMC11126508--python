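"""Complex-survey design, JKn delete-one-cluster replicate weights, variance.

The survey design is stratified and clustered: children belong to primary
sampling units (clusters), clusters to strata, and each child carries a
design weight (inverse inclusion probability, possibly nonresponse
adjusted).  Point estimates use the base weights; variances come from JKn
jackknife replication: one replicate per cluster, where replicate (h, j)
zeroes the weights of cluster j in stratum h and rescales the other
clusters of stratum h by n_h / (n_h - 1).  For a full-sample estimate
theta_hat and replicate estimates theta_(hj), the variance estimator is

    v = sum_h (n_h - 1)/n_h * sum_{j in h} (theta_(hj) - theta_hat)^2,

and confidence intervals are normal-theory intervals on a scale suited to
the quantity (log scale for rates and hazard ratios; identity scale clipped
to [0, 1] for probabilities).  Replication is propagated through the whole
estimation pipeline -- each replicate refits the model -- rather than via
the delta method.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DesignError, FormatError, InferenceError

Z_95 = 1.959963984540054  # normal 97.5% quantile


@dataclass
class SurveyDesign:
    """Per-child design table: child_id, stratum, psu, weight (+ extras).

    Every child belongs to exactly one cluster (psu) and each cluster to
    exactly one stratum; weights are positive.  Extra columns (e.g. a
    subgroup indicator) ride along and are copied into simulated panels.
    """

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        for c in ("child_id", "stratum", "psu", "weight"):
            if c not in t.columns:
                raise DesignError(f"design table missing column {c!r}")
        w = t["weight"].to_numpy(dtype=float)
        if np.any(~np.isfinite(w)) or np.any(w <= 0):
            raise DesignError("design weights must be positive and finite")
        n_strata_per_psu = t.groupby("psu")["stratum"].nunique()
        if (n_strata_per_psu > 1).any():
            bad = n_strata_per_psu[n_strata_per_psu > 1].index[0]
            raise DesignError(f"cluster {bad!r} appears in more than one stratum")
        if t["child_id"].duplicated().any():
            raise DesignError("duplicate child_id in design table")

    @property
    def n_children(self) -> int:
        return len(self.table)

    @property
    def strata(self) -> list:
        return sorted(self.table["stratum"].unique().tolist())

    @property
    def n_clusters(self) -> int:
        return self.table["psu"].nunique()

    def cluster_counts(self) -> pd.Series:
        """Number of clusters per stratum."""
        return self.table.groupby("stratum")["psu"].nunique()


@dataclass
class ReplicateWeightSet:
    """Base weights plus one JKn replicate-weight column per cluster."""

    child_id: np.ndarray
    base_weight: np.ndarray
    replicate_weights: np.ndarray  # (n_children, R)
    replicate_meta: pd.DataFrame  # columns: stratum, psu, n_h

    @property
    def n_replicates(self) -> int:
        return self.replicate_weights.shape[1]

    def weights_for(self, child_ids) -> tuple[np.ndarray, np.ndarray]:
        """Return (base, replicate matrix) rows aligned to ``child_ids``."""
        idx = pd.Index(self.child_id).get_indexer(np.asarray(child_ids))
        if np.any(idx < 0):
            raise DesignError("child_id not present in replicate weight set")
        return self.base_weight[idx], self.replicate_weights[idx]


def jackknife_replicates(design: SurveyDesign) -> ReplicateWeightSet:
    """Construct JKn delete-one-cluster replicate weights, one per cluster.

    Requires at least two clusters in every stratum.  Within each replicate
    column, the total weight of every stratum equals its base total exactly.
    """
    t = design.table.reset_index(drop=True)
    counts = design.cluster_counts()
    singletons = counts[counts < 2]
    if len(singletons):
        raise DesignError(
            f"stratum {singletons.index[0]!r} has a single cluster; "
            "JKn needs at least two clusters per stratum"
        )
    base = t["weight"].to_numpy(dtype=float)
    strat = t["stratum"].to_numpy()
    psu = t["psu"].to_numpy()
    meta_rows = []
    cols = []
    for h in design.strata:
        in_h = strat == h
        n_h = counts[h]
        clusters = pd.unique(psu[in_h])
        factor = n_h / (n_h - 1.0)
        for j in sorted(clusters.tolist()):
            col = base.copy()
            col[in_h] *= factor
            col[in_h & (psu == j)] = 0.0
            cols.append(col)
            meta_rows.append((h, j, int(n_h)))
    rep = np.column_stack(cols)
    meta = pd.DataFrame(meta_rows, columns=["stratum", "psu", "n_h"])
    return ReplicateWeightSet(
        child_id=t["child_id"].to_numpy(),
        base_weight=base,
        replicate_weights=rep,
        replicate_meta=meta,
    )


def replicate_variance(full, reps, meta: pd.DataFrame,
                       ok: np.ndarray | None = None,
                       max_bad_fraction: float = 0.05):
    """JKn variance of an estimator from its replicate re-estimates.

    Parameters
    ----------
    full : scalar or array
        Full-sample estimate theta_hat.
    reps : array, shape (R,) or (R, ...)
        Replicate estimates, one per replicate in ``meta`` order.
    meta : DataFrame with columns stratum, n_h
        Replicate bookkeeping from :func:`jackknife_replicates`.
    ok : optional bool array, shape (R,)
        Replicates that converged.  If more than ``max_bad_fraction`` are
        bad an :class:`InferenceError` is raised; otherwise bad replicates
        are dropped and each stratum's sum is rescaled by n_used/n_ok to
        keep the stratum's contribution unbiased.

    Returns
    -------
    se : same shape as ``full``
    """
    reps = np.asarray(reps, dtype=float)
    full = np.asarray(full, dtype=float)
    R = len(meta)
    if reps.shape[0] != R:
        raise InferenceError(f"expected {R} replicate estimates, got {reps.shape[0]}")
    if ok is None:
        ok = np.ones(R, dtype=bool)
    ok = np.asarray(ok, dtype=bool)
    n_bad = int((~ok).sum())
    if n_bad > max_bad_fraction * R:
        raise InferenceError(
            f"{n_bad}/{R} replicates failed ({n_bad / R:.1%} > "
            f"{max_bad_fraction:.0%} allowed)"
        )
    dev2 = (reps - full) ** 2
    v = np.zeros(full.shape, dtype=float)
    strat = meta["stratum"].to_numpy()
    n_h_col = meta["n_h"].to_numpy(dtype=float)
    for h in pd.unique(strat):
        in_h = strat == h
        n_h = n_h_col[in_h][0]
        use = in_h & ok
        n_ok = int(use.sum())
        if n_ok == 0:
            raise InferenceError(f"all replicates failed in stratum {h!r}")
        scale = (n_h - 1.0) / n_h * (in_h.sum() / n_ok)
        v = v + scale * dev2[use].sum(axis=0)
    return np.sqrt(v)


@dataclass
class IntervalEstimate:
    """Point estimate with jackknife SE and a 95% interval on a stated scale."""

    point: float
    se: float
    ci_low: float
    ci_high: float
    scale: str = "identity"


def interval_estimate(point: float, se: float, scale: str = "identity") -> IntervalEstimate:
    """Normal-theory 95% interval on the given scale.

    ``log``: interval is point * exp(+-1.96 * se) where ``se`` is the SE of
    the log estimate (used for intensities and hazard ratios).
    ``probability``: identity-scale interval clipped to [0, 1].
    ``identity``: plain symmetric interval.
    """
    if se < 0:
        raise InferenceError("standard error must be non-negative")
    if scale == "log":
        if point <= 0:
            raise InferenceError("log-scale interval needs a positive point estimate")
        lo, hi = point * np.exp(-Z_95 * se), point * np.exp(Z_95 * se)
    elif scale == "probability":
        lo = max(0.0, point - Z_95 * se)
        hi = min(1.0, point + Z_95 * se)
    elif scale == "identity":
        lo, hi = point - Z_95 * se, point + Z_95 * se
    else:
        raise InferenceError(f"unknown interval scale {scale!r}")
    return IntervalEstimate(float(point), float(se), float(lo), float(hi), scale)


def write_replicate_weights(reps: ReplicateWeightSet, csv_path, meta_path) -> None:
    """Write replicate weights as CSV plus a JSON sidecar with design metadata."""
    df = pd.DataFrame({"child_id": reps.child_id, "base_weight": reps.base_weight})
    for k in range(reps.n_replicates):
        df[f"repw_{k + 1}"] = reps.replicate_weights[:, k]
    df.to_csv(csv_path, index=False)
    meta = {
        "n_replicates": reps.n_replicates,
        "replicates": reps.replicate_meta.astype(
            {"n_h": int}).to_dict(orient="records"),
    }
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=1, default=str)


def read_replicate_weights(csv_path, meta_path) -> ReplicateWeightSet:
    df = pd.read_csv(csv_path)
    with open(meta_path) as fh:
        meta = json.load(fh)
    rep_cols = [c for c in df.columns if c.startswith("repw_")]
    if len(rep_cols) != meta["n_replicates"]:
        raise FormatError("replicate CSV and metadata sidecar disagree on R")
    return ReplicateWeightSet(
        child_id=df["child_id"].to_numpy(),
        base_weight=df["base_weight"].to_numpy(dtype=float),
        replicate_weights=df[rep_cols].to_numpy(dtype=float),
        replicate_meta=pd.DataFrame(meta["replicates"]),
    )
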