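"""Survey-weighted continuous-time multistate model for panel data.

The chain is observed only at measurement ages (interval censoring), so a
child contributes, for each consecutive pair of observations (s_j at age
a_j, s_{j+1} at age a_{j+1}), the transition-probability factor
``P_{s_j, s_{j+1}}(a_{j+1} - a_j)`` where ``P(t) = expm(Q t)``.  Design
weights enter as a pseudo-likelihood: each child's log contribution is
multiplied by its survey weight,

    l(theta) = sum_i w_i sum_j log P_{s_ij -> s_i,j+1}(dt_ij; Q(x_i)).

Covariates act proportionally on the intensities,
``q_rs(x) = q_rs0 * exp(beta_rs' x)``, with transition-specific log hazard
ratios ``beta_rs``.  Estimation maximises the weighted log-likelihood over
unconstrained log-intensities and betas; variance comes from jackknife
replication (see :mod:`growthmsm.survey`), never from the weighted Hessian.

Usage follows the Model/Results convention::

    model = MultistateModel.from_dataframe(panel, covariates=["sex"])
    res = model.fit()
    res.summary()
    res.annual_probabilities()
    jk = res.jackknife(replicate_weights)
    jk.hazard_ratio_table()
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize

from .errors import EstimationError, NotConvergedError, StructureError
from .structure import (
    N_STATES,
    TransitionStructure,
    build_structure,
    intensity_matrix,
)

__all__ = [
    "MultistateModel",
    "MultistateResults",
    "crude_initial_intensities",
    "weighted_loglik",
    "fit_msm",
    "merge_levels",
    "RATE_FLOOR",
]

#: Floor for crude initial rates with zero observed events (per year).
RATE_FLOOR = 1e-6


def merge_levels(df: pd.DataFrame, column: str, mapping: dict) -> pd.DataFrame:
    """Recode sparse covariate levels (explicit user configuration).

    Useful when a level has no observed transitions and the fit cannot
    converge; merging is never automatic.
    """
    out = df.copy()
    out[column] = out[column].map(lambda v: mapping.get(v, v))
    return out


def _design_matrix(panel: pd.DataFrame, covariates):
    """Dummy-code the covariate columns (lowest level = reference).

    Returns (X, names) where names are ``col=level`` labels for non-reference
    levels and X has one row per panel row.
    """
    cols = []
    names = []
    for c in covariates:
        vals = panel[c]
        if vals.isna().any():
            raise EstimationError(
                f"covariate {c!r} has missing values; apply complete-case "
                "exclusion first"
            )
        levels = sorted(pd.unique(vals))
        for lev in levels[1:]:
            cols.append((vals == lev).to_numpy(dtype=float))
            names.append(f"{c}={lev}")
    if not cols:
        return np.zeros((len(panel), 0)), []
    return np.column_stack(cols), names


class MultistateModel:
    """Interval-censored multistate model bound to one panel dataset.

    Parameters
    ----------
    panel : DataFrame
        Validated long-format panel (see :mod:`growthmsm.panel`).
    covariates : sequence of str
        Columns entered as categorical covariates with transition-specific
        proportional effects.  Empty for an unadjusted fit.
    weight_col : str or None
        Survey weight column; ``None`` fits unweighted (all weights one).
    structure : TransitionStructure
        Allowed instantaneous transitions; defaults to the six adjacent ones.
    band_label : str
        Free-text tag for which age band / dataset this model covers.
    """

    def __init__(self, panel: pd.DataFrame, covariates=(), weight_col="weight",
                 structure: TransitionStructure | None = None,
                 band_label: str = ""):
        from .panel import validate_panel

        self.structure = structure or build_structure()
        self.covariates = list(covariates)
        self.band_label = band_label
        panel = validate_panel(panel)
        self.panel = panel

        g = panel.groupby("child_id", sort=False)
        first = g.head(1)
        frm = panel["state"].to_numpy() - 1
        nxt_state = g["state"].shift(-1).to_numpy()
        nxt_age = g["age_years"].shift(-1).to_numpy()
        has_next = ~np.isnan(nxt_age)
        self._interval_from = frm[has_next]
        self._interval_to = (nxt_state[has_next] - 1).astype(int)
        self._interval_dt = (nxt_age - panel["age_years"].to_numpy())[has_next]
        if np.any(self._interval_dt <= 0):
            raise EstimationError("non-positive interval length in panel")

        child_ids = panel["child_id"].to_numpy()
        self.child_id = first["child_id"].to_numpy()
        child_pos = pd.Index(self.child_id).get_indexer(child_ids[has_next])
        self._interval_child = child_pos
        if weight_col is None:
            self._child_weight = np.ones(len(self.child_id))
        else:
            self._child_weight = first[weight_col].to_numpy(dtype=float)

        X_rows, self.param_names_cov = _design_matrix(panel, self.covariates)
        X = X_rows[np.flatnonzero(has_next)]
        self.k_cov = X.shape[1]
        prof, prof_of_interval = np.unique(X, axis=0, return_inverse=True)
        self._profiles = prof  # (P, k)
        dts, dt_of_interval = np.unique(np.round(self._interval_dt, 9),
                                        return_inverse=True)
        self._dts = dts

        # collapse intervals into cells (profile, dt, from, to) for speed;
        # cell weights are re-aggregated per replicate weight vector
        key = np.column_stack([prof_of_interval, dt_of_interval,
                               self._interval_from, self._interval_to])
        cells, cell_of_interval = np.unique(key, axis=0, return_inverse=True)
        self._cells = cells
        self._cell_of_interval = cell_of_interval
        self._cell_weight = self._aggregate(self._child_weight)

        self.n_children = len(self.child_id)
        self.n_intervals = int(has_next.sum())
        self.n_transitions = int(
            (self._interval_from != self._interval_to).sum())
        self.n_params = self.structure.n_transitions * (1 + self.k_cov)

    # ------------------------------------------------------------------
    @classmethod
    def from_dataframe(cls, panel, **kwargs):
        return cls(panel, **kwargs)

    def _aggregate(self, child_weights: np.ndarray) -> np.ndarray:
        """Sum per-child weights into likelihood cells."""
        w = child_weights[self._interval_child]
        return np.bincount(self._cell_of_interval, weights=w,
                           minlength=len(self._cells))

    def _split(self, params):
        m = self.structure.n_transitions
        log_q = np.asarray(params[:m], dtype=float)
        beta = np.asarray(params[m:], dtype=float).reshape(m, self.k_cov)
        return log_q, beta

    def _prob_entries(self, params):
        """Transition-probability entry per cell under ``params``.

        P(t) = expm(Q t) is evaluated for all interval lengths at once via
        the eigendecomposition of each profile's generator (P(t) =
        V diag(e^{lambda t}) V^-1), falling back to scipy's expm when the
        eigenvector matrix is ill-conditioned.
        """
        log_q, beta = self._split(params)
        P, D = len(self._profiles), len(self._dts)
        # per-profile per-transition rates: exp(log_q + beta @ x)
        log_rates = log_q[None, :] + self._profiles @ beta.T  # (P, m)
        pmats = np.empty((P, D, N_STATES, N_STATES))
        for p in range(P):
            q = intensity_matrix(np.exp(log_rates[p]), self.structure)
            pmats[p] = self._expm_many(q)
        c = self._cells
        return pmats[c[:, 0], c[:, 1], c[:, 2], c[:, 3]]

    def _expm_many(self, q):
        """expm(q * dt) for every unique interval length in the panel."""
        dts = self._dts
        try:
            lam, V = np.linalg.eig(q)
            Vinv = np.linalg.inv(V)
            if np.linalg.cond(V) < 1e8:
                E = np.exp(lam[None, :] * dts[:, None])  # (D, 4)
                out = (V[None, :, :] * E[:, None, :]) @ Vinv
                if np.abs(out.imag).max() < 1e-9:
                    return out.real
        except np.linalg.LinAlgError:
            pass
        big = q[None, :, :] * dts[:, None, None]
        return expm(big)

    def loglik(self, params, cell_weights: np.ndarray | None = None) -> float:
        """Weighted log-likelihood; -inf when an observed move is impossible."""
        w = self._cell_weight if cell_weights is None else cell_weights
        try:
            with np.errstate(over="ignore", invalid="ignore"):
                pv = self._prob_entries(params)
        except (StructureError, ValueError):
            return -np.inf
        used = w > 0
        if np.any(~np.isfinite(pv[used])) or np.any(pv[used] <= 0.0):
            return -np.inf
        return float(np.sum(w[used] * np.log(pv[used])))

    def start_params(self) -> np.ndarray:
        q0 = crude_initial_intensities(self.panel, self.structure,
                                       weight_col=None if self._all_unit_weights()
                                       else "weight")
        rates = np.array([q0[r, s] for r, s in self.structure.transitions])
        return np.concatenate([np.log(rates),
                               np.zeros(self.structure.n_transitions * self.k_cov)])

    def _all_unit_weights(self):
        return bool(np.all(self._child_weight == 1.0))

    def fit(self, start_params=None, maxiter: int = 500,
            cell_weights: np.ndarray | None = None) -> "MultistateResults":
        """Maximise the weighted log-likelihood (quasi-Newton, with a
        derivative-free fallback when the line search stalls)."""
        x0 = np.asarray(start_params if start_params is not None
                        else self.start_params(), dtype=float)
        if x0.shape != (self.n_params,):
            raise EstimationError(
                f"start_params must have shape ({self.n_params},)")

        def nll(p):
            v = self.loglik(p, cell_weights)
            return np.inf if not np.isfinite(v) else -v

        res = minimize(nll, x0, method="L-BFGS-B",
                       options={"maxiter": maxiter, "ftol": 1e-12,
                                "gtol": 1e-7})
        if not res.success:
            res2 = minimize(nll, res.x, method="Nelder-Mead",
                            options={"maxiter": 200 * self.n_params,
                                     "fatol": 1e-9, "xatol": 1e-7})
            if res2.fun <= res.fun:
                res = res2
        ok = bool(res.success) and np.all(np.isfinite(res.x)) \
            and np.isfinite(res.fun)
        return MultistateResults(self, res.x, -res.fun, ok,
                                 n_iter=int(getattr(res, "nit", -1)))


class MultistateResults:
    """Fitted multistate model: estimates, transforms and summaries."""

    def __init__(self, model: MultistateModel, params, llf: float,
                 converged: bool, n_iter: int = -1):
        self.model = model
        self.params = np.asarray(params, dtype=float)
        self.llf = float(llf)
        self.converged = bool(converged)
        self.n_iter = n_iter
        self.log_q, self.beta = model._split(self.params)
        self.band_label = model.band_label

    # -- core transforms ------------------------------------------------
    def _require_converged(self):
        if not self.converged:
            raise NotConvergedError(
                "fit did not converge; inspect the model before using "
                "derived quantities"
            )

    def _profile_vector(self, profile):
        k = self.model.k_cov
        if profile is None:
            return np.zeros(k)
        x = np.asarray(profile, dtype=float)
        if x.shape != (k,):
            raise EstimationError(f"profile must have shape ({k},)")
        return x

    def intensity_matrix(self, profile=None) -> np.ndarray:
        """Fitted generator for a covariate profile (reference by default)."""
        x = self._profile_vector(profile)
        rates = np.exp(self.log_q + self.beta @ x)
        return intensity_matrix(rates, self.model.structure)

    def transition_probability_matrix(self, t: float, profile=None) -> np.ndarray:
        from .structure import transition_probability_matrix

        return transition_probability_matrix(self.intensity_matrix(profile), t,
                                             self.model.structure)

    def annual_probabilities(self, profile=None) -> np.ndarray:
        """Annual (1-year) transition probability matrix; refuses a
        non-converged fit."""
        self._require_converged()
        return self.transition_probability_matrix(1.0, profile)

    def hazard_ratios(self) -> pd.DataFrame:
        """HR = exp(beta) per transition and covariate level (reference = 1)."""
        self._require_converged()
        labels = self.model.structure.labels()
        rows = []
        for c in self.model.covariates:
            levels = sorted(pd.unique(self.model.panel[c]))
            for t_idx, lab in enumerate(labels):
                rows.append((lab, c, levels[0], 1.0))  # reference
            for lev in levels[1:]:
                j = self.model.param_names_cov.index(f"{c}={lev}")
                for t_idx, lab in enumerate(labels):
                    rows.append((lab, c, lev, float(np.exp(self.beta[t_idx, j]))))
        return pd.DataFrame(rows, columns=["transition", "covariate",
                                           "level", "hr"])

    def summary(self) -> str:
        lab = self.model.structure.labels()
        lines = [
            "Multistate transition model (survey-weighted ML)",
            f"  dataset: {self.band_label or '(unlabelled)'}",
            f"  children: {self.model.n_children}   intervals: "
            f"{self.model.n_intervals}   observed moves: {self.model.n_transitions}",
            f"  log-likelihood: {self.llf:.4f}   converged: {self.converged}",
            "",
            f"  {'transition':34s} {'intensity/yr':>12s}",
        ]
        for l, lq in zip(lab, self.log_q):
            lines.append(f"  {l:34s} {np.exp(lq):12.6f}")
        if self.model.k_cov:
            lines.append("")
            lines.append(f"  {'transition':34s} {'covariate':>16s} {'log HR':>10s}")
            for j, name in enumerate(self.model.param_names_cov):
                for t_idx, l in enumerate(lab):
                    lines.append(
                        f"  {l:34s} {name:>16s} {self.beta[t_idx, j]:10.4f}")
        return "\n".join(lines)

    # -- inference ------------------------------------------------------
    def jackknife(self, replicate_weights, max_bad_fraction: float = 0.05,
                  n_workers: int = 1) -> "JackknifeInference":
        """Refit every JKn replicate (warm-started from this fit) and wrap
        the replicate estimates for variance and CI construction.

        Replicate refits run sequentially regardless of ``n_workers`` so
        results never depend on scheduling; the argument is accepted for
        interface stability.
        """
        from .inference import JackknifeInference

        return JackknifeInference(self, replicate_weights,
                                  max_bad_fraction=max_bad_fraction)


def crude_initial_intensities(panel: pd.DataFrame,
                              structure: TransitionStructure | None = None,
                              weight_col: str | None = "weight",
                              floor: float = RATE_FLOOR) -> np.ndarray:
    """Event-count / person-time rates for optimizer initialisation.

    q_rs = (weighted count of observed r->s interval moves) / (weighted
    person-time of intervals starting in r), over the allowed transitions;
    transitions with no events are floored at ``floor`` per year.
    """
    structure = structure or build_structure()
    if len(panel) == 0:
        raise EstimationError("cannot initialise from an empty panel")
    df = panel.sort_values(["child_id", "age_years"], kind="stable")
    g = df.groupby("child_id", sort=False)
    frm = df["state"].to_numpy() - 1
    nxt = g["state"].shift(-1).to_numpy()
    dt = (g["age_years"].shift(-1) - df["age_years"]).to_numpy()
    has = ~np.isnan(dt)
    if not has.any():
        raise EstimationError("panel has no observation intervals")
    w = (np.ones(len(df)) if weight_col is None
         else df[weight_col].to_numpy(dtype=float))
    frm, to, dt, w = frm[has], (nxt[has] - 1).astype(int), dt[has], w[has]
    rates = np.empty(structure.n_transitions)
    for i, (r, s) in enumerate(structure.transitions):
        events = float(w[(frm == r) & (to == s)].sum())
        exposure = float((w * dt)[frm == r].sum())
        rates[i] = events / exposure if exposure > 0 and events > 0 else floor
    rates = np.maximum(rates, floor)
    return intensity_matrix(rates, structure)


def weighted_loglik(log_q, beta, panel: pd.DataFrame,
                    structure: TransitionStructure | None = None,
                    covariates=(), weight_col: str | None = "weight") -> float:
    """Functional form of the weighted panel log-likelihood."""
    model = MultistateModel(panel, covariates=covariates,
                            weight_col=weight_col, structure=structure)
    beta = np.zeros((model.structure.n_transitions, model.k_cov)) \
        if beta is None else np.asarray(beta, dtype=float)
    params = np.concatenate([np.asarray(log_q, dtype=float), beta.ravel()])
    return model.loglik(params)


def fit_msm(panel: pd.DataFrame, structure: TransitionStructure | None = None,
            covariates=(), weights: str = "on", band_label: str = "",
            **fit_options) -> MultistateResults:
    """One-call fit: build the model and maximise the likelihood.

    ``weights='off'`` ignores the weight column (unweighted ML); any other
    value uses the panel's ``weight`` column as survey weights.
    """
    model = MultistateModel(panel, covariates=covariates,
                            weight_col=None if weights == "off" else "weight",
                            structure=structure, band_label=band_label)
    return model.fit(**fit_options)
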