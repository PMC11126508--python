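"""Jackknife replication through the whole estimation pipeline.

Every JKn replicate re-estimates the model with its replicate weight
vector (warm-started from the full-sample optimum, which changes nothing
at the optimum but saves most of the iterations).  Standard errors of any
derived quantity -- intensities, annual probabilities, hazard ratios --
are computed by pushing each replicate's parameter vector through the same
transform and applying the stratified JKn variance formula, so intervals
reflect the full nonlinearity of the matrix-exponential pipeline rather
than a delta-method linearisation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InferenceError
from .survey import ReplicateWeightSet, interval_estimate, replicate_variance


class JackknifeInference:
    """Replicate refits and JKn variance for a fitted multistate model."""

    def __init__(self, results, replicate_weights: ReplicateWeightSet,
                 max_bad_fraction: float = 0.05):
        self.results = results
        model = results.model
        self.meta = replicate_weights.replicate_meta
        self.max_bad_fraction = max_bad_fraction
        base, repw = replicate_weights.weights_for(model.child_id)
        # sanity: the base weights must be the ones the model was fit with
        if not np.allclose(base, model._child_weight):
            raise InferenceError(
                "replicate weight set does not match the model's base weights")
        R = repw.shape[1]
        p = np.empty((R, model.n_params))
        ok = np.zeros(R, dtype=bool)
        for r in range(R):
            cw = model._aggregate(repw[:, r])
            fit_r = model.fit(start_params=results.params, cell_weights=cw)
            p[r] = fit_r.params
            ok[r] = fit_r.converged
        self.replicate_params = p
        self.converged = ok
        self.n_failed = int((~ok).sum())
        if self.n_failed > max_bad_fraction * R:
            raise InferenceError(
                f"{self.n_failed}/{R} replicate fits failed to converge")

    # ------------------------------------------------------------------
    def se(self, transform=None):
        """JKn standard error of ``transform(params)`` (identity by default)."""
        f = (lambda x: x) if transform is None else transform
        full = np.asarray(f(self.results.params), dtype=float)
        reps = np.stack([np.asarray(f(pr), dtype=float)
                         for pr in self.replicate_params])
        return replicate_variance(full, reps, self.meta, ok=self.converged,
                                  max_bad_fraction=self.max_bad_fraction)

    def _split(self, params):
        return self.results.model._split(params)

    # -- tables ---------------------------------------------------------
    def intensity_table(self, profile=None) -> pd.DataFrame:
        """Per-transition intensities with log-scale 95% CIs."""
        model = self.results.model

        def log_rates(params):
            log_q, beta = model._split(params)
            x = self.results._profile_vector(profile)
            return log_q + beta @ x

        se_log = self.se(log_rates)
        pts = np.exp(log_rates(self.results.params))
        rows = []
        for lab, pt, s in zip(model.structure.labels(), pts, se_log):
            est = interval_estimate(pt, s, scale="log")
            rows.append((lab, est.point, est.se, est.ci_low, est.ci_high))
        return pd.DataFrame(rows, columns=["transition", "intensity",
                                           "se_log", "ci_low", "ci_high"])

    def annual_probability_table(self, profile=None, t: float = 1.0) -> pd.DataFrame:
        """All 16 t-year transition probabilities with identity-scale CIs.

        Each replicate's probabilities are recomputed through the full
        matrix-exponential pipeline.
        """
        model = self.results.model

        def probs(params):
            res = _as_results(model, params)
            return res.transition_probability_matrix(t, profile).ravel()

        se = self.se(probs).reshape(4, 4)
        P = self.results.transition_probability_matrix(t, profile)
        from .structure import STATE_NAMES

        rows = []
        for r in range(4):
            for s in range(4):
                est = interval_estimate(P[r, s], se[r, s], scale="probability")
                rows.append((STATE_NAMES[r], STATE_NAMES[s], est.point,
                             est.se, est.ci_low, est.ci_high))
        return pd.DataFrame(rows, columns=["from", "to", "probability",
                                           "se", "ci_low", "ci_high"])

    def hazard_ratio_table(self) -> pd.DataFrame:
        """Hazard ratios with log-scale 95% CIs; reference levels pinned at 1."""
        model = self.results.model
        if model.k_cov == 0:
            raise InferenceError("model has no covariates")
        full_hr = self.results.hazard_ratios()

        def log_beta(params):
            _, beta = model._split(params)
            return beta.ravel()

        se = self.se(log_beta).reshape(model.structure.n_transitions,
                                       model.k_cov)
        labels = model.structure.labels()
        rows = []
        for _, row in full_hr.iterrows():
            name = f"{row['covariate']}={row['level']}"
            if name not in model.param_names_cov:  # reference level
                rows.append((row["transition"], row["covariate"], row["level"],
                             1.0, 0.0, 1.0, 1.0))
                continue
            j = model.param_names_cov.index(name)
            t_idx = labels.index(row["transition"])
            est = interval_estimate(row["hr"], se[t_idx, j], scale="log")
            rows.append((row["transition"], row["covariate"], row["level"],
                         est.point, est.se, est.ci_low, est.ci_high))
        return pd.DataFrame(rows, columns=["transition", "covariate", "level",
                                           "hr", "se_log", "ci_low", "ci_high"])


def _as_results(model, params):
    from .model import MultistateResults

    return MultistateResults(model, params, llf=np.nan, converged=True)
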