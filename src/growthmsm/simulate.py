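"""Synthetic cohort generator with known ground truth.

Emulates the structure of a large UK birth-cohort survey (the Millennium
Cohort Study): ~10,000 children sampled through 9 strata and 398 clusters
with oversampling of disadvantaged strata, measured at waves with mean ages
3, 5, 7, 11, 14 and 17 years, with monotone inter-wave attrition and
covariate missingness.  Each child's weight-status path is an exactly
simulated continuous-time Markov chain whose generator is piecewise
constant in age bands and scaled multiplicatively by covariate effects
(the same proportional-intensities form the estimator fits, so parameter
recovery is meaningful).

All randomness flows from ``SimulationConfig.seed``; identical configs give
byte-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ConfigurationError, StructureError
from .growth import lms_bmi
from .panel import drop_single_observation_children, validate_panel
from .structure import (
    build_structure,
    intensity_matrix,
    validate_intensity_matrix,
)
from .survey import SurveyDesign

__all__ = [
    "SimulationConfig",
    "default_band_intensities",
    "make_survey_design",
    "assign_design_weights",
    "simulate_ctmc_path",
    "simulate_cohort",
    "attach_bmi",
]

#: Baseline (age-3) state distribution: underweight, healthy, overweight,
#: obesity shares observed in the survey-weighted validation cohort.
DEFAULT_BASELINE = (0.0078, 0.7270, 0.1590, 0.1063)


def default_band_intensities():
    """Generating intensities by age band (per-year rates on the 6 transitions).

    Transition order: u->h, h->u, h->o, o->h, o->ob, ob->o.  Rates are chosen
    to echo the published age gradient: young children (3-7) both gain and
    resolve excess weight quickly; from 7 the resolution rates drop sharply
    while onset rates roughly halve.
    """
    return [
        ((3.0, 7.0), intensity_matrix([0.30, 0.0030, 0.035, 0.25, 0.100, 0.120])),
        ((7.0, 11.0), intensity_matrix([0.08, 0.0015, 0.015, 0.03, 0.055, 0.017])),
        ((11.0, 18.0), intensity_matrix([0.10, 0.0025, 0.018, 0.08, 0.055, 0.040])),
    ]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    ``covariate_effects`` maps covariate name -> level -> {transition index:
    log hazard ratio} using the six-transition order of the default
    structure; unlisted levels/transitions have effect zero (reference).
    ``covariate_frequencies`` maps drawn covariate name -> {level: prob}.
    Covariates present as extra columns on the survey design table (e.g. a
    disadvantage indicator) are picked up automatically.
    """

    n_children: int = 10_000
    wave_ages: tuple = (3.0, 5.0, 7.0, 11.0, 14.0, 17.0)
    band_intensities: list | None = None
    baseline_dist: tuple = DEFAULT_BASELINE
    covariate_frequencies: dict = field(
        default_factory=lambda: {"sex": {0: 0.5, 1: 0.5}})
    covariate_effects: dict = field(
        default_factory=lambda: {"sex": {1: {2: float(np.log(1.2))}}})
    attrition_rate: float = 0.09
    missing_covariate_rate: float = 0.05
    age_offset_mean: float = 0.13
    age_jitter_sd: float = 0.15
    # default survey design (used when no explicit design is supplied)
    n_strata: int = 9
    n_clusters: int = 398
    n_disadvantaged_strata: int = 3
    oversample_factor: float = 2.0
    seed: int = 0

    def bands(self):
        bands = self.band_intensities or default_band_intensities()
        ages = np.asarray(self.wave_ages, dtype=float)
        if np.any(np.diff(ages) <= 0):
            raise ConfigurationError("wave ages must be strictly increasing")
        for r in (self.attrition_rate, self.missing_covariate_rate):
            if not 0.0 <= r <= 1.0:
                raise ConfigurationError("rates must lie in [0, 1]")
        lo = min(b[0][0] for b in bands)
        hi = max(b[0][1] for b in bands)
        edges = sorted(b[0] for b in bands)
        for (a0, a1), (b0, _) in zip(edges, edges[1:]):
            if a1 != b0:
                raise ConfigurationError("age bands must be contiguous")
        if lo > ages[0] or hi < ages[-1]:
            raise ConfigurationError(
                f"age bands [{lo}, {hi}] do not cover wave span "
                f"[{ages[0]}, {ages[-1]}]"
            )
        for _, q in bands:
            validate_intensity_matrix(q)
        return sorted(bands, key=lambda b: b[0][0])


def make_survey_design(n_children: int,
                       n_strata: int = 9,
                       n_clusters: int = 398,
                       n_disadvantaged_strata: int = 3,
                       oversample_factor: float = 2.0,
                       rng: np.random.Generator | None = None) -> SurveyDesign:
    """Stratified cluster sample with oversampled disadvantaged strata.

    The superpopulation is split equally across strata; children in the
    last ``n_disadvantaged_strata`` strata are included with probability
    ``oversample_factor`` times that of the others, and carry
    correspondingly smaller design weights (normalised to mean 1).  A 0/1
    ``disadvantaged`` column marks the oversampled strata.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    if n_clusters < 2 * n_strata:
        raise ConfigurationError("need at least two clusters per stratum")
    strata = [f"s{h}" for h in range(n_strata)]
    disadvantaged = set(strata[n_strata - n_disadvantaged_strata:])
    per = np.full(n_strata, n_clusters // n_strata)
    per[: n_clusters % n_strata] += 1
    pop_share = np.full(n_strata, 1.0 / n_strata)
    factor = np.array([oversample_factor if s in disadvantaged else 1.0 for s in strata])
    incl = pop_share * factor / (pop_share * factor).sum()
    counts = rng.multinomial(n_children, incl)
    if np.any(counts < per):
        raise ConfigurationError(
            "too few children to populate every cluster; increase "
            "n_children or reduce n_clusters")
    rows = []
    cid = 0
    for h, (s, n_h, k_h) in enumerate(zip(strata, counts, per)):
        # stratum counts follow the tilted inclusion probabilities; within a
        # stratum every cluster gets at least one child so the realised
        # sample spans the whole design
        cluster_of = np.concatenate([np.arange(k_h),
                                     rng.integers(0, k_h, size=n_h - k_h)])
        for i in range(n_h):
            rows.append((cid, s, f"{s}_c{cluster_of[i]}", factor[h],
                         int(s in disadvantaged)))
            cid += 1
    df = pd.DataFrame(rows, columns=["child_id", "stratum", "psu",
                                     "selection_prob", "disadvantaged"])
    w = 1.0 / df["selection_prob"].to_numpy()
    df["weight"] = w / w.mean()
    return SurveyDesign(df)


def assign_design_weights(design: SurveyDesign, oversample_factor,
                          subgroup_col: str = "disadvantaged") -> SurveyDesign:
    """Rescale inclusion probabilities by subgroup and reset weights.

    ``oversample_factor`` is a scalar applied to subgroup value 1, or a
    mapping subgroup-value -> factor.  Weights become the (mean-normalised)
    inverse inclusion probabilities, so weighted subgroup proportions match
    the superpopulation in expectation.
    """
    t = design.table.copy()
    if subgroup_col not in t.columns:
        raise ConfigurationError(f"design has no column {subgroup_col!r}")
    if isinstance(oversample_factor, dict):
        fac = t[subgroup_col].map(lambda g: float(oversample_factor.get(g, 1.0)))
    else:
        fac = np.where(t[subgroup_col].astype(int) == 1,
                       float(oversample_factor), 1.0)
    fac = np.asarray(fac, dtype=float)
    if np.any(fac <= 0):
        raise ConfigurationError("oversampling factors must be positive")
    base_p = t["selection_prob"].to_numpy(dtype=float) if "selection_prob" in t else 1.0
    p = base_p * fac / np.asarray(base_p * fac).mean()
    t["selection_prob"] = p
    w = 1.0 / p
    t["weight"] = w / w.mean()
    return SurveyDesign(t)


def simulate_ctmc_path(q, t0: float, t1: float, state0: int,
                       rng: np.random.Generator) -> int:
    """State at ``t1`` of an exactly simulated CTMC path started in ``state0``.

    Exponential holding times with rate -q[s, s]; at a jump the chain moves
    to r with probability q[s, r] / (-q[s, s]).  ``state0`` and the return
    value use 1-based state codes.
    """
    if t1 <= t0:
        raise ConfigurationError("t1 must exceed t0")
    q = validate_intensity_matrix(q)
    s = int(state0) - 1
    t = float(t0)
    while True:
        rate = -q[s, s]
        if rate <= 0.0:
            return s + 1
        t += rng.exponential(1.0 / rate)
        if t >= t1:
            return s + 1
        probs = q[s].copy()
        probs[s] = 0.0
        s = int(rng.choice(len(probs), p=probs / rate))


def _path_through_bands(bands, mult, t0, t1, s0, rng):
    """Simulate from t0 to t1 through piecewise bands, rates scaled by mult."""
    s = s0
    t = t0
    for (a0, a1), q_scaled in bands:
        if a1 <= t or a0 >= t1:
            continue
        seg0, seg1 = max(t, a0), min(t1, a1)
        if seg1 > seg0:
            s = simulate_ctmc_path(q_scaled[mult], seg0, seg1, s, rng)
            t = seg1
    return s


def simulate_cohort(cfg: SimulationConfig,
                    design: SurveyDesign | None = None) -> pd.DataFrame:
    """Simulate the panel: states at wave ages with attrition and missingness.

    Returns a validated long-format panel (children with at least two
    retained observations) with columns child_id, wave, age_years, state,
    weight, stratum, psu and the covariate columns.
    """
    rng = np.random.default_rng(cfg.seed)
    if design is None:
        design = make_survey_design(
            cfg.n_children, n_strata=cfg.n_strata, n_clusters=cfg.n_clusters,
            n_disadvantaged_strata=cfg.n_disadvantaged_strata,
            oversample_factor=cfg.oversample_factor, rng=rng)
    bands = cfg.bands()
    structure = build_structure()
    tbl = design.table.reset_index(drop=True)
    n = len(tbl)
    wave_ages = np.asarray(cfg.wave_ages, dtype=float)
    n_waves = len(wave_ages)

    # covariates: drawn iid per child, plus any extra design columns
    cov = {}
    for name, freqs in cfg.covariate_frequencies.items():
        levels = sorted(freqs)
        p = np.array([freqs[l] for l in levels], dtype=float)
        cov[name] = np.array(levels, dtype=object)[
            rng.choice(len(levels), size=n, p=p / p.sum())]
    core = {"child_id", "stratum", "psu", "weight", "selection_prob"}
    for c in tbl.columns:
        if c not in core and c not in cov:
            cov[c] = tbl[c].to_numpy()

    # per-child multiplicative rate scaling from covariate effects
    log_mult = np.zeros((n, structure.n_transitions))
    for name, by_level in cfg.covariate_effects.items():
        if name not in cov:
            raise ConfigurationError(
                f"covariate_effects references unknown covariate {name!r}")
        vals = cov[name]
        for level, effects in by_level.items():
            mask = vals == level
            for t_idx, loghr in effects.items():
                log_mult[mask, int(t_idx)] += float(loghr)

    # precompute scaled generators per band per unique multiplier profile
    prof, prof_idx = np.unique(np.round(log_mult, 12), axis=0, return_inverse=True)
    from .structure import rates_from_matrix
    band_q = []
    for (a0, a1), q in bands:
        base = rates_from_matrix(q)
        band_q.append(((a0, a1), {
            k: intensity_matrix(base * np.exp(prof[k])) for k in range(len(prof))
        }))

    # exact measurement ages: nominal + non-negative field-work delay
    offs = np.clip(rng.normal(cfg.age_offset_mean, cfg.age_jitter_sd, (n, n_waves)),
                   0.0, 0.75)
    ages = np.round(wave_ages[None, :] + offs, 2)

    base_states = 1 + rng.choice(4, size=n, p=np.asarray(cfg.baseline_dist)
                                 / np.sum(cfg.baseline_dist))
    # monotone dropout: child leaves after each wave with prob attrition_rate
    u = rng.random((n, n_waves - 1))
    gone = np.cumsum(u < cfg.attrition_rate, axis=1) > 0
    observed = np.ones((n, n_waves), dtype=bool)
    observed[:, 1:] = ~gone

    # covariate masking (missingness), applied to the recorded value only
    masked = {name: rng.random(n) < cfg.missing_covariate_rate
              for name in cfg.covariate_frequencies}

    rows = []
    for i in range(n):
        s = int(base_states[i])
        k = int(prof_idx[i])
        last_wave = int(observed[i].sum())
        for w in range(last_wave):
            if w > 0:
                s = _path_through_bands(band_q, k, ages[i, w - 1], ages[i, w],
                                        s, rng)
            rows.append((tbl.at[i, "child_id"], w + 1, ages[i, w], s))
    out = pd.DataFrame(rows, columns=["child_id", "wave", "age_years", "state"])
    out = out.merge(tbl[["child_id", "stratum", "psu", "weight"]], on="child_id")
    for name, vals in cov.items():
        rec = pd.Series(vals, index=tbl["child_id"].to_numpy(), name=name)
        if name in masked:
            rec = rec.where(~pd.Series(masked[name], index=rec.index), other=np.nan)
        out[name] = rec.reindex(out["child_id"].to_numpy()).to_numpy()
    out, _ = drop_single_observation_children(out)
    return validate_panel(out)


def attach_bmi(panel: pd.DataFrame, ref, rng: np.random.Generator,
               sex_col: str = "sex") -> pd.DataFrame:
    """Back-transform states to plausible BMI values through an LMS reference.

    Draws a latent z-score uniformly (in probability) within the UK
    population-monitoring z-interval of each row's state and inverts the
    LMS transform at the row's age and sex.  Exists to exercise the growth
    module end to end; the simulator itself works at the state level.
    """
    from .growth import UK90_CENTILE_BOUNDS

    c_under, c_over, c_obese = UK90_CENTILE_BOUNDS
    bounds = {1: (1e-4, c_under), 2: (c_under, c_over),
              3: (c_over, c_obese), 4: (c_obese, 1 - 1e-4)}
    out = panel.copy()
    zs = np.empty(len(out))
    bmis = np.empty(len(out))
    sex_codes = out[sex_col].to_numpy()
    for i, (st, age, sx) in enumerate(zip(out["state"], out["age_years"], sex_codes)):
        lo, hi = bounds[int(st)]
        u = lo + (hi - lo) * rng.random()
        z = float(norm.ppf(u))
        zs[i] = z
        if pd.isna(sx):  # masked covariate: the body still has a BMI
            sx = rng.integers(0, 2)
        bmis[i] = lms_bmi(z, age * 12.0, "M" if int(sx) == 1 else "F", ref)
    out["zscore"] = zs
    out["bmi"] = bmis
    return out
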