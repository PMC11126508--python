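"""End-to-end analysis pipeline: exclusions, extraction, fits, traces.

The base-case analysis extracts pairwise datasets from adjacent survey
waves, fits a time-homogeneous multistate model within each pair (so the
intensities are piecewise constant in age), derives annual transition
matrices, and links them into a Markov-trace schedule.  Scenario analyses
assume a single time-homogeneous generator across all of childhood: either
fit to all intervals anchored at the first wave (scenario 1) or to the
first wave pair only (scenario 2).  Validation runs a trace from the
observed weighted baseline distribution and compares predicted with
observed prevalence at each wave.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, EstimationError, ExtractionError
from .growth import (
    DEFAULT_IMPLAUSIBLE_Z,
    classify_uk90,
    classify_who,
    lms_zscore,
    read_growth_reference,
    synthetic_growth_reference,
)
from .model import fit_msm
from .panel import drop_single_observation_children, validate_panel
from .survey import SurveyDesign, jackknife_replicates
from .trace import (
    MatrixSchedule,
    compare_scenarios,
    markov_trace,
    observed_prevalence,
    predicted_vs_observed,
)

__all__ = [
    "ExtractionPlan",
    "ResultsBundle",
    "derive_states",
    "apply_exclusions",
    "extract_pairwise_datasets",
    "extract_scenario_dataset",
    "run_pipeline",
]


@dataclass
class ExtractionPlan:
    """What to extract: base-case pairwise datasets or a scenario dataset."""

    mode: str = "pairwise"  # pairwise | scenario1 | scenario2
    wave_pairs: list | None = None  # adjacent (wave, wave+1) pairs
    covariate_columns: list = field(default_factory=list)
    complete_case: bool = True

    def __post_init__(self):
        if self.mode not in ("pairwise", "scenario1", "scenario2"):
            raise ConfigurationError(f"unknown extraction mode {self.mode!r}")


def derive_states(panel: pd.DataFrame, ref=None, cutoffs: str = "uk90",
                  implausible_z: float = DEFAULT_IMPLAUSIBLE_Z,
                  sex_col: str = "sex") -> pd.DataFrame:
    """Fill the ``state`` column from z-scores or BMI and flag implausible rows.

    Precedence: an existing ``state`` is kept; otherwise ``zscore`` is used;
    otherwise ``bmi`` is converted through the LMS reference (which then is
    required, along with age and sex).  Rows with |z| above
    ``implausible_z`` get ``implausible = True`` rather than being silently
    kept or dropped; :func:`apply_exclusions` removes them.
    """
    out = panel.copy()
    if "state" in out.columns and out["state"].notna().all():
        if "implausible" not in out.columns:
            out["implausible"] = False
        return out
    if "zscore" not in out.columns or out["zscore"].isna().any():
        if "bmi" not in out.columns:
            raise ConfigurationError(
                "panel needs one of state, zscore or bmi per row")
        ref = ref or synthetic_growth_reference()
        z = np.empty(len(out))
        for i, (bmi, age, sx) in enumerate(zip(out["bmi"], out["age_years"],
                                               out[sex_col])):
            z[i] = lms_zscore(bmi, age * 12.0,
                              "M" if int(sx) == 1 else "F", ref)
        out["zscore"] = z
    if cutoffs == "uk90":
        states = [int(classify_uk90(z)) for z in out["zscore"]]
    elif cutoffs == "who":
        states = [int(classify_who(z, a * 12.0))
                  for z, a in zip(out["zscore"], out["age_years"])]
    else:
        raise ConfigurationError(f"unknown cutoff scheme {cutoffs!r}")
    out["state"] = states
    out["implausible"] = out["zscore"].abs() > implausible_z
    return out


def apply_exclusions(panel: pd.DataFrame,
                     covariate_columns=(),
                     complete_case: bool = True,
                     multiple_birth_col: str = "multiple_birth",
                     implausible_col: str = "implausible"):
    """Apply the study exclusion rules; return (panel, exclusion ledger).

    Rules, in order: flagged multiple births; implausible bodyweight rows
    (children falling below two usable observations as a consequence are
    attributed to this rule); children with any missing configured
    covariate (complete-case); any remaining children with fewer than two
    observations.  The ledger counts excluded children per rule and
    reconciles: input = retained + sum of exclusions.
    """
    ledger = {}
    df = panel.copy()
    ledger["input_children"] = df["child_id"].nunique()

    if multiple_birth_col in df.columns:
        is_mult = df.groupby("child_id")[multiple_birth_col].transform("max") == 1
        ledger["multiple_births"] = df.loc[is_mult, "child_id"].nunique()
        df = df.loc[~is_mult]
    else:
        ledger["multiple_births"] = 0

    if implausible_col in df.columns:
        before = set(df["child_id"].unique())
        df = df.loc[~df[implausible_col].astype(bool)]
        df, _ = drop_single_observation_children(df)
        ledger["implausible_records"] = len(before - set(df["child_id"].unique()))
    else:
        ledger["implausible_records"] = 0

    if complete_case and covariate_columns:
        incomplete = df.groupby("child_id")[list(covariate_columns)] \
            .transform(lambda s: s.isna().any())
        bad = incomplete.any(axis=1)
        ledger["incomplete_covariates"] = df.loc[bad, "child_id"].nunique()
        df = df.loc[~bad]
    else:
        ledger["incomplete_covariates"] = 0

    df, n_single = drop_single_observation_children(df)
    ledger["single_observation"] = n_single
    ledger["retained_children"] = df["child_id"].nunique()
    if ledger["retained_children"] == 0:
        raise ExtractionError("all children excluded; nothing to analyse")
    assert ledger["input_children"] == ledger["retained_children"] + \
        ledger["multiple_births"] + ledger["implausible_records"] + \
        ledger["incomplete_covariates"] + ledger["single_observation"]
    return df.reset_index(drop=True), ledger


def _waves(panel: pd.DataFrame):
    if "wave" not in panel.columns:
        raise ExtractionError("extraction requires a 'wave' column")
    return sorted(panel["wave"].unique().tolist())


def extract_pairwise_datasets(panel: pd.DataFrame,
                              plan: ExtractionPlan) -> list:
    """One fit-ready dataset per adjacent wave pair.

    A child contributes to a pair iff it has a valid state at both waves;
    exactly those two observations are kept.  Returns a list of
    ``(pair, DataFrame)`` with ``pair = (wave_early, wave_late)``.
    """
    if plan.mode != "pairwise":
        raise ConfigurationError("plan mode must be 'pairwise'")
    waves = _waves(panel)
    pairs = plan.wave_pairs or list(zip(waves, waves[1:]))
    for a, b in pairs:
        if (a, b) not in zip(waves, waves[1:]):
            raise ConfigurationError(f"({a}, {b}) is not an adjacent wave pair")
    out = []
    for a, b in pairs:
        sub = panel[panel["wave"].isin([a, b])]
        counts = sub.groupby("child_id")["wave"].nunique()
        keep = counts[counts == 2].index
        if len(keep) < 2:
            raise ExtractionError(f"wave pair ({a}, {b}) has fewer than 2 children")
        out.append(((a, b), sub[sub["child_id"].isin(keep)]
                    .reset_index(drop=True)))
    return out


def extract_scenario_dataset(panel: pd.DataFrame,
                             plan: ExtractionPlan) -> pd.DataFrame:
    """Scenario datasets for the time-homogeneous models.

    Scenario 1: children observed at the first wave with at least one
    later observation; all their observations are kept and gaps are treated
    as single long intervals.  Scenario 2: the first adjacent wave pair
    only (definitionally the first pairwise dataset).
    """
    waves = _waves(panel)
    first = waves[0]
    if plan.mode == "scenario2":
        pair_plan = ExtractionPlan(mode="pairwise",
                                   wave_pairs=[(waves[0], waves[1])],
                                   covariate_columns=plan.covariate_columns,
                                   complete_case=plan.complete_case)
        return extract_pairwise_datasets(panel, pair_plan)[0][1]
    if plan.mode != "scenario1":
        raise ConfigurationError("plan mode must be scenario1 or scenario2")
    has_first = panel.groupby("child_id")["wave"].transform("min") == first
    sub = panel.loc[has_first]
    sub, _ = drop_single_observation_children(sub)
    if sub["child_id"].nunique() < 2:
        raise ExtractionError("scenario 1 dataset has fewer than 2 children")
    return sub.reset_index(drop=True)


@dataclass
class ResultsBundle:
    """Everything the pipeline produced, plus run metadata."""

    fits: dict  # label -> MultistateResults
    annual_tables: dict  # label -> DataFrame (with CIs when replicated)
    hr_tables: dict  # label -> DataFrame
    traces: dict  # model name -> MarkovTrace
    validation: pd.DataFrame | None
    scenario_comparison: pd.DataFrame | None
    exclusion_ledger: dict
    metadata: dict
    output_dir: Path | None = None


def _config_hash(config: dict) -> str:
    # hash only analysis-relevant keys, so two runs writing to different
    # directories produce identical result files
    cfg = {k: v for k, v in config.items() if k != "output_dir"}
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _fit_band(df, label, covariates, use_weights, replicates):
    res = fit_msm(df, weights="on" if use_weights else "off",
                  band_label=label)
    tables = {}
    jk = None
    if replicates:
        design = SurveyDesign(
            df.groupby("child_id", sort=False)
            .head(1)[["child_id", "stratum", "psu", "weight"]]
            .reset_index(drop=True))
        jk = res.jackknife(jackknife_replicates(design))
        tables["annual"] = jk.annual_probability_table()
        tables["intensity"] = jk.intensity_table()
    else:
        P = res.annual_probabilities()
        from .structure import STATE_NAMES

        rows = [(STATE_NAMES[r], STATE_NAMES[s], P[r, s])
                for r in range(4) for s in range(4)]
        tables["annual"] = pd.DataFrame(rows, columns=["from", "to",
                                                       "probability"])
    hr_rows = []
    for cov in covariates:
        sub = df.dropna(subset=[cov])
        sub, _ = drop_single_observation_children(sub)
        res_c = fit_msm(sub, covariates=[cov],
                        weights="on" if use_weights else "off",
                        band_label=f"{label}|{cov}")
        if replicates:
            design = SurveyDesign(
                sub.groupby("child_id", sort=False)
                .head(1)[["child_id", "stratum", "psu", "weight"]]
                .reset_index(drop=True))
            jk_c = res_c.jackknife(jackknife_replicates(design))
            hr_rows.append(jk_c.hazard_ratio_table())
        else:
            hr_rows.append(res_c.hazard_ratios())
    hr = pd.concat(hr_rows, ignore_index=True) if hr_rows else None
    return res, tables, hr


def run_pipeline(config: dict) -> ResultsBundle:
    """Run the configured analysis end to end; deterministic given config.

    Config keys (all optional unless noted): ``seed``; ``simulation`` (a
    mapping of :class:`~growthmsm.simulate.SimulationConfig` overrides) or
    ``input`` with ``panel_csv`` (+ optional ``growth_reference_csv``);
    ``cutoffs`` (uk90|who); ``mode`` (pairwise|scenario1|scenario2|all);
    ``covariates``; ``complete_case``; ``replicates`` (bool);
    ``output_dir``.
    """
    seed = int(config.get("seed", 0))
    cutoffs = config.get("cutoffs", "uk90")
    mode = config.get("mode", "pairwise")
    covariates = list(config.get("covariates", []))
    complete_case = bool(config.get("complete_case", True))
    use_replicates = bool(config.get("replicates", False))
    outdir = config.get("output_dir")

    ref = None
    if "simulation" in config:
        from .simulate import SimulationConfig, attach_bmi, simulate_cohort

        sim_kwargs = dict(config["simulation"])
        sim_kwargs.setdefault("seed", seed)
        cfg = SimulationConfig(**sim_kwargs)
        panel = simulate_cohort(cfg)
        if cutoffs != "uk90" or config.get("emit_bmi", False):
            rng = np.random.default_rng(seed + 1)
            panel = attach_bmi(panel, synthetic_growth_reference(), rng)
            panel = panel.drop(columns=["state"])
    elif "input" in config:
        # raw read; states may still need deriving, so validate later
        panel = pd.read_csv(config["input"]["panel_csv"])
        ref_path = config["input"].get("growth_reference_csv")
        if ref_path:
            ref = read_growth_reference(ref_path)
    else:
        raise ConfigurationError("config needs a 'simulation' or 'input' block")
    panel = derive_states(panel, ref=ref, cutoffs=cutoffs,
                          implausible_z=float(config.get("implausible_z",
                                                         DEFAULT_IMPLAUSIBLE_Z)))
    panel, ledger = apply_exclusions(panel, covariate_columns=covariates,
                                     complete_case=complete_case)
    panel = validate_panel(panel)

    plan = ExtractionPlan(mode="pairwise", covariate_columns=covariates,
                          complete_case=complete_case)
    obs_prev = observed_prevalence(panel)
    baseline = obs_prev.iloc[0][["p_underweight", "p_healthy",
                                 "p_overweight", "p_obesity"]].to_numpy(dtype=float)
    age0 = float(round(obs_prev.iloc[0]["mean_age"]))
    age_end = float(round(obs_prev.iloc[-1]["mean_age"]))

    fits, annual_tables, hr_tables, traces = {}, {}, {}, {}
    run_base = mode in ("pairwise", "all")
    if run_base:
        pair_sets = extract_pairwise_datasets(panel, plan)
        entries = []
        for (a, b), df in pair_sets:
            label = f"waves {a}-{b}"
            res, tables, hr = _fit_band(df, label, covariates, True,
                                        use_replicates)
            fits[label] = res
            annual_tables[label] = tables["annual"]
            if hr is not None:
                hr_tables[label] = hr
            ages = df.groupby("wave")["age_years"].mean()
            entries.append((float(round(ages.loc[a])), float(round(ages.loc[b])),
                            res.annual_probabilities()))
        traces["base"] = markov_trace(baseline, MatrixSchedule(entries),
                                      age0, age_end)
    for scen in ("scenario1", "scenario2"):
        if mode not in (scen, "all"):
            continue
        df = extract_scenario_dataset(
            panel, ExtractionPlan(mode=scen, covariate_columns=covariates,
                                  complete_case=complete_case))
        res, tables, hr = _fit_band(df, scen, covariates, True, use_replicates)
        fits[scen] = res
        annual_tables[scen] = tables["annual"]
        if hr is not None:
            hr_tables[scen] = hr
        sched = MatrixSchedule([(age0, age_end, res.annual_probabilities())])
        traces[scen] = markov_trace(baseline, sched, age0, age_end)

    validation = None
    comparison = None
    if traces:
        ref_trace = traces.get("base") or next(iter(traces.values()))
        validation = predicted_vs_observed(ref_trace, obs_prev)
        if "base" in traces and len(traces) > 1:
            comparison = compare_scenarios(
                traces["base"],
                {k: v for k, v in traces.items() if k != "base"}, obs_prev)

    metadata = {
        "seed": seed,
        "config_hash": _config_hash(config),
        "cutoffs": cutoffs,
        "mode": mode,
        "exclusions": ledger,
        "n_children": int(panel["child_id"].nunique()),
    }
    bundle = ResultsBundle(fits=fits, annual_tables=annual_tables,
                           hr_tables=hr_tables, traces=traces,
                           validation=validation,
                           scenario_comparison=comparison,
                           exclusion_ledger=ledger, metadata=metadata)
    if outdir:
        bundle.output_dir = _write_bundle(bundle, Path(outdir))
    return bundle


def _write_bundle(bundle: ResultsBundle, outdir: Path) -> Path:
    """Persist every reported number to a stage output file."""
    outdir.mkdir(parents=True, exist_ok=True)
    for label, tab in bundle.annual_tables.items():
        tab.to_csv(outdir / f"annual_{_slug(label)}.csv", index=False)
    for label, tab in bundle.hr_tables.items():
        tab.to_csv(outdir / f"hr_{_slug(label)}.csv", index=False)
    for name, tr in bundle.traces.items():
        tr.to_frame().to_csv(outdir / f"trace_{_slug(name)}.csv", index=False)
    if bundle.validation is not None:
        bundle.validation.to_csv(outdir / "validation_ratios.csv", index=False)
    if bundle.scenario_comparison is not None:
        bundle.scenario_comparison.to_csv(outdir / "scenario_comparison.csv",
                                          index=False)
    with open(outdir / "metadata.json", "w") as fh:
        json.dump(bundle.metadata, fh, indent=1, sort_keys=True)
    return outdir


def _slug(s) -> str:
    return str(s).replace(" ", "_").replace("|", "_")
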