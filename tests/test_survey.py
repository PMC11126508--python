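"""JKn replicate weights, replicate variance and interval construction."""

import numpy as np
import pandas as pd
import pytest

from growthmsm.errors import DesignError, InferenceError
from growthmsm.simulate import make_survey_design
from growthmsm.survey import (
    SurveyDesign,
    interval_estimate,
    jackknife_replicates,
    read_replicate_weights,
    replicate_variance,
    write_replicate_weights,
)


def design_from(rows):
    return SurveyDesign(pd.DataFrame(
        rows, columns=["child_id", "stratum", "psu", "weight"]))


class TestReplicateConstruction:
    def test_smallest_legal_design_doubles_survivor(self):
        d = design_from([(1, "s", "a", 1.0), (2, "s", "b", 1.0)])
        reps = jackknife_replicates(d)
        assert reps.n_replicates == 2
        # replicate deleting cluster a: child 2 doubled, child 1 zeroed
        assert reps.replicate_weights[:, 0].tolist() == [0.0, 2.0]
        assert reps.replicate_weights[:, 1].tolist() == [2.0, 0.0]

    def test_one_replicate_per_cluster(self):
        d = make_survey_design(1000, rng=np.random.default_rng(0))
        reps = jackknife_replicates(d)
        assert reps.n_replicates == d.n_clusters == 398

    def test_stratum_totals_preserved_in_every_column(self):
        # balanced clusters: deleting one and rescaling the stratum mates by
        # n_h/(n_h-1) leaves every stratum's weight total unchanged
        rows = []
        cid = 0
        for h in range(4):
            for c in range(4):
                for _ in range(10):
                    rows.append((cid, f"s{h}", f"s{h}_c{c}", 1.0 + 0.5 * h))
                    cid += 1
        d = design_from(rows)
        reps = jackknife_replicates(d)
        strat = d.table["stratum"].to_numpy()
        for h in d.strata:
            base_total = reps.base_weight[strat == h].sum()
            col_totals = reps.replicate_weights[strat == h].sum(axis=0)
            assert np.allclose(col_totals, base_total, rtol=1e-12)

    def test_singleton_cluster_stratum_rejected(self):
        d = design_from([(1, "s", "a", 1.0), (2, "s", "a", 1.0),
                         (3, "t", "b", 1.0), (4, "t", "c", 1.0)])
        with pytest.raises(DesignError, match="'s'"):
            jackknife_replicates(d)

    def test_construction_is_deterministic(self):
        d = make_survey_design(200, n_strata=3, n_clusters=9,
                               n_disadvantaged_strata=1,
                               rng=np.random.default_rng(2))
        a, b = jackknife_replicates(d), jackknife_replicates(d)
        assert np.array_equal(a.replicate_weights, b.replicate_weights)


def weighted_mean(w, x):
    return np.sum(w * x) / np.sum(w)


class TestReplicateVariance:
    def test_identical_replicates_give_zero_se(self):
        meta = pd.DataFrame({"stratum": ["s", "s"], "psu": ["a", "b"],
                             "n_h": [2, 2]})
        assert replicate_variance(1.0, [1.0, 1.0], meta) == 0.0

    def test_matches_textbook_jkn_for_weighted_mean(self):
        rng = np.random.default_rng(5)
        d = make_survey_design(120, n_strata=1, n_clusters=6,
                               n_disadvantaged_strata=0, rng=rng)
        x = rng.normal(size=120)
        reps = jackknife_replicates(d)
        full = weighted_mean(reps.base_weight, x)
        theta = np.array([weighted_mean(reps.replicate_weights[:, r], x)
                          for r in range(reps.n_replicates)])
        se = replicate_variance(full, theta, reps.replicate_meta)
        n_h = 6
        v_direct = (n_h - 1) / n_h * np.sum((theta - full) ** 2)
        assert se == pytest.approx(np.sqrt(v_direct), rel=1e-12)

    def test_reduces_to_classic_delete_one_jackknife(self):
        # one child per cluster, equal weights, single stratum: JKn SE of the
        # mean equals the classic delete-one jackknife SE
        rng = np.random.default_rng(6)
        n = 30
        x = rng.normal(size=n)
        d = design_from([(i, "s", f"c{i}", 1.0) for i in range(n)])
        reps = jackknife_replicates(d)
        theta = np.array([weighted_mean(reps.replicate_weights[:, r], x)
                          for r in range(n)])
        se = replicate_variance(x.mean(), theta, reps.replicate_meta)
        loo = np.array([np.delete(x, i).mean() for i in range(n)])
        classic = np.sqrt((n - 1) / n * np.sum((loo - loo.mean()) ** 2))
        assert se == pytest.approx(classic, rel=1e-10)

    def test_ci_coverage_for_weighted_total(self):
        # 500 simulated samples: normal-theory JKn CIs for a weighted total
        # should cover the superpopulation total ~95% of the time
        rng = np.random.default_rng(7)
        mu, n = 10.0, 200
        hits = 0
        n_sim = 500
        for _ in range(n_sim):
            d = make_survey_design(n, n_strata=4, n_clusters=40,
                                   n_disadvantaged_strata=2,
                                   oversample_factor=2.0, rng=rng)
            # cluster-correlated responses make the design effect real
            cluster_eff = {c: rng.normal(0, 0.5) for c in d.table["psu"].unique()}
            x = (mu + d.table["psu"].map(cluster_eff).to_numpy()
                 + rng.normal(0, 1, n))
            reps = jackknife_replicates(d)
            w = reps.base_weight
            full = weighted_mean(w, x)
            theta = reps.replicate_weights.T @ x / reps.replicate_weights.sum(axis=0)
            se = replicate_variance(full, theta, reps.replicate_meta)
            est = interval_estimate(full, se, scale="identity")
            hits += est.ci_low <= mu <= est.ci_high
        cover = hits / n_sim
        tol = 3 * np.sqrt(0.95 * 0.05 / n_sim)
        assert abs(cover - 0.95) < max(tol, 0.03)

    def test_too_many_failed_replicates_raises(self):
        meta = pd.DataFrame({"stratum": ["s"] * 10, "psu": list("abcdefghij"),
                             "n_h": [10] * 10})
        ok = np.ones(10, bool)
        ok[:2] = False
        with pytest.raises(InferenceError, match="failed"):
            replicate_variance(1.0, np.ones(10), meta, ok=ok)


class TestIntervals:
    def test_zero_se_degenerates_to_point(self):
        est = interval_estimate(0.4, 0.0, scale="probability")
        assert est.ci_low == est.ci_high == est.point == 0.4

    def test_log_scale_interval(self):
        est = interval_estimate(1.5, 0.1, scale="log")
        assert est.ci_low == pytest.approx(1.5 * np.exp(-1.959963984540054 * 0.1))
        assert est.ci_high == pytest.approx(1.5 * np.exp(1.959963984540054 * 0.1))

    def test_probability_clipping(self):
        est = interval_estimate(0.001, 0.5, scale="probability")
        assert est.ci_low == 0.0
        est = interval_estimate(0.999, 0.5, scale="probability")
        assert est.ci_high == 1.0


class TestReplicateIO:
    def test_round_trip(self, tmp_path):
        d = make_survey_design(40, n_strata=2, n_clusters=6,
                               n_disadvantaged_strata=1,
                               rng=np.random.default_rng(8))
        reps = jackknife_replicates(d)
        csv, meta = tmp_path / "w.csv", tmp_path / "w.json"
        write_replicate_weights(reps, csv, meta)
        back = read_replicate_weights(csv, meta)
        assert np.allclose(back.replicate_weights, reps.replicate_weights)
        assert back.replicate_meta["stratum"].tolist() == \
            reps.replicate_meta["stratum"].tolist()
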