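import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lipidscore.assoc import (correlation_matrix, correlation_network,
                              fit_logistic_gee, fit_outcome_models,
                              fit_recovery_cox, prepare_recovery, recovery_km,
                              _km_curve)
from lipidscore.data import CohortTable, LipidomicsMatrix
from lipidscore.preprocess import zscore


class TestCorrelationMatrix:
    def test_self_correlation_one(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"x": rng.normal(size=10)})
        df["x2"] = df["x"]
        r, p = correlation_matrix(df, method="pearson")
        assert r.loc["x", "x2"] == pytest.approx(1.0)

    def test_spearman_exact_rank_formula(self):
        # oracle: rho = 1 - 6*sum(d^2)/(n(n^2-1)) for x=(1,2,3,4), y=(1,3,2,4)
        df = pd.DataFrame({"x": [1, 2, 3, 4], "y": [1, 3, 2, 4]})
        d2 = sum((rx - ry) ** 2 for rx, ry in zip([1, 2, 3, 4], [1, 3, 2, 4]))
        expected = 1 - 6 * d2 / (4 * 15)
        assert expected == 0.8
        r, p = correlation_matrix(df, method="spearman")
        assert r.loc["x", "y"] == pytest.approx(0.8)

    def test_zero_r_gives_p_one(self):
        # orthogonal columns: t = 0 -> p = 1
        df = pd.DataFrame({"x": [1.0, -1.0, 1.0, -1.0, 0.0],
                           "y": [1.0, 1.0, -1.0, -1.0, 0.0]})
        r, p = correlation_matrix(df, method="pearson")
        assert r.loc["x", "y"] == pytest.approx(0.0, abs=1e-12)
        assert p.loc["x", "y"] == pytest.approx(1.0)

    def test_t_distribution_pvalues(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(30, 2)), columns=["x", "y"])
        r, p = correlation_matrix(df, method="pearson")
        rv = r.loc["x", "y"]
        t = rv * np.sqrt((30 - 2) / (1 - rv * rv))
        assert p.loc["x", "y"] == pytest.approx(2 * stats.t.sf(abs(t), 28))

    def test_constant_column_missing(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0],
                           "y": [5.0, 5.0, 5.0, 5.0]})
        r, p = correlation_matrix(df, method="pearson")
        assert np.isnan(r.loc["x", "y"])

    def test_too_few_rows(self):
        df = pd.DataFrame({"x": [1.0, 2.0], "y": [2.0, 1.0]})
        with pytest.raises(ValueError):
            correlation_matrix(df)


class TestCorrelationNetwork:
    def _zmatrix(self, values):
        return zscore(LipidomicsMatrix(values))

    def test_high_correlation_edge(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=200)
        values = pd.DataFrame({
            "PE(16:0_18:2)": np.exp(base * 0.9 + rng.normal(0, 0.2, 200)),
            "PE(16:0_20:4)": np.exp(base * 0.9 + rng.normal(0, 0.2, 200)),
            "CE(18:1)": np.exp(rng.normal(size=200)),
        }, index=[f"s{i}" for i in range(200)])
        net = correlation_network(self._zmatrix(values), r_thresh=0.7)
        pairs = {frozenset((a, b)) for a, b in
                 zip(net.edges["node1"], net.edges["node2"])}
        assert frozenset(("PE(16:0_18:2)", "PE(16:0_20:4)")) in pairs
        assert len(pairs) == 1

    def test_threshold_one_only_duplicates(self):
        rng = np.random.default_rng(1)
        col = rng.normal(size=50)
        values = pd.DataFrame({
            "PE(16:0_18:2)": np.exp(col),
            "PE(16:0_20:4)": np.exp(col),           # exact duplicate
            "CE(18:1)": np.exp(rng.normal(size=50)),
        }, index=[f"s{i}" for i in range(50)])
        net = correlation_network(self._zmatrix(values), r_thresh=1.0)
        assert len(net.edges) == 1

    def test_planted_block_density(self, small_trauma):
        from lipidscore.pipeline import preprocess_matrix
        matrix, cohort, truth = small_trauma
        _, z = preprocess_matrix(matrix)
        net = correlation_network(z, r_thresh=0.5)
        planted = [s for s in truth.planted_pe if s in net.nodes]
        pairs = {frozenset((a, b)) for a, b in
                 zip(net.edges["node1"], net.edges["node2"])}
        possible = [frozenset((a, b)) for i, a in enumerate(planted)
                    for b in planted[i + 1:]]
        density = np.mean([p in pairs for p in possible])
        assert density >= 0.5

    def test_per_class_cap(self, small_trauma):
        from lipidscore.pipeline import preprocess_matrix
        matrix, _, _ = small_trauma
        _, z = preprocess_matrix(matrix)
        net = correlation_network(z, per_class_top={"TAG": 10}, r_thresh=0.7)
        assert net.selection["TAG"] == 10

    def test_order_invariance(self, small_trauma):
        from lipidscore.pipeline import preprocess_matrix
        matrix, _, _ = small_trauma
        _, z = preprocess_matrix(matrix)
        net1 = correlation_network(z, per_class_top={}, r_thresh=0.7)
        shuffled = LipidomicsMatrix(
            z.inverse()[list(reversed(list(z.z.columns)))])
        net2 = correlation_network(zscore(shuffled), per_class_top={},
                                   r_thresh=0.7)
        e1 = {frozenset((a, b)) for a, b in
              zip(net1.edges["node1"], net1.edges["node2"])}
        e2 = {frozenset((a, b)) for a, b in
              zip(net2.edges["node1"], net2.edges["node2"])}
        assert e1 == e2


def km_bruteforce(times, events):
    """Independent product-limit oracle over the raw definition."""
    out = {}
    s = 1.0
    for t in sorted(set(times)):
        at_risk = sum(1 for ti in times if ti >= t)
        deaths = sum(1 for ti, ei in zip(times, events) if ti == t and ei)
        s *= 1 - deaths / at_risk
        out[t] = s
    return out


def _cohort_df(rows):
    recs = []
    for i, r in enumerate(rows):
        rec = {"subject_id": f"P{i}", "timepoint": "0h", "outcome": "resolving",
               "died": 0, "death_day": np.nan}
        rec.update(r)
        recs.append(rec)
    return pd.DataFrame(recs)


class TestRecovery:
    def test_all_discharged_day_one(self):
        df = _cohort_df([{"icu_los_days": 1}] * 4)
        curves, _ = recovery_km(df)
        c = curves["resolving"]
        assert c.times[0] == 1
        assert c.probability[0] == pytest.approx(0.0)

    def test_hand_computed_product_limit(self):
        df = _cohort_df([{"icu_los_days": d} for d in [1, 2, 3, 4]])
        curves, _ = recovery_km(df)
        c = curves["resolving"]
        np.testing.assert_allclose(c.probability, [0.75, 0.5, 0.25, 0.0])

    def test_matches_bruteforce_on_fixtures(self):
        rng = np.random.default_rng(0)
        for trial in range(10):
            n = int(rng.integers(3, 9))
            times = rng.integers(1, 10, n).astype(float)
            events = rng.integers(0, 2, n)
            oracle = km_bruteforce(times, events)
            curve = _km_curve(times, events, "g")
            for t, s in zip(curve.times, curve.probability):
                assert s == pytest.approx(oracle[t])

    def test_late_death_max_stay_convention(self):
        rows = [{"icu_los_days": d} for d in [1, 2, 3, 4]]
        rows.append({"icu_los_days": 10, "died": 1, "death_day": 10,
                     "outcome": "non_resolving"})
        df = _cohort_df(rows)
        prep = prepare_recovery(df)
        dead = prep[prep["subject_id"] == "P4"]
        # carried at the dataset maximum stay (10) and never recovers
        assert dead["time"].iloc[0] == 10
        assert dead["event"].iloc[0] == 0
        curves, _ = recovery_km(df, group_col="outcome")
        c = curves["non_resolving"]
        assert c.probability[-1] > 0

    def test_early_death_excluded(self):
        rows = [{"icu_los_days": 2},
                {"icu_los_days": 1, "died": 1, "death_day": 2}]
        prep = prepare_recovery(_cohort_df(rows))
        assert list(prep["subject_id"]) == ["P0"]

    def test_censor_at_30(self):
        rows = [{"icu_los_days": 45}, {"icu_los_days": 2}]
        prep = prepare_recovery(_cohort_df(rows))
        long = prep[prep["subject_id"] == "P0"]
        assert long["time"].iloc[0] == 30
        assert long["event"].iloc[0] == 0

    def test_empty_group_errors(self, small_trauma):
        _, cohort, _ = small_trauma
        df = cohort.table.copy()
        df.loc[df["outcome"] == "resolving", "outcome"] = np.nan
        # groups with zero subjects simply disappear; an explicitly empty
        # requested group raises
        curves, _ = recovery_km(df.dropna(subset=["outcome"]))
        assert "resolving" not in curves


class TestOutcomeModels:
    def _logistic_cohort(self, seed, n=500, beta=1.0, n_sites=5):
        rng = np.random.default_rng(seed)
        lrs = rng.normal(size=n)
        site = rng.integers(1, n_sites + 1, n)
        lin = -0.3 + beta * lrs
        y = (rng.random(n) < 1 / (1 + np.exp(-lin))).astype(float)
        return pd.DataFrame({"y": y, "lrs": lrs, "site_id": site})

    def test_logistic_coefficient_recovery(self):
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            df = self._logistic_cohort(seed)
            eff = fit_logistic_gee(df, "y", ["lrs"], cluster_col="site_id")
            est = eff.loc[eff["term"] == "lrs", "coef"].iloc[0]
            hits += abs(est - 1.0) <= 0.3
        assert hits >= int(0.9 * n_seeds)

    def test_null_covariate_coverage(self):
        covered = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            df = self._logistic_cohort(seed, n=300, beta=0.8)
            df["noise"] = rng.normal(size=len(df))
            eff = fit_logistic_gee(df, "y", ["lrs", "noise"],
                                   cluster_col="site_id")
            row = eff[eff["term"] == "noise"].iloc[0]
            covered += row["ci_low"] <= 1.0 <= row["ci_high"]
        # ~95% coverage; allow generous MC slack
        assert covered >= 0.85 * n_seeds

    def test_single_cluster_equals_plain_fit(self):
        df = self._logistic_cohort(3, n=300)
        df["site_id"] = 1
        eff_clustered = fit_logistic_gee(df, "y", ["lrs"],
                                         cluster_col="site_id")
        eff_plain = fit_logistic_gee(df, "y", ["lrs"], cluster_col=None)
        assert eff_clustered["coef"].iloc[0] == pytest.approx(
            eff_plain["coef"].iloc[0], rel=1e-6)

    def test_cox_effect_direction(self, small_trauma):
        _, cohort, _ = small_trauma
        prep = prepare_recovery(cohort.table)
        df = cohort.table.drop_duplicates("subject_id").set_index("subject_id")
        work = prep.set_index("subject_id")
        work["iss"] = df.loc[work.index, "iss"]
        work = work.dropna(subset=["iss"])
        eff = fit_recovery_cox(work.reset_index(), ["iss"])
        # higher injury severity -> slower recovery (HR < 1)
        assert eff["hr"].iloc[0] < 1.0

    def test_fit_outcome_models_stacks(self):
        df = self._logistic_cohort(5)
        out = fit_outcome_models(df, [
            {"name": "m1", "kind": "logistic", "outcome": "y",
             "covariates": ["lrs"], "cluster": "site_id"},
        ])
        assert set(out["model"]) == {"m1"}
        assert "coef" in out.columns
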