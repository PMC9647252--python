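import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lipidscore.preprocess import filter_missing, impute_min, zscore
from lipidscore.simulate import (CovidGenConfig, SEMConfig, TraumaGenConfig,
                                 generate_covid_cohort, generate_sem,
                                 generate_trauma_cohort)
from lipidscore.simulate.config import ConfigError
from lipidscore.simulate.sem import CycleError


class TestTraumaGenerator:
    def test_deterministic(self, small_trauma_cfg):
        m1, c1, _ = generate_trauma_cohort(small_trauma_cfg, 5)
        m2, c2, _ = generate_trauma_cohort(small_trauma_cfg, 5)
        pd.testing.assert_frame_equal(m1.values, m2.values)
        pd.testing.assert_frame_equal(c1.table, c2.table)

    def test_early_nonsurvivors_only_0h(self, small_trauma):
        _, cohort, _ = small_trauma
        early = cohort.table[cohort.table["outcome"] == "early_nonsurvivor"]
        assert set(early["timepoint"]) == {"0h"}

    def test_resolvers_have_three_timepoints(self, small_trauma):
        _, cohort, _ = small_trauma
        res = cohort.table[cohort.table["outcome"] == "resolving"]
        counts = res.groupby("subject_id")["timepoint"].nunique()
        assert (counts == 3).all()

    def test_passes_core_validation(self, small_trauma):
        matrix, cohort, _ = small_trauma
        # validation runs in constructors; chain the preprocessing stages
        z = zscore(impute_min(filter_missing(matrix)))
        assert z.z.shape[0] == matrix.values.shape[0]

    def test_global_0h_drop_deepest_in_early_nonsurvivors(self, small_trauma):
        matrix, cohort, _ = small_trauma
        m = impute_min(filter_missing(matrix))
        total = m.values.sum(axis=1)
        cdf = cohort.table.set_index("sample_id")
        means = {}
        for grp in ["healthy", "resolving", "early_nonsurvivor"]:
            tp = "HC" if grp == "healthy" else "0h"
            ids = cdf[(cdf["outcome"] == grp)
                      & (cdf["timepoint"] == tp)].index
            means[grp] = total.loc[ids].mean()
        assert means["early_nonsurvivor"] < means["resolving"] < means["healthy"]

    def test_planted_rise_at_72h(self, small_trauma):
        matrix, cohort, truth = small_trauma
        z = zscore(impute_min(filter_missing(matrix)))
        cdf = cohort.table.set_index("sample_id")
        at72 = cdf[cdf["timepoint"] == "72h"]
        nr = at72[at72["outcome"] == "non_resolving"].index
        rs = at72[at72["outcome"] == "resolving"].index
        planted = [s for s in truth.planted_pe if s in z.z.columns]
        diff = z.z.loc[nr, planted].mean().mean() - \
            z.z.loc[rs, planted].mean().mean()
        assert diff > 0.5

    def test_tp_attenuates_0h_drop(self, small_trauma):
        matrix, cohort, _ = small_trauma
        m = impute_min(filter_missing(matrix))
        total = m.values.sum(axis=1)
        cdf = cohort.table.set_index("sample_id")
        at0 = cdf[(cdf["timepoint"] == "0h") & (cdf["outcome"] != "healthy")]
        tp = total.loc[at0[at0["arm"] == "TP"].index].mean()
        sc = total.loc[at0[at0["arm"] == "standard_care"].index].mean()
        assert tp > sc

    def test_null_config_calibration(self):
        """No planted effects -> two-group KS test rejects at ~alpha."""
        cfg = TraumaGenConfig(
            n_per_cell={("resolving", "standard_care"): 25,
                        ("non_resolving", "standard_care"): 25},
            n_healthy=2,
            species_counts={"PE": 8, "CE": 4},
            drop0h={"resolving": 1.0, "non_resolving": 1.0,
                    "early_nonsurvivor": 1.0},
            drop24h={"resolving": 1.0, "non_resolving": 1.0},
            drop72h={"resolving": 1.0, "non_resolving": 1.0},
            rise72h=1.0, fall72h=1.0, decoy_fall72h=1.0, tp_attenuation=0.0,
            missing_rate=0.0, high_missing_frac=0.0,
            planted_other_counts={}, planted_down_count=0,
        )
        alpha = 0.05
        rejections = 0
        trials = 0
        for seed in range(60):
            matrix, cohort, truth = generate_trauma_cohort(cfg, seed)
            cdf = cohort.table.set_index("sample_id")
            at72 = cdf[cdf["timepoint"] == "72h"]
            a = at72[at72["outcome"] == "resolving"].index
            b = at72[at72["outcome"] == "non_resolving"].index
            col = matrix.values.columns[seed % matrix.values.shape[1]]
            # skip planted block columns (they share a latent factor)
            if col in truth.planted_pe:
                continue
            p = stats.ks_2samp(matrix.values.loc[a, col],
                               matrix.values.loc[b, col]).pvalue
            trials += 1
            rejections += p < alpha
        # binomial(trials, 0.05): expect ~3; bound far in the tail
        assert rejections <= stats.binom.ppf(0.999, trials, alpha)

    def test_effect_monotonicity(self, small_trauma_cfg):
        import dataclasses
        diffs = []
        for rise in [1.0, 1.5, 2.0, 3.0]:
            cfg = dataclasses.replace(small_trauma_cfg, rise72h=rise)
            matrix, cohort, truth = generate_trauma_cohort(cfg, 3)
            m = impute_min(filter_missing(matrix))
            cdf = cohort.table.set_index("sample_id")
            at72 = cdf[cdf["timepoint"] == "72h"]
            nr = at72[at72["outcome"] == "non_resolving"].index
            rs = at72[at72["outcome"] == "resolving"].index
            planted = [s for s in truth.planted_pe if s in m.values.columns]
            diffs.append(np.log(m.values.loc[nr, planted].mean()
                                / m.values.loc[rs, planted].mean()).mean())
        assert all(b > a for a, b in zip(diffs, diffs[1:]))

    def test_invalid_config_lists_fields(self):
        cfg = TraumaGenConfig(rise72h=-1.0, rho=1.5)
        with pytest.raises(ConfigError) as err:
            generate_trauma_cohort(cfg, 0)
        assert "rise72h" in str(err.value)
        assert "rho" in str(err.value)


class TestCovidGenerator:
    def test_deterministic(self):
        cfg = CovidGenConfig()
        m1, c1, _ = generate_covid_cohort(cfg, 4)
        m2, c2, _ = generate_covid_cohort(cfg, 4)
        pd.testing.assert_frame_equal(m1.values, m2.values)
        pd.testing.assert_frame_equal(c1.table, c2.table)

    def test_zero_effect_null(self):
        cfg = CovidGenConfig(pe_effect=1.0)
        diffs = []
        for seed in range(20):
            matrix, cohort, truth = generate_covid_cohort(cfg, seed)
            z = zscore(impute_min(filter_missing(matrix)))
            cdf = cohort.table.set_index("sample_id")
            sev = cdf[cdf["severity"] == "severe"].index
            non = cdf[cdf["severity"] == "non_severe"].index
            planted = [s for s in truth.planted_pe if s in z.z.columns]
            diffs.append(z.z.loc[sev, planted].mean().mean()
                         - z.z.loc[non, planted].mean().mean())
        # centered at zero across seeds
        assert abs(np.mean(diffs)) < 0.2

    def test_logistic_sign_recovery(self):
        from lipidscore.differential import _logit_fit
        cfg = CovidGenConfig()
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            matrix, cohort, truth = generate_covid_cohort(cfg, seed)
            z = zscore(impute_min(filter_missing(matrix)))
            cdf = cohort.table.set_index("sample_id")
            sel = cdf[cdf["severity"].isin(["severe", "non_severe"])]
            planted = [s for s in truth.planted_pe if s in z.z.columns]
            score = z.z.loc[sel.index, planted].mean(axis=1)
            y = (sel["severity"] == "severe").to_numpy(dtype=float)
            X = np.column_stack([np.ones(len(y)), score.to_numpy()])
            beta, _, _, sep = _logit_fit(X, y)
            hits += (not sep) and beta[1] > 0
        assert hits >= int(0.95 * n_seeds)

    def test_crp_lymphocyte_coupling(self, small_covid):
        _, cohort, _ = small_covid
        df = cohort.table
        sev = df[df["severity"] == "severe"]
        non = df[df["severity"] == "non_severe"]
        assert sev["crp"].mean() > non["crp"].mean()
        assert sev["lymphocyte"].mean() < non["lymphocyte"].mean()


class TestSEMGenerator:
    def test_deterministic(self):
        cfg = SEMConfig(variables=[("a", "continuous"), ("b", "continuous")],
                        edges=[("a", "b", 0.5)], n=100)
        d1, _ = generate_sem(cfg, 9)
        d2, _ = generate_sem(cfg, 9)
        pd.testing.assert_frame_equal(d1, d2)

    def test_cycle_detected(self):
        cfg = SEMConfig(variables=[("a", "continuous"), ("b", "continuous")],
                        edges=[("a", "b", 0.5), ("b", "a", 0.5)], n=10)
        with pytest.raises(CycleError):
            generate_sem(cfg, 0)

    def test_empty_edges_near_zero_correlation(self):
        cfg = SEMConfig(variables=[(f"v{i}", "continuous") for i in range(4)],
                        edges=[], n=5000)
        ok = 0
        n_seeds = 20
        for seed in range(n_seeds):
            df, _ = generate_sem(cfg, seed)
            r = np.corrcoef(df.to_numpy(), rowvar=False)
            off = r[np.triu_indices(4, 1)]
            ok += np.all(np.abs(off) < 0.05)
        assert ok >= int(0.95 * n_seeds)

    def test_chain_path_correlations(self):
        # X -> Y -> Z with weights 0.8: marginal r(X,Z) ~= 0.64 * sd ratio,
        # partial correlation given Y ~= 0
        cfg = SEMConfig(
            variables=[("x", "continuous"), ("y", "continuous"),
                       ("z", "continuous")],
            edges=[("x", "y", 0.8), ("y", "z", 0.8)], n=20000)
        df, _ = generate_sem(cfg, 42)
        x, y, z = df["x"], df["y"], df["z"]
        # closed form: corr(x,z) = 0.64*var(x)/ (sd(x) sd(z));
        # with unit noise sds: var(y)=1.64, var(z)=.64*1.64+1
        expected = 0.64 / np.sqrt(1.0) / np.sqrt(0.64 * 1.64 + 1.0)
        assert np.corrcoef(x, z)[0, 1] == pytest.approx(expected, abs=0.03)
        resx = x - np.polyval(np.polyfit(y, x, 1), y)
        resz = z - np.polyval(np.polyfit(y, z, 1), y)
        assert abs(np.corrcoef(resx, resz)[0, 1]) < 0.03

    def test_binary_child_logistic(self):
        cfg = SEMConfig(variables=[("x", "continuous"), ("t", "binary")],
                        edges=[("x", "t", 2.0)], n=4000)
        df, _ = generate_sem(cfg, 3)
        assert set(np.unique(df["t"])) == {0.0, 1.0}
        # monotone relationship
        hi = df[df["x"] > 1]["t"].mean()
        lo = df[df["x"] < -1]["t"].mean()
        assert hi > 0.8 > 0.2 > lo
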