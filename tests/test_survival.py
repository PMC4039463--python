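"""Survival cohort construction, KM, log-rank, ROC cutoff, Cox, Spearman."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import cnadose as cd
from cnadose.survival import (
    SurvivalCohort, build_cohort, km_estimate, logrank_test,
    roc_burden_cutoff, cox_adjusted, spearman_colinearity, figo_rank,
)


def make_cohort(times, events, stages=None, samples=None) -> SurvivalCohort:
    n = len(times)
    samples = samples or [f"p{i}" for i in range(n)]
    stages = stages or ["IB1"] * n
    data = pd.DataFrame({"sample": samples, "time": times, "event": events,
                         "stage": stages,
                         "figo_rank": [figo_rank(s) for s in stages]})
    return SurvivalCohort(data=data, n_excluded_untreated=0)


class TestBuildCohort:
    def test_printed_clinical_table_cohort(self, table2):
        cn = table2[table2["analysis"].str.contains("CN")]
        cohort = build_cohort(cn)
        assert cohort.n == 28
        assert cohort.n_excluded_untreated == 3
        assert cohort.survival_rate == pytest.approx(64.3, abs=0.05)
        assert round(cohort.mean_time_to_death) == 19

    def test_death_of_unknown_cause_censored(self, table2):
        cohort = build_cohort(table2[table2["sample"] == "R221"])
        assert cohort.data["event"].iloc[0] == 0

    def test_stage_specific_survival_rates(self, table2):
        cn = table2[table2["analysis"].str.contains("CN")]
        cohort = build_cohort(cn)
        merged = cohort.data["stage"].str.replace(r"^IV[AB]$", "IV",
                                                  regex=True)
        rates = {s: 100 * (1 - sub["event"].mean())
                 for s, sub in cohort.data.groupby(merged)}
        assert rates["IB1"] == pytest.approx(75.0)
        assert rates["IB2"] == pytest.approx(100.0)
        assert rates["IIB"] == pytest.approx(100.0)
        assert rates["IIIB"] == pytest.approx(44.4, abs=0.05)
        assert rates["IV"] == pytest.approx(0.0)

    def test_all_untreated_warns_and_empties(self):
        clinical = pd.DataFrame({
            "sample": ["a"], "stage": ["IB1"], "followup_months": [10],
            "status": ["alive"], "treatment": ["UNTREATED"]})
        with pytest.warns(UserWarning, match="untreated"):
            cohort = build_cohort(clinical)
        assert cohort.n == 0

    def test_missing_followup_names_patient(self):
        clinical = pd.DataFrame({
            "sample": ["ok", "bad"], "stage": ["IB1", "IB1"],
            "followup_months": [10, None], "status": ["alive", "alive"],
            "treated": [True, True]})
        with pytest.raises(ValueError, match="bad"):
            build_cohort(clinical)


class TestKaplanMeier:
    def test_no_events_survival_stays_one(self):
        cohort = make_cohort([5, 10, 15], [0, 0, 0])
        km = km_estimate(cohort)["all"]
        assert len(km.event_times) == 0
        assert km.survival_at(100) == 1.0

    def test_six_patient_worked_example(self):
        # times 1, 2+, 3, 4, 5+, 6 with deaths at 1, 3, 4, 6:
        # S = 5/6, then x3/4, x2/3, x0
        cohort = make_cohort([1, 2, 3, 4, 5, 6], [1, 0, 1, 1, 0, 1])
        km = km_estimate(cohort)["all"]
        expected = [5 / 6, 5 / 6 * 3 / 4, 5 / 6 * 3 / 4 * 2 / 3, 0.0]
        assert np.allclose(km.survival, expected)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(0)
        times = rng.integers(1, 40, 25)
        cohort = make_cohort(times, [1] * 25)
        km = km_estimate(cohort)["all"]
        for t in np.unique(times):
            assert km.survival_at(t) == pytest.approx((times > t).mean())


class TestLogrank:
    def test_identical_groups_give_null_statistic(self):
        times = [3, 5, 7, 9]
        events = [1, 0, 1, 1]
        cohort = make_cohort(times * 2, events * 2)
        groups = pd.Series(["a"] * 4 + ["b"] * 4,
                           index=cohort.data["sample"])
        chi2, df, p = logrank_test(cohort, groups)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 1
        assert p == pytest.approx(1.0)

    def test_single_group_rejected(self):
        cohort = make_cohort([1, 2], [1, 1])
        groups = pd.Series(["a", "a"], index=cohort.data["sample"])
        with pytest.raises(ValueError):
            logrank_test(cohort, groups)

    def test_matches_permutation_null_on_small_cohort(self):
        rng = np.random.default_rng(1)
        times = rng.integers(1, 30, 12)
        events = rng.integers(0, 2, 12)
        labels = np.array(["a"] * 6 + ["b"] * 6)
        cohort = make_cohort(times, events)
        groups = pd.Series(labels, index=cohort.data["sample"])
        chi2_obs, _, p_asym = logrank_test(cohort, groups)
        n_mc = 2000
        hits = 0
        for _ in range(n_mc):
            perm = pd.Series(rng.permutation(labels),
                             index=cohort.data["sample"])
            chi2, _, _ = logrank_test(cohort, perm)
            hits += chi2 >= chi2_obs - 1e-12
        p_mc = hits / n_mc
        se = np.sqrt(p_mc * (1 - p_mc) / n_mc)
        assert abs(p_asym - p_mc) <= 2 * se + 0.02

    def test_invariant_to_time_shift(self):
        rng = np.random.default_rng(2)
        times = rng.integers(1, 50, 16)
        events = rng.integers(0, 2, 16)
        labels = pd.Series(["a"] * 8 + ["b"] * 8,
                           index=[f"p{i}" for i in range(16)])
        c1 = make_cohort(times, events)
        c2 = make_cohort(times + 100, events)
        assert logrank_test(c1, labels)[0] == pytest.approx(
            logrank_test(c2, labels)[0])

    def test_power_against_burden_effect_at_defaults(self):
        # burden-linked hazard at generator defaults: low vs high burden
        # groups separate in most replicates
        from cnadose.burden import group_by_burden
        hits, total = 0, 120
        for i in range(total):
            cfg = cd.CohortConfig(n_tumors=30, n_genes=0,
                                  marker_spacing=500_000)
            cohort = cd.generate_cohort(cfg, seed=5000 + i)
            b = cohort.truth.burden_pct.rename("pct_total").reset_index() \
                .rename(columns={"index": "sample"})
            groups = group_by_burden(b)
            keep = groups[groups.isin(["low", "high"])]
            sc = build_cohort(cohort.clinical)
            sub = sc.data[sc.data["sample"].isin(keep.index)]
            sc2 = SurvivalCohort(data=sub.reset_index(drop=True),
                                 n_excluded_untreated=0)
            try:
                _, _, p = logrank_test(sc2, keep)
            except ValueError:
                continue
            hits += p < 0.05
        assert hits / total > 0.8


class TestRocCutoff:
    def test_perfect_separation_reaches_unit_youden(self):
        burdens = [1, 2, 3, 10, 11, 12]
        events = [0, 0, 0, 1, 1, 1]
        res = roc_burden_cutoff(burdens, events)
        assert res["youden_j"] == pytest.approx(1.0)
        assert res["cutoff"] == 10

    def test_equals_exhaustive_scan(self):
        rng = np.random.default_rng(3)
        burdens = rng.uniform(0, 30, 40)
        events = rng.integers(0, 2, 40)
        res = roc_burden_cutoff(burdens, events)
        best_j = max(
            ((events[burdens >= c] == 1).sum() / events.sum())
            + ((events[burdens < c] == 0).sum() / (events == 0).sum()) - 1
            for c in np.unique(burdens))
        assert res["youden_j"] == pytest.approx(best_j)

    def test_invariant_to_patient_order(self):
        rng = np.random.default_rng(4)
        burdens = rng.uniform(0, 30, 20)
        events = rng.integers(0, 2, 20)
        perm = rng.permutation(20)
        assert roc_burden_cutoff(burdens, events) == \
            roc_burden_cutoff(burdens[perm], events[perm])

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_burden_cutoff([1, 2, 3], [0, 0, 0])

    def test_printed_cohort_high_risk_split(self, table1, table2):
        cn = table2[table2["analysis"].str.contains("CN")]
        cohort = build_cohort(cn)
        joined = cohort.data.merge(
            table1.rename(columns={"tumor": "sample"}), on="sample")
        res = roc_burden_cutoff(joined["pct_genome"], joined["event"])
        assert res["n_high"] == 7
        assert res["mean_high"] == pytest.approx(22.2, abs=0.05)
        high = joined[joined["pct_genome"] >= res["cutoff"]]
        assert 100 * high["event"].mean() == pytest.approx(71.4, abs=0.05)


class TestCox:
    def test_matches_hand_derived_score_root(self):
        # 4 patients, binary covariate, 2 events, no ties:
        # the partial-likelihood score vanishes at beta = ln(sqrt(2))
        cohort = make_cohort([1, 2, 3, 4], [1, 1, 0, 0])
        cov = pd.DataFrame({"x": [1.0, 0.0, 1.0, 0.0]},
                           index=cohort.data["sample"])
        out = cox_adjusted(cohort, cov)
        assert out.loc["x", "coef"] == pytest.approx(np.log(np.sqrt(2)),
                                                     abs=1e-4)

    def test_zero_variance_covariate_rejected(self):
        cohort = make_cohort([1, 2, 3, 4], [1, 1, 0, 0])
        cov = pd.DataFrame({"x": [1.0, 1.0, 1.0, 1.0]},
                           index=cohort.data["sample"])
        with pytest.raises(ValueError, match="zero-variance"):
            cox_adjusted(cohort, cov)

    def test_null_covariate_wald_p_uniform(self):
        rng = np.random.default_rng(5)
        ps = []
        for _ in range(100):
            n = 60
            times = rng.exponential(20, n)
            censor = rng.uniform(10, 40, n)
            obs = np.minimum(times, censor)
            events = (times <= censor).astype(int)
            cohort = make_cohort(obs, events)
            cov = pd.DataFrame({"x": rng.normal(0, 1, n)},
                               index=cohort.data["sample"])
            ps.append(cox_adjusted(cohort, cov).loc["x", "p"])
        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestSpearman:
    def test_perfect_rank_agreement(self):
        ranks = [0, 1, 2, 3, 4]
        measures = pd.DataFrame({"m": [10, 20, 30, 40, 50]})
        out = spearman_colinearity(ranks, measures)
        assert out.loc["m", "rho"] == pytest.approx(1.0)

    def test_equals_pearson_on_midranks(self):
        rng = np.random.default_rng(6)
        x = rng.integers(0, 5, 15).astype(float)
        y = rng.normal(0, 1, 15)
        out = spearman_colinearity(x, pd.DataFrame({"m": y}))
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        assert out.loc["m", "rho"] == pytest.approx(sps.pearsonr(rx, ry)[0])

    def test_constant_measure_flagged(self):
        out = spearman_colinearity([0, 1, 2], pd.DataFrame({"m": [5, 5, 5]}))
        assert out.loc["m", "constant"]

    def test_printed_cohort_figo_burden_colinearity(self, table1, table2):
        cn = table2[table2["analysis"].str.contains("CN")]
        cohort = build_cohort(cn)
        joined = cohort.data.merge(
            table1.rename(columns={"tumor": "sample"}), on="sample")
        out = spearman_colinearity(joined["figo_rank"],
                                   joined[["pct_genome"]])
        # positive burden-stage co-linearity in the printed cohort
        assert out.loc["pct_genome", "rho"] > 0.3
        assert out.loc["pct_genome", "p"] < 0.05
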