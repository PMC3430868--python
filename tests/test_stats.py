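"""Stage/treatment statistics: averaging, ANOVA, Dunnett, percent change."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from vmrpipe import (
    arm_means,
    percent_change,
    stage_anova,
    summarize_by_stage,
    treatment_comparison,
)


def table_from(rows):
    return pd.DataFrame(
        rows,
        columns=["rat_id", "group", "stage", "arm", "session_index",
                 "volume_ml", "censored"],
    )


def baseline_row(rat, stage, vol, group="ENDO", idx=0, censored=False):
    return (rat, group, stage, "baseline", idx, vol, censored)


class TestSummarize:
    def test_two_sessions_average(self):
        t = table_from([baseline_row("r1", "P", 0.5), baseline_row("r1", "P", 0.7, idx=1)])
        s = summarize_by_stage(t)
        assert s.loc[0, "mean_ml"] == pytest.approx(0.6)
        assert s.loc[0, "n_sessions"] == 2

    def test_single_session_is_itself(self):
        s = summarize_by_stage(table_from([baseline_row("r1", "E", 0.42)]))
        assert s.loc[0, "mean_ml"] == 0.42

    def test_censored_excluded_and_counted(self):
        t = table_from([baseline_row("r1", "P", 0.5),
                        baseline_row("r1", "P", 1.0, idx=1, censored=True)])
        s = summarize_by_stage(t)
        assert s.loc[0, "mean_ml"] == 0.5
        assert s.loc[0, "n_censored"] == 1
        s_cap = summarize_by_stage(t, censored_policy="cap")
        assert s_cap.loc[0, "mean_ml"] == pytest.approx(0.75)

    def test_matches_groupby_oracle(self):
        rng = np.random.default_rng(8)
        rows = [baseline_row(f"r{i}", s, rng.uniform(0.2, 0.9), idx=j)
                for i in range(5) for s in ("DI", "DII", "P", "E") for j in range(3)]
        t = table_from(rows)
        s = summarize_by_stage(t).set_index(["rat_id", "stage"])["mean_ml"]
        for (rat, stage), val in s.items():
            manual = t[(t.rat_id == rat) & (t.stage == stage)]["volume_ml"].mean()
            assert val == pytest.approx(manual)


class TestStageAnova:
    def _summary(self, stage_values, n_rats=6, jitter=None):
        rows = []
        for i in range(n_rats):
            for s, v in stage_values.items():
                dv = v if jitter is None else v + jitter[i]
                rows.append({"rat_id": f"r{i}", "group": "ENDO", "stage": s,
                             "mean_ml": dv, "n_sessions": 2, "n_censored": 0})
        return pd.DataFrame(rows)

    def test_identical_stage_vectors_give_null_f(self):
        rng = np.random.default_rng(1)
        jit = rng.normal(0, 0.05, 6)
        summary = self._summary({"DI": 0.5, "DII": 0.5, "P": 0.5, "E": 0.5},
                                jitter=jit)
        res = stage_anova(summary, "ENDO")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_textbook_formula(self):
        """One-way F computed from explicit between/within sums of squares."""
        rng = np.random.default_rng(2)
        summary = self._summary({"DI": 0.55, "DII": 0.57, "P": 0.45, "E": 0.58})
        summary["mean_ml"] += rng.normal(0, 0.04, len(summary))
        res = stage_anova(summary, "ENDO")
        groups = [g["mean_ml"].to_numpy() for _, g in summary.groupby("stage")]
        grand = np.concatenate(groups).mean()
        ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        k, n = len(groups), sum(len(g) for g in groups)
        f = (ssb / (k - 1)) / (ssw / (n - k))
        p = scipy.stats.f.sf(f, k - 1, n - k)
        assert res.statistic == pytest.approx(f, abs=1e-6)
        assert res.p_value == pytest.approx(p, abs=1e-6)
        assert res.posthoc is not None and len(res.posthoc) == 6

    def test_rm_design_detects_within_rat_stage_effect(self):
        rng = np.random.default_rng(3)
        jit = rng.normal(0, 0.2, 8)  # large rat effect masks the stage effect
        summary = self._summary({"DI": 0.55, "DII": 0.56, "P": 0.45, "E": 0.57},
                                n_rats=8, jitter=jit)
        summary["mean_ml"] += rng.normal(0, 0.01, len(summary))
        oneway = stage_anova(summary, "ENDO", design="oneway")
        rm = stage_anova(summary, "ENDO", design="rm")
        assert rm.p_value < 1e-6  # rat-as-subject removes the rat variance
        assert rm.p_value < oneway.p_value
        # cross-check the closed-form F against statsmodels' AnovaRM
        from statsmodels.stats.anova import AnovaRM
        ref = AnovaRM(summary, depvar="mean_ml", subject="rat_id",
                      within=["stage"]).fit().anova_table.iloc[0]
        assert rm.statistic == pytest.approx(float(ref["F Value"]), rel=1e-9)
        assert rm.p_value == pytest.approx(float(ref["Pr > F"]), rel=1e-9)
        assert rm.df == (float(ref["Num DF"]), float(ref["Den DF"]))

    def test_invariant_to_rat_relabeling(self):
        summary = self._summary({"DI": 0.55, "DII": 0.57, "P": 0.45, "E": 0.58},
                                jitter=np.linspace(-0.03, 0.03, 6))
        relabeled = summary.copy()
        relabeled["rat_id"] = relabeled["rat_id"].map(
            lambda r: f"x{int(r[1:]) * 7 % 13}")
        a = stage_anova(summary, "ENDO")
        b = stage_anova(relabeled, "ENDO")
        assert a.statistic == pytest.approx(b.statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_insufficient_replication_rejected(self):
        summary = self._summary({"DI": 0.5, "P": 0.4}, n_rats=1)
        with pytest.raises(ValueError):
            stage_anova(summary, "ENDO")


class TestTreatmentComparison:
    def test_identical_arms_give_t0_p1(self):
        arms = pd.DataFrame({"baseline": [0.5, 0.6, 0.55],
                             "vehicle_ip": [0.5, 0.6, 0.55]},
                            index=["r1", "r2", "r3"])
        res = treatment_comparison(arms)
        assert res.test == "paired t-test"
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_two_arms_dispatch_paired_t(self):
        arms = pd.DataFrame({"baseline": [0.5, 0.6, 0.55, 0.52],
                             "indo10_ip": [0.9, 1.0, 0.95, 0.93]},
                            index=list("abcd"))
        res = treatment_comparison(arms)
        t, p = scipy.stats.ttest_rel(arms["indo10_ip"], arms["baseline"])
        assert res.test == "paired t-test"
        assert res.statistic == pytest.approx(t)
        assert res.p_value == pytest.approx(p)

    def test_three_arms_dispatch_dunnett(self):
        arms = pd.DataFrame({
            "baseline": [0.45, 0.52, 0.48, 0.50, 0.47, 0.49],
            "vehicle_ip": [0.55, 0.60, 0.52, 0.58, 0.54, 0.57],
            "indo10_ip": [0.80, 0.92, 0.85, 0.88, 0.79, 0.90],
        })
        res = treatment_comparison(arms)
        assert res.test == "ANOVA + Dunnett"
        assert res.posthoc is not None and len(res.posthoc) == 2

    def test_dunnett_matches_independent_reference(self):
        """Fixture checked against the many-to-one comparison implemented in
        R's multcomp::glht (Dunnett contrasts on a one-way fit); reference
        t statistics 3.4486387 / 17.0899206, adjusted p 0.006726 / <1e-8."""
        arms = pd.DataFrame({
            "baseline": [0.45, 0.52, 0.48, 0.50, 0.47, 0.49],
            "vehicle_ip": [0.55, 0.60, 0.52, 0.58, 0.54, 0.57],
            "indo10_ip": [0.80, 0.92, 0.85, 0.88, 0.79, 0.90],
        })
        res = treatment_comparison(arms)
        by = dict(zip(res.posthoc["comparison"], res.posthoc["statistic"]))
        assert by["vehicle_ip vs baseline"] == pytest.approx(3.4486387, abs=1e-5)
        assert by["indo10_ip vs baseline"] == pytest.approx(17.0899206, abs=1e-5)
        pv = dict(zip(res.posthoc["comparison"], res.posthoc["p"]))
        assert pv["vehicle_ip vs baseline"] == pytest.approx(0.006726, abs=5e-3)
        assert pv["indo10_ip vs baseline"] < 1e-6
        # decision at alpha=0.05: both arms differ from control
        assert (res.posthoc["p"] < 0.05).all()

    def test_missing_control_rejected(self):
        arms = pd.DataFrame({"vehicle_ip": [0.5], "indo10_ip": [0.9]})
        with pytest.raises(ValueError, match="control"):
            treatment_comparison(arms)


class TestPercentChange:
    def test_no_change(self):
        pre = pd.Series([0.5, 0.6], index=["a", "b"])
        est = percent_change(pre, pre.copy())
        assert est.mean_percent == 0.0 and est.sem_percent == 0.0

    def test_doubling_gives_plus_100(self):
        pre = pd.Series([0.4, 0.5, 0.6], index=list("abc"))
        est = percent_change(pre, 2 * pre)
        assert est.mean_percent == pytest.approx(100.0)
        assert est.sem_percent == pytest.approx(0.0, abs=1e-9)

    def test_hand_arithmetic(self):
        pre = pd.Series([1.0, 1.0, 1.0], index=list("abc"))
        post = pd.Series([1.1, 1.2, 1.3], index=list("abc"))
        est = percent_change(pre, post)
        assert est.mean_percent == pytest.approx(20.0)
        assert est.sem_percent == pytest.approx(5.7735, abs=1e-3)
        assert est.n == 3

    def test_scale_invariance(self):
        rng = np.random.default_rng(6)
        pre = pd.Series(rng.uniform(0.3, 0.7, 10))
        post = pre * rng.uniform(1.5, 2.2, 10)
        a = percent_change(pre, post)
        b = percent_change(3.7 * pre, 3.7 * post)
        assert a.mean_percent == pytest.approx(b.mean_percent)
        assert a.sem_percent == pytest.approx(b.sem_percent)

    def test_zero_pre_rejected(self):
        with pytest.raises(ValueError):
            percent_change(pd.Series([0.0], index=["a"]),
                           pd.Series([0.5], index=["a"]))

    def test_unpaired_rats_rejected(self):
        with pytest.raises(ValueError):
            percent_change(pd.Series([0.5], index=["a"]),
                           pd.Series([0.6], index=["b"]))


class TestArmMeans:
    def test_wide_table_per_rat(self):
        t = table_from([
            baseline_row("r1", "P", 0.4), baseline_row("r1", "P", 0.6, idx=1),
            ("r1", "ENDO", "P", "indo10_ip", 2, 0.9, False),
        ])
        wide = arm_means(t)
        assert wide.loc["r1", "baseline"] == pytest.approx(0.5)
        assert wide.loc["r1", "indo10_ip"] == pytest.approx(0.9)
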