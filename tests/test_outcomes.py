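"""Survival analysis: interval construction, Cox oracle, Simon-Makuch, stats."""

import numpy as np
import pandas as pd
import pytest
from lifelines import KaplanMeierFitter
from scipy.optimize import minimize_scalar

from fontanflow import outcomes as oc, phantom as ph


def _assign(rows):
    return pd.DataFrame(rows, columns=["patient_id", "scan_time_yr", "cluster"])


class TestBuildIntervals:
    def test_single_exam_spans_follow_up(self):
        table = oc.build_intervals(
            _assign([("p1", 0.0, "A")]),
            pd.DataFrame({"patient_id": ["p1"], "time": [7.5], "event": [1]}))
        assert len(table) == 1
        row = table.iloc[0]
        assert (row["start"], row["stop"], row["event"], row["cluster"]) == \
            (0.0, 7.5, 1, "A")

    def test_cluster_switch_creates_two_rows(self):
        table = oc.build_intervals(
            _assign([("p1", 0.0, "A"), ("p1", 2.0, "B")]),
            pd.DataFrame({"patient_id": ["p1"], "time": [5.0], "event": [1]}))
        assert len(table) == 2
        first, second = table.iloc[0], table.iloc[1]
        assert (first["start"], first["stop"], first["cluster"],
                first["event"]) == (0.0, 2.0, "A", 0)
        assert (second["start"], second["stop"], second["cluster"],
                second["event"]) == (2.0, 5.0, "B", 1)

    def test_event_before_first_exam_rejected(self):
        table = oc.build_intervals(
            _assign([("p1", 0.0, "A")]),
            pd.DataFrame({"patient_id": ["p1"], "time": [0.0], "event": [1]}))
        assert len(table) == 0
        assert table.attrs["rejected"]

    def test_durations_sum_to_follow_up(self):
        table = oc.build_intervals(
            _assign([("p1", 0.0, "A"), ("p1", 1.0, "B"), ("p1", 3.0, "A")]),
            pd.DataFrame({"patient_id": ["p1"], "time": [6.0], "event": [0]}))
        assert (table["stop"] - table["start"]).sum() == pytest.approx(6.0)


def _sim_table(hr=1.0, n=300, seed=0):
    """Two-cluster cohort with a known hazard ratio, single exam each."""
    labels = np.repeat([0, 1], n)
    out = ph.generate_outcomes(labels, hazards=[0.05, 0.05 * hr],
                               censor_rate=0.02, follow_up=15.0, seed=seed)
    assign = pd.DataFrame({"patient_id": out["patient_id"],
                           "scan_time_yr": 0.0, "cluster": labels})
    return oc.build_intervals(assign, out)


class TestCoxFit:
    def test_matches_brute_force_partial_likelihood(self):
        table = _sim_table(hr=2.5, n=60, seed=1)
        res = oc.cox_tv_fit(table, reference=0)
        x = (table["cluster"] == 1).to_numpy(float)
        stop = table["stop"].to_numpy()
        event = table["event"].to_numpy().astype(bool)
        assert len(np.unique(stop[event])) == event.sum()  # tie-free

        def neg_pl(beta):
            ll = 0.0
            for t in stop[event]:
                at_risk = (table["start"].to_numpy() < t) & (stop >= t)
                xi = x[(stop == t) & event][0]
                ll += beta * xi - np.log(np.exp(beta * x[at_risk]).sum())
            return -ll

        best = minimize_scalar(neg_pl, bounds=(-3, 3), method="bounded",
                               options={"xatol": 1e-10})
        assert res.table["log_hr"].iloc[0] == pytest.approx(best.x, abs=1e-4)

    def test_single_cluster_rejected(self):
        table = _sim_table(n=30, seed=2)
        only = table[table["cluster"] == 0]
        with pytest.raises(ValueError, match="contrast"):
            oc.cox_tv_fit(only, reference=0)

    def test_no_events_rejected(self):
        table = _sim_table(n=30, seed=3)
        censored = table.assign(event=0)
        with pytest.raises(ValueError, match="event"):
            oc.cox_tv_fit(censored)

    def test_hazard_ratio_grid_uses_each_reference(self):
        table = _sim_table(hr=2.0, n=100, seed=4)
        grid = oc.hazard_ratio_grid(table)
        assert set(grid["reference"]) == {0, 1}
        hr01 = grid[(grid.reference == 0)]["hr"].iloc[0]
        hr10 = grid[(grid.reference == 1)]["hr"].iloc[0]
        assert hr01 == pytest.approx(1.0 / hr10, rel=1e-6)


class TestSimonMakuch:
    def test_reduces_to_kaplan_meier_without_switching(self):
        table = _sim_table(n=40, seed=5)
        sm = oc.simon_makuch(table, min_at_risk=1)
        for g in (0, 1):
            sub = table[table["cluster"] == g]
            km = KaplanMeierFitter().fit(sub["stop"], sub["event"])
            curve = sm[g]
            for _, row in curve.iterrows():
                km_s = float(km.survival_function_at_times(row["time"]).iloc[0])
                assert row["survival"] == pytest.approx(km_s, abs=1e-12)

    def test_small_group_truncated_at_origin(self):
        table = _sim_table(n=40, seed=6)
        nine = table[table["cluster"] == 0].head(9).copy()
        rest = table[table["cluster"] == 1]
        sm = oc.simon_makuch(pd.concat([nine, rest]), min_at_risk=10)
        assert len(sm[0]) == 1 and sm[0]["survival"].iloc[0] == 1.0

    def test_all_censored_gives_flat_curve(self):
        table = _sim_table(n=30, seed=7).assign(event=0)
        sm = oc.simon_makuch(table, min_at_risk=1)
        for curve in sm.values():
            assert (curve["survival"] == 1.0).all()

    def test_membership_follows_current_cluster(self):
        # one switching patient: at risk in B (not A) after the switch
        table = pd.DataFrame({
            "patient_id": ["p1", "p1"] + [f"q{i}" for i in range(12)],
            "start": [0.0, 2.0] + [0.0] * 12,
            "stop": [2.0, 8.0] + [10.0] * 12,
            "event": [0, 1] + [0] * 12,
            "cluster": ["A", "B"] + ["B"] * 12})
        sm = oc.simon_makuch(table, min_at_risk=1)
        assert (sm["A"]["survival"] == 1.0).all()
        assert sm["B"]["survival"].iloc[-1] < 1.0


class TestTransitions:
    def test_static_patients_are_fully_stable(self):
        a = _assign([("p1", 0, "A"), ("p1", 1, "A"),
                     ("p2", 0, "B"), ("p2", 2, "B")])
        t = oc.transition_stats(a)
        assert t.pct_same_first_last == 100.0
        assert t.pct_same_consecutive == 100.0

    def test_half_stable_first_to_last(self):
        a = _assign([("p1", 0, "A"), ("p1", 1, "A"),
                     ("p2", 0, "A"), ("p2", 1, "B")])
        t = oc.transition_stats(a)
        assert t.pct_same_first_last == 50.0

    def test_aba_counts_as_stable_endpoints_only(self):
        a = _assign([("p1", 0, "A"), ("p1", 1, "B"), ("p1", 2, "A")])
        t = oc.transition_stats(a)
        assert t.pct_same_first_last == 100.0
        assert t.pct_same_consecutive == 0.0
        assert t.n_transitions == 2

    def test_requires_a_multiscan_patient(self):
        with pytest.raises(ValueError):
            oc.transition_stats(_assign([("p1", 0, "A")]))


class TestGroupCompare:
    def test_null_groups_give_adjusted_ge_raw(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame({"g": np.repeat([0, 1, 2], 50),
                           "x": rng.normal(size=150)})
        rep = oc.group_compare(df, "g", continuous=["x"])
        dunn = rep["continuous"]["x"]["dunn"]
        assert (dunn["p_adj"] >= dunn["p"] - 1e-12).all()
        assert rep["continuous"]["x"]["p"] > 0.01

    def test_strong_shift_detected(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame({
            "g": np.repeat([0, 1], 200),
            "x": np.concatenate([rng.normal(0, 1, 200),
                                 rng.normal(2, 1, 200)])})
        rep = oc.group_compare(df, "g", continuous=["x"])
        assert rep["continuous"]["x"]["p"] < 1e-3

    def test_chi_square_on_imbalanced_table(self):
        df = pd.DataFrame({
            "g": ["a"] * 40 + ["b"] * 40,
            "c": ["x"] * 30 + ["y"] * 10 + ["x"] * 10 + ["y"] * 30})
        rep = oc.group_compare(df, "g", categorical=["c"])
        assert rep["categorical"]["c"]["p"] < 1e-3

    def test_tiny_group_excluded_with_note(self):
        df = pd.DataFrame({"g": ["a"] * 20 + ["b"] * 20 + ["c"],
                           "x": np.arange(41.0)})
        rep = oc.group_compare(df, "g", continuous=["x"])
        assert rep["excluded_groups"] == ["c"]
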