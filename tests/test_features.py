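import numpy as np
import pandas as pd
import pytest

import wardflag as wf
from wardflag import cohort, features
from wardflag.config import AGG_VITALS

T0 = pd.Timestamp("2021-03-01T00:00")


def obs_frame(rows):
    return pd.DataFrame(
        rows, columns=["encounter_id", "patient_id", "timestamp", "vital", "value", "level"]
    )


def mk_obs(eid, hours, vital, value):
    return (eid, "P" + eid, T0 + pd.Timedelta(hours=hours), vital, value, pd.NA)


class TestSlope:
    def test_printed_formula(self):
        t1, t2 = T0, T0 + pd.Timedelta(minutes=60)
        assert features.compute_slope(100, t1, 110, t2) == pytest.approx(10 / 60)

    def test_flat_pair_is_zero(self):
        assert features.compute_slope(97, T0, 97, T0 + pd.Timedelta(minutes=30)) == 0.0

    def test_coincident_times_give_missing(self):
        assert np.isnan(features.compute_slope(100, T0, 110, T0))


class TestWindowFeatures:
    def test_two_point_aggregates(self):
        obs = obs_frame([mk_obs("E1", 0, "SBP", 100.0), mk_obs("E1", 23, "SBP", 110.0)])
        t = T0 + pd.Timedelta(hours=23)
        row = features.compute_window_features(obs, t, 24.0, admission_time=T0,
                                               age=60, sex="male")
        assert row["SBP_min"] == 100 and row["SBP_max"] == 110
        assert row["SBP_mean"] == 105 and row["SBP_median"] == 105
        assert row["SBP_n_window"] == 2
        assert row["SBP_last"] == 110
        assert row["SBP_last_interval"] == 23 * 60
        assert row["SBP_slope"] == pytest.approx(10 / (23 * 60))
        assert row["SBP_std"] == pytest.approx(5.0)  # population formula
        assert row["los_min"] == 23 * 60

    def test_single_observation_degeneracies(self):
        obs = obs_frame([mk_obs("E1", 0, "HR", 80.0)])
        row = features.compute_window_features(obs, T0, 24.0, admission_time=T0)
        assert row["HR_std"] == 0.0
        assert np.isnan(row["HR_slope"]) and np.isnan(row["HR_last_interval"])
        assert np.isnan(row["SBP_mean"])  # vital absent from window -> missing

    def test_flags_reflect_window_presence(self):
        obs = obs_frame(
            [mk_obs("E1", 0, "HR", 80.0), mk_obs("E1", 1, "O2FLOW", 2.0),
             (
                 "E1", "PE1", T0 + pd.Timedelta(hours=2), "AVPU", np.nan, "Alert"
             )]
        )
        t = T0 + pd.Timedelta(hours=2)
        row = features.compute_window_features(obs, t, 24.0, admission_time=T0)
        assert row["O2_flow_flag"] == 1.0 and row["AVPU_flag"] == 1.0
        # 26 h later both fall outside the 24-h lookback
        obs2 = obs[obs["vital"] == "HR"]
        row2 = features.compute_window_features(obs2, t, 24.0, admission_time=T0)
        assert row2["O2_flow_flag"] == 0.0 and row2["AVPU_flag"] == 0.0

    def test_prediction_before_admission_is_fatal(self):
        obs = obs_frame([mk_obs("E1", 1, "HR", 80.0)])
        with pytest.raises(ValueError, match="admission"):
            features.compute_window_features(
                obs, T0, 24.0, admission_time=T0 + pd.Timedelta(hours=2)
            )

    def test_brute_force_recomputation(self):
        """Aggregates match a naive per-window scan on randomized encounters."""
        rng = np.random.default_rng(7)
        H = 24.0
        for _ in range(250):
            n = int(rng.integers(1, 25))
            hours = np.sort(rng.uniform(0, 72, n))
            vitals = rng.choice(AGG_VITALS, n)
            vals = rng.uniform(50, 150, n)
            obs = obs_frame([mk_obs("E1", h, v, x) for h, v, x in zip(hours, vitals, vals)])
            t = T0 + pd.Timedelta(hours=float(rng.uniform(0, 72)))
            row = features.compute_window_features(obs, t, H, admission_time=T0)
            for vital in set(vitals):
                in_w = [
                    (h, x)
                    for h, v, x in zip(hours, vitals, vals)
                    if v == vital and t - pd.Timedelta(hours=H) < T0 + pd.Timedelta(hours=h) <= t
                ]
                if not in_w:
                    assert np.isnan(row[f"{vital}_mean"])
                    assert row[f"{vital}_n_window"] == 0
                    continue
                seg = np.array([x for _, x in in_w])
                assert row[f"{vital}_min"] == pytest.approx(seg.min(), rel=1e-9)
                assert row[f"{vital}_max"] == pytest.approx(seg.max(), rel=1e-9)
                assert row[f"{vital}_mean"] == pytest.approx(seg.mean(), rel=1e-9)
                assert row[f"{vital}_median"] == pytest.approx(np.median(seg), rel=1e-9)
                assert row[f"{vital}_std"] == pytest.approx(seg.std(), abs=1e-9)
                assert row[f"{vital}_n_window"] == len(seg)
                assert row[f"{vital}_last"] == pytest.approx(seg[-1], rel=1e-9)

    def test_frequency_is_count_over_window_length(self, small_cohort):
        table = small_cohort["table"]
        H = small_cohort["config"].historical_window_h
        for v in AGG_VITALS:
            np.testing.assert_allclose(
                table[f"{v}_freq"] * H, table[f"{v}_n_window"], rtol=0, atol=1e-12
            )

    def test_translation_invariance(self):
        rng = np.random.default_rng(1)
        hours = np.sort(rng.uniform(0, 30, 12))
        obs = obs_frame([mk_obs("E1", h, "RR", 15 + rng.normal()) for h in hours])
        t = T0 + pd.Timedelta(hours=29)
        row1 = features.compute_window_features(obs, t, 24.0, admission_time=T0)
        shift = pd.Timedelta(days=40)
        obs2 = obs.copy()
        obs2["timestamp"] = obs2["timestamp"] + shift
        row2 = features.compute_window_features(
            obs2, t + shift, 24.0, admission_time=T0
        )
        for k, v in row1.items():
            if k == "los_min":
                assert row2[k] != v
                continue
            assert (np.isnan(v) and np.isnan(row2[k])) or row2[k] == pytest.approx(v)


class TestDesignMatrix:
    def _enc(self, eid="E1", los_h=48.0):
        return pd.DataFrame(
            [{
                "encounter_id": eid, "patient_id": "P" + eid, "admission_time": T0,
                "discharge_time": T0 + pd.Timedelta(hours=los_h),
                "age": 55.0, "sex": "female", "care_type": "Acute Care",
            }]
        )

    def test_one_row_per_nonflag_point(self):
        obs = obs_frame([mk_obs("E1", h, "SBP", 120.0) for h in (1, 2, 3)])
        flags = cohort.detect_red_flags(obs)
        tbl = wf.assemble_design_matrix(self._enc(), obs, flags, cohort_ids=["E1"])
        assert len(tbl) == 3

    def test_flagged_point_excluded(self):
        obs = obs_frame(
            [mk_obs("E1", 1, "SBP", 120.0), mk_obs("E1", 2, "SBP", 80.0),
             mk_obs("E1", 3, "SBP", 120.0)]
        )
        flags = cohort.detect_red_flags(obs)  # SBP 80 < 90 triggers
        tbl = wf.assemble_design_matrix(self._enc(), obs, flags, cohort_ids=["E1"])
        assert len(tbl) == 2
        assert tbl["label_2h"].tolist() == [1, 0]

    def test_empty_cohort_keeps_full_header(self):
        obs = obs_frame([])
        flags = cohort.detect_red_flags(obs_frame([]))
        tbl = wf.assemble_design_matrix(self._enc(), obs, flags, cohort_ids=[])
        assert len(tbl) == 0
        assert list(tbl.columns[:2]) == ["encounter_id", "time"]
        assert list(tbl.columns[2 : 2 + len(wf.FEATURE_COLUMNS)]) == wf.FEATURE_COLUMNS

    def test_schema_has_82_features_and_invariants_hold(self, small_cohort):
        table = small_cohort["table"]
        assert len(wf.FEATURE_COLUMNS) == 82
        for v in AGG_VITALS:
            sel = table[f"{v}_n_window"] > 0
            assert (table.loc[sel, f"{v}_min"] <= table.loc[sel, f"{v}_median"] + 1e-12).all()
            assert (table.loc[sel, f"{v}_median"] <= table.loc[sel, f"{v}_max"] + 1e-12).all()
            assert (table.loc[sel, f"{v}_std"] >= 0).all()
        assert (table["los_min"] >= 0).all()
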