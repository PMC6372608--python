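"""Outlier removal, FiO2 imputation and hourly-grid construction."""

import numpy as np
import pandas as pd
import pytest

from deepsofa.preprocessing import (
    FFILL,
    MEASURED,
    NORMAL,
    ZERO,
    CleaningRules,
    Fio2Table,
    NormalValues,
    build_hourly_grid,
    impute_fio2,
    remove_outliers,
)

from conftest import toy_encounter_row, toy_events


class TestRemoveOutliers:
    def test_range_rules(self):
        ev = toy_events(
            [("E1", "MAP", 1.0, 350.0), ("E1", "MAP", 2.0, 80.0),
             ("E1", "GCS", 1.0, 16.0), ("E1", "GCS", 2.0, 15.0)]
        )
        out, report = remove_outliers(ev)
        assert set(zip(out["variable"], out["value"])) == {("MAP", 80.0), ("GCS", 15.0)}
        assert report["MAP"]["range"] == 1
        assert report["GCS"]["range"] == 1

    def test_modified_zscore_mad_zero_fallback(self):
        # median 10, MAD 0 -> mean-AD fallback flags the 1000
        ev = toy_events([("E1", "creatinine", float(i), 10.0) for i in range(4)]
                        + [("E1", "creatinine", 5.0, 1000.0)])
        rules = CleaningRules(
            ranges={"creatinine": (0.0, 2000.0)},
            zscore_flags={"creatinine": True},
        )
        out, report = remove_outliers(ev, rules)
        assert report["creatinine"]["zscore"] == 1
        assert 1000.0 not in out["value"].to_numpy()

    def test_zero_spread_skips_screen(self):
        ev = toy_events([("E1", "creatinine", float(i), 1.0) for i in range(5)])
        rules = CleaningRules(
            ranges={"creatinine": (0.0, 20.0)}, zscore_flags={"creatinine": True}
        )
        out, report = remove_outliers(ev, rules)
        assert len(out) == 5
        assert report["creatinine"]["zscore"] == 0

    def test_zscore_hand_computed(self):
        # values 1..9 plus 100: med 5.5, MAD 2.5 -> z(100) = 0.6745*94.5/2.5 = 25.5
        vals = [float(v) for v in range(1, 10)] + [100.0]
        ev = toy_events([("E1", "platelets", float(i), v) for i, v in enumerate(vals)])
        rules = CleaningRules(
            ranges={"platelets": (0.0, 1000.0)}, zscore_flags={"platelets": True}
        )
        out, report = remove_outliers(ev, rules)
        assert report["platelets"]["zscore"] == 1
        assert out["value"].max() == 9.0

    def test_bad_range_config_rejected(self):
        with pytest.raises(ValueError, match="lo must be"):
            CleaningRules(ranges={"MAP": (5.0, 5.0)}, zscore_flags={})


class TestImputeFio2:
    def test_room_air(self):
        ev = toy_events([("E1", "o2_device", 1.0, 0.0)])
        out = impute_fio2(ev)
        fio2 = out[out["variable"] == "FiO2"]
        assert len(fio2) == 1
        assert fio2["value"].iloc[0] == 21.0

    def test_nasal_cannula_formula(self):
        # 21 + 4 * 2 L/min = 29%
        ev = toy_events(
            [("E1", "o2_device", 1.0, 1.0), ("E1", "o2_flow", 1.0, 2.0)]
        )
        out = impute_fio2(ev)
        assert out.loc[out["variable"] == "FiO2", "value"].iloc[0] == 29.0

    def test_clamped_to_physical_bound(self):
        table = Fio2Table(
            devices={"nasal_cannula": {"code": 1, "base": 21.0, "per_lpm": 30.0,
                                       "max": 150.0}}
        )
        ev = toy_events(
            [("E1", "o2_device", 1.0, 1.0), ("E1", "o2_flow", 1.0, 3.0)]
        )
        out = impute_fio2(ev, table)
        assert out.loc[out["variable"] == "FiO2", "value"].iloc[0] == 100.0

    def test_charted_fio2_not_overwritten(self):
        ev = toy_events(
            [("E1", "o2_device", 1.0, 1.0), ("E1", "o2_flow", 1.0, 2.0),
             ("E1", "FiO2", 1.0, 50.0)]
        )
        out = impute_fio2(ev)
        assert (out["variable"] == "FiO2").sum() == 1

    def test_passthrough_device_emits_nothing(self):
        ev = toy_events([("E1", "o2_device", 1.0, 5.0)])  # ventilator
        out = impute_fio2(ev)
        assert (out["variable"] == "FiO2").sum() == 0


class TestBuildHourlyGrid:
    def test_in_hour_mean(self):
        enc = toy_encounter_row(icu_los_hours=4.0)
        ev = toy_events(
            [("E1", "MAP", 2.2, 100.0), ("E1", "MAP", 2.9, 120.0)]
        )
        grid = build_hourly_grid(ev, enc)
        assert grid.values.loc[3, "MAP"] == 110.0
        assert grid.provenance.loc[3, "MAP"] == MEASURED

    def test_forward_fill(self):
        enc = toy_encounter_row(icu_los_hours=6.0)
        ev = toy_events([("E1", "creatinine", 1.5, 0.9)])
        grid = build_hourly_grid(ev, enc)
        assert grid.values.loc[5, "creatinine"] == 0.9
        assert grid.provenance.loc[5, "creatinine"] == FFILL

    def test_vasopressor_zero_fill(self):
        enc = toy_encounter_row(icu_los_hours=3.0)
        ev = toy_events([("E1", "MAP", 1.0, 80.0)])
        grid = build_hourly_grid(ev, enc)
        assert (grid.values["norepinephrine"] == 0).all()
        assert (grid.provenance["norepinephrine"] == ZERO).all()

    def test_normal_value_imputation_tagged(self):
        enc = toy_encounter_row(icu_los_hours=3.0)
        ev = toy_events([("E1", "MAP", 1.0, 80.0)])
        grid = build_hourly_grid(ev, enc)
        assert (grid.provenance["bilirubin"] == NORMAL).all()
        normals = NormalValues.default()
        assert (grid.values["bilirubin"] == normals["bilirubin"]).all()

    def test_offset_zero_lands_in_hour_one(self):
        enc = toy_encounter_row(icu_los_hours=2.0)
        ev = toy_events([("E1", "MAP", 0.0, 77.0)])
        grid = build_hourly_grid(ev, enc)
        assert grid.values.loc[1, "MAP"] == 77.0
        assert grid.provenance.loc[1, "MAP"] == MEASURED

    def test_urine_summed_not_averaged(self):
        enc = toy_encounter_row(icu_los_hours=2.0)
        ev = toy_events(
            [("E1", "urine", 0.5, 40.0), ("E1", "urine", 0.9, 60.0),
             ("E1", "MAP", 1.0, 80.0)]
        )
        grid = build_hourly_grid(ev, enc)
        assert grid.values.loc[1, "urine"] == 100.0

    def test_no_events_raises(self):
        enc = toy_encounter_row(icu_los_hours=3.0)
        with pytest.raises(ValueError, match="no usable events"):
            build_hourly_grid(toy_events([]), enc)


class TestGridProperties:
    def test_completeness_and_provenance(self, small_grids):
        for grid in list(small_grids.values())[:25]:
            assert not grid.values.isna().any().any()
            assert set(np.unique(grid.provenance.to_numpy())) <= {
                MEASURED, FFILL, ZERO, NORMAL
            }
            grid.validate()

    def test_urine_conservation(self, small_cohort, small_grids):
        """Measured hourly urine sums equal the cleaned in-stay event totals."""
        from deepsofa.preprocessing import impute_fio2, remove_outliers

        cleaned, _ = remove_outliers(impute_fio2(small_cohort.events))
        checked = 0
        for eid, grid in small_grids.items():
            raw = cleaned[
                (cleaned["encounter_id"] == eid) & (cleaned["variable"] == "urine")
            ]
            in_stay = raw[raw["offset_hours"] <= grid.n_hours]
            measured = grid.provenance["urine"] == MEASURED
            if measured.any():
                assert grid.values.loc[measured, "urine"].sum() == pytest.approx(
                    in_stay["value"].sum(), rel=1e-9
                )
                checked += 1
        assert checked > 10

    def test_truncation_causality(self, small_cohort):
        """First k rows of the grid never depend on events after hour k."""
        for eid in small_cohort.encounters["encounter_id"][:5]:
            enc = small_cohort.encounters.set_index(
                "encounter_id", drop=False
            ).loc[eid]
            ev = small_cohort.events_for(eid)
            full = build_hourly_grid(ev, enc)
            k = max(1, full.n_hours // 2)
            truncated = build_hourly_grid(
                ev[ev["offset_hours"] <= k], enc
            )
            pd.testing.assert_frame_equal(
                full.values.loc[:k], truncated.values.loc[:k]
            )

    def test_pipeline_determinism(self, small_cohort):
        from deepsofa.preprocessing import preprocess_cohort

        sub = small_cohort.subset(small_cohort.encounters["encounter_id"][:5])
        g1, _ = preprocess_cohort(sub)
        g2, _ = preprocess_cohort(sub)
        for eid in g1:
            pd.testing.assert_frame_equal(g1[eid].values, g2[eid].values)
            pd.testing.assert_frame_equal(g1[eid].provenance, g2[eid].provenance)
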