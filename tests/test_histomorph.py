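"""ASBMR parameter computation: worked examples, identities, recovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from skelphen import histomorph as hm
from skelphen import synthetic as syn


def _gp(rz=50.0, pz=100.0, hz=50.0):
    b = np.tile([0.0, rz, rz + pz, rz + pz + hz], (4, 1))
    return hm.GrowthPlateRaw(boundary_y_um=b,
                             cell_counts={"RZ": 20, "PZ": 60, "HZ": 20})


class TestGrowthPlate:
    def test_worked_example(self):
        res = hm.growth_plate_heights(_gp(50, 100, 50))
        assert res.total_um == pytest.approx(200.0)
        assert res.height_fractions_pct["RZ"] == pytest.approx(25.0)
        assert res.height_fractions_pct["PZ"] == pytest.approx(50.0)
        assert res.height_fractions_pct["HZ"] == pytest.approx(25.0)

    def test_mean_over_four_locations(self):
        b = np.array([
            [0, 40, 140, 190],
            [0, 60, 160, 210],
            [0, 50, 150, 200],
            [0, 50, 150, 200],
        ], dtype=float)
        raw = hm.GrowthPlateRaw(boundary_y_um=b, cell_counts={"RZ": 1, "PZ": 1, "HZ": 1})
        assert hm.growth_plate_heights(raw).heights_um["RZ"] == pytest.approx(50.0)

    def test_missing_location_rejected(self):
        with pytest.raises(ValueError, match="4 locations"):
            hm.GrowthPlateRaw(boundary_y_um=np.zeros((3, 4)),
                              cell_counts={"RZ": 1, "PZ": 1, "HZ": 1})

    def test_unordered_boundaries_rejected(self):
        b = np.tile([0.0, 100.0, 50.0, 200.0], (4, 1))
        with pytest.raises(ValueError, match="ordered"):
            hm.GrowthPlateRaw(boundary_y_um=b, cell_counts={"RZ": 1, "PZ": 1, "HZ": 1})

    def test_fractions_sum_to_100(self):
        _, gp = syn.gen_histomorph_tables(
            syn.HistomorphSimConfig(zone_jitter=5.0), seed=3)
        res = hm.growth_plate_heights(gp)
        assert sum(res.height_fractions_pct.values()) == pytest.approx(100.0, abs=1e-9)
        assert sum(res.cell_fractions_pct.values()) == pytest.approx(100.0, abs=1e-9)

    def test_jittered_recovery_unbiased(self):
        # DERIVED: 100 jittered sections, mean recovered height |bias| < 1%
        cfg = syn.HistomorphSimConfig(hz_height=60.0, zone_jitter=3.0)
        heights = []
        for seed in range(100):
            _, gp = syn.gen_histomorph_tables(cfg, seed=seed)
            heights.append(hm.growth_plate_heights(gp).heights_um["HZ"])
        assert abs(np.mean(heights) / 60.0 - 1) < 0.01


class TestOsteoclasts:
    def test_count_normalisation(self):
        rec = hm.HistomorphRecord(b_pm_mm=10.0, oc_count=5)
        assert hm.osteoclast_params(rec).oc_n_per_bpm == pytest.approx(0.5)

    def test_surface_percentage(self):
        rec = hm.HistomorphRecord(b_pm_mm=10.0, oc_count=3, oc_lengths_mm=(0.7, 0.5))
        assert hm.osteoclast_params(rec).oc_s_per_bpm_pct == pytest.approx(12.0)

    def test_coverage_exceeding_perimeter_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            hm.HistomorphRecord(b_pm_mm=1.0, oc_lengths_mm=(0.7, 0.5))

    def test_noisy_recovery(self):
        cfg = syn.HistomorphSimConfig(oc_coverage=0.12, trace_jitter=0.2)
        vals = []
        for seed in range(50):
            rec, _ = syn.gen_histomorph_tables(cfg, seed=seed)
            vals.append(hm.osteoclast_params(rec).oc_s_per_bpm_pct)
        assert np.mean(vals) == pytest.approx(12.0, abs=1.0)


class TestDynamicFormation:
    def test_definitional_example(self):
        # dL=2 mm, sL=0, B.Pm=10 mm, distances 4 um, interval 2 d
        rec = hm.HistomorphRecord(b_pm_mm=10.0, double_label_mm=2.0,
                                  interlabel_um=(4.0,) * 10, label_interval_days=2.0)
        res = hm.dynamic_formation(rec)
        assert res.ms_pct == pytest.approx(20.0)
        assert res.mar_um_per_day == pytest.approx(2.0)
        assert res.bfr_um_per_day == pytest.approx(0.4)

    def test_single_labels_count_half(self):
        rec = hm.HistomorphRecord(b_pm_mm=10.0, single_label_mm=2.0,
                                  double_label_mm=0.0)
        res = hm.dynamic_formation(rec)
        assert res.ms_pct == pytest.approx(10.0)
        assert res.mar_um_per_day is None
        assert "no_double_labels" in res.flags

    def test_pure_double_label_mode(self):
        rec = hm.HistomorphRecord(b_pm_mm=10.0, double_label_mm=1.0,
                                  single_label_mm=2.0, interlabel_um=(4.0,))
        assert hm.dynamic_formation(rec, pure_double_label=True).ms_pct == pytest.approx(10.0)
        assert hm.dynamic_formation(rec).ms_pct == pytest.approx(20.0)

    def test_bfr_identity_exact(self):
        for seed in range(20):
            cfg = syn.HistomorphSimConfig(interlabel_jitter=0.5, trace_jitter=0.2)
            rec, _ = syn.gen_histomorph_tables(cfg, seed=seed)
            res = hm.dynamic_formation(rec)
            assert res.bfr_um_per_day == (res.ms_pct / 100.0) * res.mar_um_per_day

    def test_mar_recovery_with_jitter(self):
        # DERIVED: 500 measurements of 3 um mean / 2 d -> 1.5 um/d within 5%
        cfg = syn.HistomorphSimConfig(interlabel_mean_um=3.0, interlabel_jitter=0.6,
                                      n_interlabel=500)
        rec, _ = syn.gen_histomorph_tables(cfg, seed=17)
        res = hm.dynamic_formation(rec)
        assert abs(res.mar_um_per_day / 1.5 - 1) < 0.05


class TestOsteoidAndResorption:
    def test_osteoid_surface(self):
        rec = hm.HistomorphRecord(b_pm_mm=10.0, osteoid_lengths_mm=(0.5,),
                                  osteoid_widths_um=(2.0, 4.0, 6.0))
        res = hm.osteoid_params(rec)
        assert res.os_per_bpm_pct == pytest.approx(5.0)
        assert res.o_th_um == pytest.approx(4.0)

    def test_negative_width_rejected(self):
        with pytest.raises(ValueError, match="widths"):
            hm.HistomorphRecord(b_pm_mm=10.0, osteoid_widths_um=(-1.0,))

    def test_resorption_extremes(self):
        assert hm.resorption_fraction(hm.HistomorphRecord(b_pm_mm=10.0)) == 0.0
        full = hm.HistomorphRecord(b_pm_mm=10.0, eroded_lengths_mm=(10.0,))
        assert hm.resorption_fraction(full) == pytest.approx(100.0)

    def test_eroded_recovery(self):
        cfg = syn.HistomorphSimConfig(eroded_coverage=0.25, trace_jitter=0.15)
        vals = [hm.resorption_fraction(syn.gen_histomorph_tables(cfg, seed=s)[0])
                for s in range(50)]
        assert np.mean(vals) == pytest.approx(25.0, abs=2.0)


class TestUnitsAndAveraging:
    @given(k=st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=25, deadline=None)
    def test_length_unit_equivariance(self, k):
        rec = hm.HistomorphRecord(b_pm_mm=10.0, oc_count=5, oc_lengths_mm=(1.2,),
                                  eroded_lengths_mm=(2.5,), double_label_mm=2.0,
                                  interlabel_um=(4.0,))
        scaled = hm.HistomorphRecord(
            b_pm_mm=10.0 * k, oc_count=5, oc_lengths_mm=(1.2 * k,),
            eroded_lengths_mm=(2.5 * k,), double_label_mm=2.0 * k,
            interlabel_um=(4.0,))
        assert hm.osteoclast_params(scaled).oc_s_per_bpm_pct == pytest.approx(
            hm.osteoclast_params(rec).oc_s_per_bpm_pct, rel=1e-12)
        assert hm.resorption_fraction(scaled) == pytest.approx(
            hm.resorption_fraction(rec), rel=1e-12)
        assert hm.dynamic_formation(scaled).ms_pct == pytest.approx(
            hm.dynamic_formation(rec).ms_pct, rel=1e-12)

    def test_section_replicates_averaged(self):
        r1 = hm.HistomorphRecord(b_pm_mm=10.0, oc_count=4, double_label_mm=1.0,
                                 interlabel_um=(4.0,))
        r2 = hm.HistomorphRecord(b_pm_mm=10.0, oc_count=6, double_label_mm=3.0,
                                 interlabel_um=(2.0,))
        avg = hm.average_records([r1, r2])
        assert avg["oc_n_per_bpm"] == pytest.approx(0.5)
        assert avg["ms_pct"] == pytest.approx(20.0)
        assert avg["mar_um_per_day"] == pytest.approx(1.5)
        # BFR identity holds on the averaged record too
        assert avg["bfr_um_per_day"] == pytest.approx(0.2 * 1.5)


class TestSegmentTables:
    def test_round_trip_csv(self, tmp_path):
        table = pd.DataFrame({
            "segment_id": range(5),
            "length_um": [1200.0, 500.0, 2000.0, 300.0, 6000.0],
            "flag": ["osteoclast", "osteoid", "double_label", "single_label", "plain"],
            "width_um": [None, 4.0, None, None, None],
            "interlabel_um": [None, None, 4.0, None, None],
        })
        path = tmp_path / "section.csv"
        table.to_csv(path, index=False)
        rec = hm.read_segment_table(path)
        assert rec.b_pm_mm == pytest.approx(10.0)
        assert rec.oc_count == 1
        assert hm.osteoclast_params(rec).oc_s_per_bpm_pct == pytest.approx(12.0)
        assert hm.dynamic_formation(rec).ms_pct == pytest.approx(21.5)

    def test_unknown_flag_rejected(self):
        table = pd.DataFrame({"segment_id": [0], "length_um": [1.0], "flag": ["bogus"]})
        with pytest.raises(ValueError, match="unknown segment flags"):
            hm.record_from_segments(table)
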