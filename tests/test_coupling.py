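"""Classification bands, intensity strata, bouts, occurrence and grouping."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clckit import coupling
from clckit.config import AnalysisConfig, CohortConfig
from clckit.experiments import analyze_synthetic_subject
from clckit.synthetic import generate_subject
from tests.conftest import make_records


class TestClassify:
    @pytest.mark.parametrize("sr,hr,expected_class,expected_dev", [
        (100, 100, "CLC", 0.0),
        (99, 100, "CLC", 0.01),          # deviation exactly at the 1% edge
        (90, 100, "weak_CLC", 0.10),     # exactly at the 10% edge
        (88, 100, "no_CLC", 0.12),
        (130, 100, "no_CLC", 0.30),
    ])
    def test_band_examples(self, sr, hr, expected_class, expected_dev):
        out = coupling.classify(make_records([(sr, hr)]))
        assert out["coupling_class"].iloc[0] == expected_class
        assert out["deviation"].iloc[0] == pytest.approx(expected_dev, abs=1e-15)

    @pytest.mark.parametrize("sr,expected", [
        (60, "light"), (99, "light"), (100, "moderate"),
        (129, "moderate"), (130, "vigorous"), (185, "vigorous"),
    ])
    def test_intensity_half_open_intervals(self, sr, expected):
        out = coupling.classify(make_records([(sr, 100)]))
        assert out["intensity_class"].iloc[0] == expected

    def test_ratio_matches_sr_over_hr(self):
        out = coupling.classify(make_records([(107, 93), (61, 181)]))
        assert np.allclose(out["ratio"], out["sr"] / out["hr"], atol=1e-12)

    def test_nonpositive_hr_is_a_hard_error(self):
        with pytest.raises(ValueError):
            coupling.classify(make_records([(100, 0)]))

    @given(st.lists(st.tuples(st.integers(60, 300),
                              st.floats(21, 249, allow_nan=False)),
                    min_size=1, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_classification_is_a_partition(self, pairs):
        out = coupling.classify(make_records(pairs))
        assert out["coupling_class"].isin(coupling.COUPLING_CLASSES).all()
        assert out["intensity_class"].isin(coupling.INTENSITY_CLASSES).all()

    def test_tightening_clc_band_never_adds_clc(self):
        records = make_records([(90 + i, 100) for i in range(21)])
        occs = []
        for thr in (0.02, 0.01, 0.005):
            config = AnalysisConfig(clc_threshold=thr)
            inst = coupling.classify(records, config)
            occs.append((inst["coupling_class"] == "CLC").sum())
        assert occs == sorted(occs, reverse=True)


class TestOccurrence:
    def test_direct_counts(self):
        inst = coupling.classify(make_records([(100, 100), (70, 100)]))
        occ = coupling.occurrence(inst).set_index("coupling_class")["percentage"]
        assert occ["CLC"] == 50.0 and occ["weak_CLC"] == 0.0 and occ["no_CLC"] == 50.0

    def test_all_clc(self):
        inst = coupling.classify(make_records([(100, 100)] * 4))
        occ = coupling.occurrence(inst).set_index("coupling_class")["percentage"]
        assert occ["CLC"] == 100.0

    def test_percentages_sum_to_100_within_each_stratum(self):
        pairs = [(sr, 100) for sr in (60, 85, 99, 100, 101, 120, 130, 170)]
        inst = coupling.classify(make_records(pairs))
        occ = coupling.occurrence(inst, stratify_by_intensity=True)
        sums = occ.groupby("intensity_class")["percentage"].sum()
        assert np.allclose(sums, 100.0, atol=1e-9)

    def test_empty_instances_give_empty_summary(self):
        empty = coupling.classify(make_records([(100, 100)])).iloc[0:0]
        assert coupling.occurrence(empty).empty

    def test_noiseless_cohort_occurrence_matches_ground_truth(self):
        config = CohortConfig(n_subjects=2, days=14, seed=21,
                              couple_fraction=0.05).noiseless()
        for i in range(2):
            rep, truth = analyze_synthetic_subject(config, i)
            assert rep.clc_occurrence == pytest.approx(
                100 * truth.entrained_fraction, abs=1.0)


class TestBouts:
    def _bouts_for(self, minute_offsets, gap=60.0):
        t0 = pd.Timestamp("2023-01-02 10:00")
        records = pd.DataFrame({
            "timestamp": [t0 + pd.Timedelta(minutes=m) for m in minute_offsets],
            "sr": 100.0, "hr": 100.0,
        })
        inst = coupling.classify(records)
        return coupling.segment_bouts(inst, AnalysisConfig(gap_minutes=gap))

    def test_59_minute_gap_merges(self):
        assert len(self._bouts_for(list(range(11)) + [69])) == 1

    def test_60_minute_gap_splits(self):
        bouts = self._bouts_for(list(range(11)) + [70])
        assert len(bouts) == 2
        assert bouts["duration"].tolist() == [11.0, 1.0]

    def test_single_minute_is_a_one_minute_bout(self):
        bouts = self._bouts_for([0])
        assert bouts["duration"].tolist() == [1.0]

    def test_segmentation_is_order_stable(self):
        offsets = [0, 1, 2, 200, 201, 500]
        a = self._bouts_for(offsets)
        rng = np.random.default_rng(0)
        b = self._bouts_for(list(rng.permutation(offsets)))
        pd.testing.assert_frame_equal(a, b)

    def test_recovers_generator_schedule(self):
        config = CohortConfig(n_subjects=1, days=10, seed=13,
                              min_bout_spacing=130.0).noiseless()
        hr, sr, truth = generate_subject(config, 0)
        from clckit import ingest
        table = ingest.align_and_filter(ingest.minutely_hr(hr), sr)
        inst = coupling.classify(table)
        bouts = coupling.segment_bouts(inst)
        assert len(bouts) == len(truth.bouts)

    def test_start_hour_histogram(self):
        bouts = pd.DataFrame({"bout_class": ["CLC", "CLC"], "start_hour": [9, 18]})
        prof = coupling.time_of_day_profile(bouts)
        assert prof["fraction"].tolist() == [0.5, 0.5]

    def test_degenerate_start_hours(self):
        bouts = pd.DataFrame({"bout_class": ["weak_CLC"] * 3, "start_hour": [12] * 3})
        prof = coupling.time_of_day_profile(bouts)
        assert prof["fraction"].tolist() == [1.0] and prof["start_hour"].tolist() == [12]


class TestBoutDurations:
    def _bouts(self, rows):
        return pd.DataFrame(rows, columns=["bout_class", "duration"])

    def test_single_bout_median(self):
        out = coupling.bout_duration_by_class(self._bouts([("CLC", 10.0)]))
        assert out.loc[out["bout_class"] == "CLC", "median_duration"].iloc[0] == 10.0

    def test_median_of_three(self):
        out = coupling.bout_duration_by_class(
            self._bouts([("weak_CLC", 10.0), ("weak_CLC", 20.0), ("weak_CLC", 30.0)]))
        assert out["median_duration"].tolist() == [20.0]

    def test_absent_class_is_absent_not_zero(self):
        out = coupling.bout_duration_by_class(self._bouts([("no_CLC", 15.0)]))
        assert set(out["bout_class"]) == {"no_CLC"}

    def test_entrainment_in_long_bouts_orders_medians(self):
        """Restricting entrainment to long bouts makes coupled bouts longer."""
        config = CohortConfig(n_subjects=1, days=30, seed=3, couple_fraction=0.6,
                              entrain_min_bout_minutes=45.0).noiseless()
        rep, _ = analyze_synthetic_subject(config, 0)
        durations = rep.duration_by_class.set_index("bout_class")["median_duration"]
        assert durations["CLC"] > durations["no_CLC"]


class TestGrouping:
    def test_printed_subject_values(self):
        g = coupling.group_subject(6.84, 4.75)
        assert g.d_statistic == pytest.approx(2.09)
        assert g.group == "most_moderate"

    @pytest.mark.parametrize("occ_m,occ_v,expected", [
        (6.5, 5.0, "most_moderate"),     # D = 1.5 exactly
        (5.0, 6.5, "most_vigorous"),     # D = -1.5 exactly
        (5.0, 5.0, "constant"),
        (5.7, 4.5, "constant"),
    ])
    def test_boundaries(self, occ_m, occ_v, expected):
        assert coupling.group_subject(occ_m, occ_v).group == expected

    def test_rejects_out_of_range_percentages(self):
        with pytest.raises(ValueError):
            coupling.group_subject(-1.0, 50.0)


class TestBoutLabel:
    def test_strongest_class_with_min_share_wins(self):
        classes = pd.Series(["CLC"] * 2 + ["no_CLC"] * 8)
        assert coupling._bout_label(classes, 0.20) == "CLC"

    def test_falls_back_to_modal_class(self):
        classes = pd.Series(["CLC"] * 1 + ["no_CLC"] * 9)
        assert coupling._bout_label(classes, 0.20) == "no_CLC"

    def test_modal_tie_goes_to_stronger(self):
        # min_share of 1.0 is unattainable for either class -> modal path
        classes = pd.Series(["weak_CLC", "no_CLC"])
        assert coupling._bout_label(classes, 1.0) == "weak_CLC"
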