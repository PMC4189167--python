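"""Peak-table reading, filtering, control subtraction and aggregation."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from endosource import peaks as pk
from conftest import make_peaks


def _write(tmp_path, text, name="t.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadPeakTable:
    def test_well_formed_rows(self, tmp_path):
        p = _write(
            tmp_path,
            "sample_id,bio_rep,tech_rep,dye,size_bp,height\n"
            "s1,1,1,6FAM,100.2,50\n"
            "s1,1,1,Max550,200.7,40\n"
            "s1,1,2,6FAM,100.1,60\n",
        )
        df = pk.read_peak_table(p)
        assert len(df) == 3
        assert list(df.columns) == list(pk.REQUIRED_COLUMNS)

    def test_missing_column_named(self, tmp_path):
        p = _write(tmp_path, "sample_id,bio_rep,dye,size_bp,height\ns,1,6FAM,100,50\n")
        with pytest.raises(pk.PeakTableError, match="tech_rep"):
            pk.read_peak_table(p)

    def test_unknown_dye_lists_allowed(self, tmp_path):
        p = _write(
            tmp_path,
            "sample_id,bio_rep,tech_rep,dye,size_bp,height\ns,1,1,NED,100,50\n",
        )
        with pytest.raises(pk.PeakTableError, match="6FAM.*Max550"):
            pk.read_peak_table(p)

    def test_malformed_rows_reported_with_line_numbers(self, tmp_path):
        p = _write(
            tmp_path,
            "sample_id,bio_rep,tech_rep,dye,size_bp,height\n"
            "s,1,1,6FAM,100,50\n"
            "s,1,1,6FAM,oops,50\n",
        )
        with pytest.raises(pk.PeakTableError, match=r"line\(s\) \[3\]"):
            pk.read_peak_table(p)


class TestFilterPeaks:
    @pytest.mark.parametrize(
        "size,height,kept",
        [
            (100.0, 34.0, False),  # below the 35-unit cutoff
            (26.0, 500.0, False),  # primer dimer window 1-26 bp
            (27.0, 35.0, True),  # boundary: >=35 units and >26 bp retained
            (26.4, 500.0, False),  # bins to 26 -> removed
            (26.5, 500.0, True),  # rounds half up to 27 -> retained
        ],
    )
    def test_boundary_behaviour(self, size, height, kept):
        df = make_peaks([("s", 1, 1, "6FAM", size, height)])
        out = pk.filter_peaks(df)
        assert (len(out) == 1) == kept

    def test_order_preserved(self):
        df = make_peaks(
            [("s", 1, 1, "6FAM", s, 100.0) for s in (300.0, 50.0, 200.0)]
        )
        out = pk.filter_peaks(df)
        assert list(out["size_bp"]) == [300.0, 50.0, 200.0]

    @given(
        st.lists(
            st.tuples(
                st.floats(0.0, 1200.0, allow_nan=False),
                st.floats(0.0, 5000.0, allow_nan=False),
            ),
            max_size=40,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_idempotent_and_commutes(self, raw):
        df = make_peaks([("s", 1, 1, "6FAM", s, h) for s, h in raw])
        once = pk.filter_peaks(df)
        twice = pk.filter_peaks(once)
        pd.testing.assert_frame_equal(once, twice)
        # height-only then dimer-only equals the combined filter
        height_first = pk.filter_peaks(
            pk.filter_peaks(df, height_cutoff=pk.HEIGHT_CUTOFF, dimer_max=1e-9 + 0.5),
            height_cutoff=1e-9, dimer_max=pk.DIMER_MAX,
        )
        pd.testing.assert_frame_equal(once, height_first)


class TestExclusions:
    def test_empty_list_identity(self):
        df = pk.bin_sizes(make_peaks([("s", 1, 1, "6FAM", 100.0, 50.0)]))
        pd.testing.assert_frame_equal(pk.remove_excluded_sizes(df, []), df)

    def test_range_containment(self):
        df = make_peaks([("s", 1, 1, "6FAM", 1100.0, 50.0),
                         ("s", 1, 1, "Max550", 1100.0, 50.0)])
        out = pk.remove_excluded_sizes(df, [("6FAM", (1050, 1200))])
        assert list(out["dye"]) == ["Max550"]  # only the matching channel removed

    def test_exclusions_from_digest_prediction(self):
        # a chloroplast-like reference's predicted fragments define the exclusion
        from endosource import digest as dg

        amplicon = "A" * 120 + "CTAAG" + "A" * 200  # fwd cut at 121
        pred = dg.predict_terminal_fragments(amplicon, sequence_id="chloro")
        exclusions = dg.exclusions_from_predictions([pred])
        df = make_peaks([
            ("s", 1, 1, "6FAM", float(pred.fwd_fragment), 50.0),
            ("s", 1, 1, "6FAM", float(pred.fwd_fragment) + 5, 50.0),
            ("s", 1, 1, "Max550", float(pred.rev_fragment), 50.0),
        ])
        out = pk.remove_excluded_sizes(df, exclusions)
        assert len(out) == 1 and out.iloc[0]["size_bp"] == pred.fwd_fragment + 5


class TestControlSubtraction:
    @staticmethod
    def _series(d):
        idx = pd.MultiIndex.from_tuples(list(d), names=("dye", "size_cat"))
        return pd.Series(list(d.values()), index=idx, dtype=float)

    def test_simple_subtraction(self):
        s = self._series({("6FAM", 100): 100.0})
        c = self._series({("6FAM", 100): 40.0})
        out = pk.subtract_water_control(s, c)
        assert out[("6FAM", 100)] == 60.0

    def test_floored_at_zero(self):
        s = self._series({("6FAM", 100): 30.0})
        c = self._series({("6FAM", 100): 40.0})
        assert pk.subtract_water_control(s, c)[("6FAM", 100)] == 0.0

    def test_control_only_category_yields_zero(self):
        s = self._series({("6FAM", 100): 10.0})
        c = self._series({("6FAM", 200): 40.0})
        out = pk.subtract_water_control(s, c)
        assert out[("6FAM", 200)] == 0.0

    def test_missing_control_passthrough_with_warning(self, caplog):
        s = self._series({("6FAM", 100): 10.0})
        with caplog.at_level("WARNING", logger="endosource.peaks"):
            out = pk.subtract_water_control(s, None)
        assert out.equals(s)
        assert "water control" in caplog.text


class TestAggregateProfile:
    def _sample(self, detections):
        """detections: mapping trial index -> list of size categories (6FAM)."""
        rows = []
        for trial, sizes in detections.items():
            bio, tech = divmod(trial, 2)
            for s in sizes:
                rows.append(("s", bio + 1, tech + 1, "6FAM", float(s), 100.0))
        return make_peaks(rows)

    def test_single_trial_detection_not_present(self):
        df = self._sample({0: [100], 1: [], 2: [], 3: [], 4: [], 5: []})
        prof = pk.aggregate_profile(df, n_trials=6)
        assert prof.table.loc[("6FAM", 100), "trial_count"] == 1
        assert not prof.table.loc[("6FAM", 100), "present"]
        assert ("6FAM", 100) not in prof.present_set()

    def test_two_of_six_present(self):
        df = self._sample({0: [100], 3: [100]})
        prof = pk.aggregate_profile(df, n_trials=6)
        assert prof.table.loc[("6FAM", 100), "trial_count"] == 2
        assert prof.table.loc[("6FAM", 100), "present"]

    def test_all_six(self):
        df = self._sample({t: [100] for t in range(6)})
        prof = pk.aggregate_profile(df, n_trials=6)
        assert prof.table.loc[("6FAM", 100), "trial_count"] == 6

    def test_zero_trials_error(self):
        with pytest.raises(ValueError, match="zero trials"):
            pk.aggregate_profile(make_peaks([]))

    def test_presence_monotone_in_detection(self):
        base = self._sample({0: [100], 1: [100]})
        more = self._sample({0: [100], 1: [100], 2: [100]})
        p0 = pk.aggregate_profile(base, n_trials=6).present_set()
        p1 = pk.aggregate_profile(more, n_trials=6).present_set()
        assert p0 <= p1


class TestMeanIntensityProfile:
    def test_single_trial_identity(self):
        df = make_peaks([("s", 1, 1, "6FAM", 100.0, 80.0),
                         ("s", 1, 1, "Max550", 90.0, 70.0)])
        out = pk.mean_intensity_profile(df)
        assert dict(out) == {100: 80.0}  # reverse channel excluded

    def test_mean_idempotent_on_identical_trials(self):
        df = make_peaks([("s", 1, 1, "6FAM", 100.0, 80.0),
                         ("s", 1, 2, "6FAM", 100.0, 80.0)])
        assert pk.mean_intensity_profile(df)[100] == 80.0

    def test_matches_hand_average(self, rng):
        heights = rng.uniform(40, 300, size=6)
        rows = [("s", b + 1, t + 1, "6FAM", 150.0, h)
                for (b, t), h in zip([(b, t) for b in range(3) for t in range(2)], heights)]
        df = make_peaks(rows)
        out = pk.mean_intensity_profile(df)
        assert out[150] == pytest.approx(heights.mean())

    def test_no_forward_channel_warns_empty(self):
        df = make_peaks([("s", 1, 1, "Max550", 90.0, 70.0)])
        with pytest.warns(UserWarning, match="6FAM"):
            out = pk.mean_intensity_profile(df)
        assert out.empty
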