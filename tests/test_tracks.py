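"""Binning, RPKM normalization, replicate averaging and window assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from enhancernet.intervals import ReadSet
from enhancernet.tracks import (
    BinnedTrack,
    FeatureSpec,
    assemble_features,
    average_replicates,
    bin_reads,
    extract_window,
    rpkm_normalize,
    subtract_control,
)


def reads_from(starts, chrom="chr1", length=100):
    starts = np.asarray(starts, dtype=np.int64)
    return ReadSet.from_arrays({chrom: starts}, {chrom: starts + length})


class TestBinReads:
    def test_read_lands_in_bin_of_its_start(self):
        counts, dropped = bin_reads(reads_from([250]), {"chr1": 1000}, bin_width=100)
        assert dropped == 0
        expected = np.zeros(10)
        expected[2] = 1
        np.testing.assert_array_equal(counts["chr1"], expected)

    def test_zero_reads_gives_zero_arrays(self):
        counts, _ = bin_reads(ReadSet(), {"chr1": 550}, bin_width=100)
        np.testing.assert_array_equal(counts["chr1"], np.zeros(6))

    def test_counts_are_additive(self):
        counts, _ = bin_reads(reads_from([0, 10, 99]), {"chr1": 1000})
        assert counts["chr1"][0] == 3

    def test_out_of_bounds_reads_are_dropped_and_counted(self):
        rs = reads_from([50, 1500])
        counts, dropped = bin_reads(rs, {"chr1": 1000})
        assert dropped == 1
        assert counts["chr1"].sum() == 1

    def test_midpoint_assignment_mode(self):
        rs = ReadSet.from_arrays({"chr1": np.array([80])}, {"chr1": np.array([140])})
        counts, _ = bin_reads(rs, {"chr1": 1000}, position="midpoint")
        assert counts["chr1"][1] == 1  # midpoint 110 -> bin 1

    def test_conservation_of_in_bounds_reads(self):
        rng = np.random.default_rng(3)
        starts = rng.integers(0, 2000, size=500)
        counts, dropped = bin_reads(reads_from(starts), {"chr1": 1500})
        assert counts["chr1"].sum() + dropped == 500
        assert counts["chr1"].sum() == np.sum(starts < 1500)


class TestRpkm:
    def test_direct_evaluation_of_formula(self):
        track = rpkm_normalize({"chr1": np.array([0, 10])}, total_mapped=10**7,
                               bin_width=100, mark="m")
        np.testing.assert_allclose(track.values["chr1"], [0.0, 10.0])

    def test_doubling_library_halves_values(self):
        c = {"chr1": np.array([4.0, 8.0])}
        t1 = rpkm_normalize(c, 10**6, 100)
        t2 = rpkm_normalize(c, 2 * 10**6, 100)
        np.testing.assert_allclose(t2.values["chr1"], t1.values["chr1"] / 2)

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError):
            rpkm_normalize({"chr1": np.zeros(3)}, total_mapped=0)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.lists(st.integers(0, 100), min_size=1, max_size=20),
           st.lists(st.integers(0, 100), min_size=1, max_size=20))
    def test_linearity_in_counts(self, a, b):
        n = min(len(a), len(b))
        ca, cb = np.array(a[:n], float), np.array(b[:n], float)
        total = 10**6
        lhs = rpkm_normalize({"c": ca + cb}, total).values["c"]
        rhs = (rpkm_normalize({"c": ca}, total).values["c"]
               + rpkm_normalize({"c": cb}, total).values["c"])
        np.testing.assert_allclose(lhs, rhs)


class TestReplicates:
    def _track(self, vals, mark="m"):
        return BinnedTrack(mark=mark, bin_width=100,
                           values={"chr1": np.asarray(vals, float)})

    def test_single_replicate_is_identity(self):
        t = self._track([1, 2, 3])
        np.testing.assert_array_equal(
            average_replicates([t]).values["chr1"], t.values["chr1"]
        )

    def test_mean_and_permutation_invariance(self):
        a, b = self._track([2, 2]), self._track([4, 6])
        np.testing.assert_allclose(
            average_replicates([a, b]).values["chr1"], [3, 4]
        )
        np.testing.assert_allclose(
            average_replicates([b, a]).values["chr1"],
            average_replicates([a, b]).values["chr1"],
        )

    def test_shape_and_mark_mismatches_rejected(self):
        with pytest.raises(ValueError):
            average_replicates([self._track([1]), self._track([1, 2])])
        with pytest.raises(ValueError):
            average_replicates([self._track([1]), self._track([1], mark="other")])
        with pytest.raises(ValueError):
            average_replicates([])


def test_subtract_control_floors_at_zero():
    t = BinnedTrack("m", 100, {"chr1": np.array([3.0, 1.0])})
    c = BinnedTrack("input", 100, {"chr1": np.array([1.0, 2.0])})
    np.testing.assert_allclose(subtract_control(t, c).values["chr1"], [2.0, 0.0])


class TestExtractWindow:
    def test_constant_track(self):
        t = BinnedTrack("m", 100, {"chr1": np.full(50, 7.0)})
        np.testing.assert_array_equal(extract_window(t, "chr1", 25, 10), np.full(20, 7.0))

    def test_window_length_is_twice_flank(self):
        t = BinnedTrack("m", 100, {"chr1": np.zeros(50)})
        assert extract_window(t, "chr1", 25, 10).size == 20

    @pytest.mark.parametrize("center", [0, 3, 25, 47, 49])
    def test_matches_naive_loop_with_edge_padding(self, center):
        rng = np.random.default_rng(center)
        arr = rng.random(50)
        t = BinnedTrack("m", 100, {"chr1": arr})
        flank = 10
        naive = np.array([
            arr[center + o] if 0 <= center + o < arr.size else 0.0
            for o in range(-flank, flank)
        ])
        np.testing.assert_array_equal(extract_window(t, "chr1", center, flank), naive)
        if center == 3:
            assert np.all(extract_window(t, "chr1", center, flank)[:7] == 0)

    def test_out_of_range_center_rejected(self):
        t = BinnedTrack("m", 100, {"chr1": np.zeros(10)})
        with pytest.raises(ValueError):
            extract_window(t, "chr1", 10, 10)


class TestAssembleFeatures:
    @pytest.mark.parametrize("n_marks,expected", [(24, 480), (11, 220), (9, 180)])
    def test_feature_counts_for_standard_mark_panels(self, n_marks, expected):
        marks = tuple(f"mark{i}" for i in range(n_marks))
        tracks = {m: BinnedTrack(m, 100, {"chr1": np.zeros(40)}) for m in marks}
        spec = FeatureSpec(marks=marks)
        fm = assemble_features(tracks, spec, [("chr1", 20)])
        assert fm.n_features == expected
        assert spec.n_features == expected
        assert len(fm.column_map) == expected

    def test_zero_tracks_give_zero_rows(self):
        spec = FeatureSpec(marks=("m",))
        tracks = {"m": BinnedTrack("m", 100, {"chr1": np.zeros(40)})}
        fm = assemble_features(tracks, spec, [("chr1", 5), ("chr1", 30)])
        assert fm.X.shape == (2, 20)
        assert np.all(fm.X == 0)

    def test_missing_mark_is_named_in_error(self):
        spec = FeatureSpec(marks=("present", "absent"))
        tracks = {"present": BinnedTrack("present", 100, {"chr1": np.zeros(10)})}
        with pytest.raises(ValueError, match="absent"):
            assemble_features(tracks, spec, [("chr1", 5)])

    def test_delta_track_lights_exactly_the_mapped_column(self):
        # single nonzero bin: for every offset the value must appear in the
        # one column whose (mark, offset) entry matches, and nowhere else
        spec = FeatureSpec(marks=("a", "b"))
        n_bins, hot = 60, 30
        arr = np.zeros(n_bins)
        arr[hot] = 5.0
        tracks = {
            "a": BinnedTrack("a", 100, {"chr1": arr}),
            "b": BinnedTrack("b", 100, {"chr1": np.zeros(n_bins)}),
        }
        for offset in range(-10, 10):
            center = hot - offset
            fm = assemble_features(tracks, spec, [("chr1", center)])
            nz = np.flatnonzero(fm.X[0])
            assert nz.size == 1
            assert fm.column_map[nz[0]] == ("a", offset)

    def test_column_map_is_mark_major_bijection(self):
        spec = FeatureSpec(marks=("x", "y"))
        tracks = {m: BinnedTrack(m, 100, {"chr1": np.zeros(30)}) for m in ("x", "y")}
        fm = assemble_features(tracks, spec, [("chr1", 15)])
        assert fm.column_map[:3] == [("x", -10), ("x", -9), ("x", -8)]
        assert fm.column_map[20] == ("y", -10)
        assert len(set(fm.column_map)) == 40

    def test_edge_rows_are_flagged(self):
        spec = FeatureSpec(marks=("m",))
        tracks = {"m": BinnedTrack("m", 100, {"chr1": np.zeros(40)})}
        fm = assemble_features(tracks, spec, [("chr1", 2), ("chr1", 20)])
        assert fm.edge_padded.tolist() == [True, False]
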