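"""Training/test-set construction from peak-call geometry."""

import numpy as np
import pytest

from enhancernet.datasets import (
    build_test_set,
    build_training_set,
    select_negative_training,
    select_positive_training,
)
from enhancernet.intervals import ElementClass, SummitIndex, make_peak
from enhancernet.tracks import BinnedTrack, FeatureSpec

CHROM_LEN = 200_000


@pytest.fixture
def flat_tracks():
    n_bins = CHROM_LEN // 100
    return {
        m: BinnedTrack(m, 100, {"chr1": np.full(n_bins, 1.0)})
        for m in ("markA", "markB")
    }


@pytest.fixture
def spec():
    return FeatureSpec(marks=("markA", "markB"))


def site(summit, cls=ElementClass.P300, width=200, chrom="chr1"):
    return make_peak(chrom, max(summit - width // 2, 0), summit + width // 2,
                     cls, summit)


class TestSelectPositive:
    def test_requires_dhs_overlap_and_tss_distance(self):
        tss = [site(50_000, ElementClass.TSS)]
        dhs = [site(10_000, ElementClass.DHS), site(49_500, ElementClass.DHS)]
        p300 = [
            site(10_000),       # DHS overlap, 40 kb from TSS -> selected
            site(20_000),       # no DHS overlap -> excluded
            site(49_400),       # DHS overlap but 600 bp from TSS -> excluded
        ]
        selected = select_positive_training(p300, dhs, tss)
        assert selected == [p300[0]]


class TestSelectNegative:
    def test_n_random_zero_returns_only_dhs_overlapping_tss(self):
        dhs = [site(10_000, ElementClass.DHS)]
        tss = [site(10_050, ElementClass.TSS), site(50_000, ElementClass.TSS)]
        out = select_negative_training(tss, dhs, {"chr1": CHROM_LEN}, n_random=0)
        assert out == [tss[0]]

    def test_background_bins_respect_distance_rule(self):
        dhs = [site(10_000, ElementClass.DHS)]
        tss = [site(50_000, ElementClass.TSS)]
        out = select_negative_training(tss, dhs, {"chr1": CHROM_LEN},
                                       n_random=200, seed=0)
        background = [p for p in out if p.element_class == ElementClass.UNKNOWN]
        assert len(background) == 200
        avoid = SummitIndex(tss + dhs)
        for b in background:
            assert avoid.nearest_distance(b.chrom, b.summit) > 1000

    def test_same_seed_reproduces_draw(self):
        tss = [site(50_000, ElementClass.TSS)]
        a = select_negative_training(tss, [], {"chr1": CHROM_LEN}, 50, seed=4)
        b = select_negative_training(tss, [], {"chr1": CHROM_LEN}, 50, seed=4)
        assert [(p.chrom, p.start) for p in a] == [(p.chrom, p.start) for p in b]

    def test_exhausted_background_space_reports_achieved_count(self):
        # every bin of a tiny genome is within 1 kb of some avoided summit
        tss = [site(s, ElementClass.TSS, chrom="chr1") for s in range(500, 5000, 900)]
        with pytest.raises(RuntimeError, match="achieved"):
            select_negative_training(tss, [], {"chr1": 5_000}, n_random=10, seed=0)


class TestBuildTrainingSet:
    def make_pools(self, n_pos=20, n_tss=30, n_bg=400):
        positives = [site(3_000 + 600 * i) for i in range(n_pos)]
        tss = [site(60_000 + 600 * i, ElementClass.TSS) for i in range(n_tss)]
        bg = [site(120_000 + 150 * i, ElementClass.UNKNOWN, width=100)
              for i in range(n_bg)]
        return positives, tss + bg

    def test_one_to_ten_ratio_row_counts(self, flat_tracks, spec):
        positives, negatives = self.make_pools()
        ds = build_training_set(positives, negatives, flat_tracks, spec,
                                ratio=10, seed=0)
        assert ds.n_samples == 20 + 200
        assert int(ds.labels.sum()) == 20

    def test_ratio_one_with_exact_counts_keeps_everything(self, flat_tracks, spec):
        positives, _ = self.make_pools()
        negatives = [site(60_000 + 600 * i, ElementClass.TSS) for i in range(20)]
        ds = build_training_set(positives, negatives, flat_tracks, spec, ratio=1)
        assert ds.n_samples == 40

    def test_provenance_label_consistency_and_stratified_subsampling(self, flat_tracks, spec):
        positives, negatives = self.make_pools(n_pos=10, n_tss=100, n_bg=300)
        ds = build_training_set(positives, negatives, flat_tracks, spec,
                                ratio=10, seed=1)
        pos_mask = ds.labels == 1
        assert set(ds.provenance[pos_mask]) == {"P300"}
        assert set(ds.provenance[~pos_mask]) <= {"TSS", "RANDOM_BG"}
        # 100 negatives drawn from a 100 TSS : 300 background pool -> 25:75
        n_tss = int((ds.provenance == "TSS").sum())
        assert n_tss == 25

    def test_fixed_seed_is_byte_identical(self, flat_tracks, spec):
        positives, negatives = self.make_pools()
        a = build_training_set(positives, negatives, flat_tracks, spec, seed=9)
        b = build_training_set(positives, negatives, flat_tracks, spec, seed=9)
        np.testing.assert_array_equal(a.features.X, b.features.X)
        np.testing.assert_array_equal(a.provenance, b.provenance)

    def test_shortfall_raises_or_downsamples_positives(self, flat_tracks, spec):
        positives, _ = self.make_pools()
        negatives = [site(60_000 + 600 * i, ElementClass.TSS) for i in range(50)]
        with pytest.raises(ValueError, match="1:10"):
            build_training_set(positives, negatives, flat_tracks, spec, ratio=10)
        ds = build_training_set(positives, negatives, flat_tracks, spec, ratio=10,
                                on_shortfall="downsample_positives")
        assert int(ds.labels.sum()) == 5
        assert ds.n_samples == 55

    def test_empty_positives_rejected(self, flat_tracks, spec):
        with pytest.raises(ValueError):
            build_training_set([], [site(1000, ElementClass.TSS)],
                               flat_tracks, spec)

    def test_no_training_positive_near_tss(self, flat_tracks, spec):
        """Post-hoc audit of the distal rule on a fully built set."""
        tss = [site(60_000 + 600 * i, ElementClass.TSS) for i in range(30)]
        dhs = [site(3_000 + 600 * i, ElementClass.DHS) for i in range(20)]
        p300 = [site(3_000 + 600 * i) for i in range(20)] + [site(60_150)]
        positives = select_positive_training(p300, dhs + [site(60_150, ElementClass.DHS)], tss)
        tss_index = SummitIndex(tss)
        ds = build_training_set(positives, tss, flat_tracks, spec, ratio=1,
                                seed=0)
        for (chrom, b), label in zip(ds.features.locations, ds.labels):
            if label == 1:
                assert tss_index.nearest_distance(chrom, b * 100 + 50) > 900


class TestBuildTestSet:
    def test_positives_from_p300_only_when_other_classes_absent(self, flat_tracks, spec):
        dhs = [site(10_000, ElementClass.DHS)]
        tss = [site(50_000, ElementClass.TSS)]
        p300 = [site(10_000)]
        ds = build_test_set(p300, [], [], dhs, tss, flat_tracks, spec)
        assert int(ds.labels.sum()) == 1
        assert (ds.provenance == "TSS").sum() == 1

    def test_tfbs_without_dhs_overlap_excluded(self, flat_tracks, spec):
        dhs = [site(10_000, ElementClass.DHS)]
        tfbs = [site(20_000, ElementClass.TFBS)]
        ds = build_test_set([], [], tfbs, dhs, [], flat_tracks, spec)
        assert int(ds.labels.sum()) == 0

    def test_duplicates_across_classes_deduplicated_by_summit_bin(self, flat_tracks, spec):
        dhs = [site(10_000, ElementClass.DHS)]
        p300 = [site(10_000)]
        tfbs = [site(10_020, ElementClass.TFBS)]  # same 100 bp summit bin
        ds = build_test_set(p300, [], tfbs, dhs, [], flat_tracks, spec)
        assert int(ds.labels.sum()) == 1

    def test_optional_dhs_filter_on_tss(self, flat_tracks, spec):
        dhs = [site(10_000, ElementClass.DHS)]
        tss = [site(10_050, ElementClass.TSS), site(50_000, ElementClass.TSS)]
        ds_all = build_test_set([], [], [], dhs, tss, flat_tracks, spec)
        ds_filtered = build_test_set([], [], [], dhs, tss, flat_tracks, spec,
                                     dhs_filter_tss=True)
        assert ds_all.n_samples == 2
        assert ds_filtered.n_samples == 1
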