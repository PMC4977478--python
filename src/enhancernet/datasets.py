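"""Construct labeled training and test sets from peak-call geometry.

Positive training examples are distal p300 co-activator binding sites that
overlap a DNase hypersensitive site (DHS) and lie more than 1 kb
(summit-to-summit) from every transcription start site (TSS).  Negative
examples are TSS that overlap DHS, plus random 100 bp background bins distal
to all DHS and TSS summits.  The positive:negative ratio is 1:r (default
r=10), enforced by seeded, class-proportional subsampling of the negatives.

The test set uses all distal, DHS-overlapping p300/CBP/TFBS peaks as
positives and TSS as negatives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .intervals import (
    ElementClass,
    IntervalIndex,
    PeakCall,
    SummitIndex,
    deduplicate_peaks,
    make_peak,
    overlaps_any,
)
from .tracks import BinnedTrack, FeatureSpec, assemble_features

logger = logging.getLogger(__name__)

#: provenance tags
P300, CBP, TFBS, TSS, RANDOM_BG = "P300", "CBP", "TFBS", "TSS", "RANDOM_BG"
_POSITIVE_PROVENANCE = {P300, CBP, TFBS}
_NEGATIVE_PROVENANCE = {TSS, RANDOM_BG}


@dataclass
class LabeledDataset:
    """Aligned features, 1/0 enhancer labels, and per-row source class."""

    features: "FeatureMatrix"
    labels: np.ndarray
    provenance: np.ndarray

    def __post_init__(self) -> None:
        n = self.features.n_samples
        if self.labels.shape != (n,) or self.provenance.shape != (n,):
            raise ValueError("labels and provenance must align with feature rows")
        pos = np.isin(self.provenance, list(_POSITIVE_PROVENANCE))
        if not np.array_equal(self.labels.astype(int), pos.astype(int)):
            raise ValueError("labels inconsistent with provenance classes")

    @property
    def n_samples(self) -> int:
        return self.features.n_samples

    def to_tsv(self, path: str | Path) -> None:
        df = self.features.to_dataframe()
        df["label"] = self.labels
        df["provenance"] = self.provenance
        df.to_csv(path, sep="\t", index=False)


def select_positive_training(
    p300: Sequence[PeakCall],
    dhs: Sequence[PeakCall],
    tss: Sequence[PeakCall],
    min_dist: int = 1000,
) -> list[PeakCall]:
    """p300 peaks overlapping >=1 DHS and >min_dist (summit) from every TSS."""
    dhs_index = IntervalIndex(dhs)
    tss_index = SummitIndex(tss)
    selected = [
        p for p in p300
        if overlaps_any(p, dhs_index)
        and tss_index.nearest_distance(p.chrom, p.summit) > min_dist
    ]
    logger.info("selected %d/%d p300 peaks as training positives", len(selected), len(p300))
    return selected


def select_negative_training(
    tss: Sequence[PeakCall],
    dhs: Sequence[PeakCall],
    genome: Mapping[str, int],
    n_random: int,
    min_dist: int = 1000,
    seed: int = 0,
    bin_width: int = 100,
) -> list[PeakCall]:
    """DHS-overlapping TSS plus n_random distal background bins.

    Background bins are drawn uniformly over the genome (100 bp bins) and kept
    only if their centers are more than ``min_dist`` from every DHS and TSS
    summit; the draw is reproducible from ``seed``.  Rejected draws are
    redrawn; if after 1000x oversampling too few eligible bins were found, an
    error reports the achieved count.
    """
    if n_random < 0:
        raise ValueError("n_random must be >= 0")
    dhs_index = IntervalIndex(dhs)
    tss_selected = [t for t in tss if overlaps_any(t, dhs_index)]
    logger.info("kept %d/%d DHS-overlapping TSS as training negatives",
                len(tss_selected), len(tss))
    if n_random == 0:
        return tss_selected

    avoid = SummitIndex(list(tss) + list(dhs))
    rng = np.random.default_rng(seed)
    chroms = list(genome)
    lengths = np.array([genome[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    background: list[PeakCall] = []
    max_draws = 1000 * n_random
    draws = 0
    while len(background) < n_random and draws < max_draws:
        batch = min(4 * n_random, max_draws - draws)
        draws += batch
        chosen = rng.choice(len(chroms), size=batch, p=probs)
        u = rng.random(batch)
        for ci, frac in zip(chosen, u):
            chrom = chroms[ci]
            n_bins = genome[chrom] // bin_width
            b = int(frac * n_bins)
            start = b * bin_width
            center = start + bin_width // 2
            if avoid.nearest_distance(chrom, center) > min_dist:
                background.append(
                    make_peak(chrom, start, start + bin_width, ElementClass.UNKNOWN, center)
                )
                if len(background) == n_random:
                    break
    if len(background) < n_random:
        raise RuntimeError(
            f"could not draw {n_random} distal background bins "
            f"(achieved {len(background)} after {draws} draws)"
        )
    return tss_selected + background


def _provenance_of(peak: PeakCall) -> str:
    return RANDOM_BG if peak.element_class == ElementClass.UNKNOWN else peak.element_class.value


def _features_at_summits(
    peaks: Sequence[PeakCall],
    tracks: Mapping[str, BinnedTrack],
    spec: FeatureSpec,
):
    locations = [(p.chrom, p.summit // spec.bin_width) for p in peaks]
    return assemble_features(tracks, spec, locations)


def build_training_set(
    positives: Sequence[PeakCall],
    negatives: Sequence[PeakCall],
    tracks: Mapping[str, BinnedTrack],
    spec: FeatureSpec,
    ratio: int = 10,
    seed: int = 0,
    on_shortfall: str = "error",
) -> LabeledDataset:
    """Assemble features at summit bins with a 1:ratio positive:negative mix.

    Negatives are subsampled uniformly (seeded) preserving the TSS:background
    proportion of the input pool.  If fewer than ratio*|positives| negatives
    are available, ``on_shortfall`` chooses between raising and downsampling
    the positives instead.
    """
    if not positives:
        raise ValueError("no positive training examples")
    if on_shortfall not in ("error", "downsample_positives"):
        raise ValueError("on_shortfall must be 'error' or 'downsample_positives'")
    rng = np.random.default_rng(seed)
    positives = list(positives)
    negatives = list(negatives)
    n_neg_needed = ratio * len(positives)
    if len(negatives) < n_neg_needed:
        if on_shortfall == "error":
            raise ValueError(
                f"need {n_neg_needed} negatives for a 1:{ratio} ratio, have {len(negatives)}"
            )
        n_pos = len(negatives) // ratio
        if n_pos == 0:
            raise ValueError("too few negatives even to downsample positives")
        keep = rng.choice(len(positives), size=n_pos, replace=False)
        positives = [positives[i] for i in np.sort(keep)]
        n_neg_needed = ratio * len(positives)

    if n_neg_needed < len(negatives):
        prov = np.array([_provenance_of(p) for p in negatives])
        keep_idx: list[int] = []
        classes, counts = np.unique(prov, return_counts=True)
        # largest-remainder allocation keeps class proportions and the exact total
        quotas = counts * n_neg_needed / len(negatives)
        base = np.floor(quotas).astype(int)
        remainder = n_neg_needed - base.sum()
        order = np.argsort(-(quotas - base), kind="stable")
        base[order[:remainder]] += 1
        for cls, take in zip(classes, base):
            idx = np.flatnonzero(prov == cls)
            chosen = rng.choice(idx, size=take, replace=False)
            keep_idx.extend(chosen.tolist())
        negatives = [negatives[i] for i in sorted(keep_idx)]

    peaks = list(positives) + list(negatives)
    features = _features_at_summits(peaks, tracks, spec)
    labels = np.array([1] * len(positives) + [0] * len(negatives))
    provenance = np.array([_provenance_of(p) for p in peaks])
    logger.info("training set: %d positives, %d negatives (ratio 1:%d)",
                len(positives), len(negatives), ratio)
    return LabeledDataset(features=features, labels=labels, provenance=provenance)


def build_test_set(
    p300: Sequence[PeakCall],
    cbp: Sequence[PeakCall],
    tfbs: Sequence[PeakCall],
    dhs: Sequence[PeakCall],
    tss: Sequence[PeakCall],
    tracks: Mapping[str, BinnedTrack],
    spec: FeatureSpec,
    min_dist: int = 1000,
    dhs_filter_tss: bool = False,
) -> LabeledDataset:
    """Positives: distal DHS-overlapping p300/CBP/TFBS (dedup by summit bin); negatives: TSS.

    Element classes absent for a cell type are passed as empty sequences.
    ``dhs_filter_tss`` optionally restricts negatives to DHS-overlapping TSS
    for parity with training.
    """
    dhs_index = IntervalIndex(dhs)
    tss_index = SummitIndex(tss)
    positives = [
        p for p in list(p300) + list(cbp) + list(tfbs)
        if overlaps_any(p, dhs_index)
        and tss_index.nearest_distance(p.chrom, p.summit) > min_dist
    ]
    positives = deduplicate_peaks(positives, bin_width=spec.bin_width)
    negatives = list(tss)
    if dhs_filter_tss:
        negatives = [t for t in negatives if overlaps_any(t, dhs_index)]
    peaks = positives + negatives
    features = _features_at_summits(peaks, tracks, spec)
    labels = np.array([1] * len(positives) + [0] * len(negatives))
    provenance = np.array([_provenance_of(p) for p in peaks])
    return LabeledDataset(features=features, labels=labels, provenance=provenance)
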