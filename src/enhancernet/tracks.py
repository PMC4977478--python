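"""Binned enrichment tracks and windowed feature assembly.

ChIP-seq reads are binned into fixed-width (default 100 bp) genomic bins,
normalized to RPKM (reads per kilobase of bin per million mapped reads), and
replicate-averaged.  A sample's feature vector concatenates, for each histone
mark, the 20 bins spanning -1 kb..+1 kb around its location.  Because a 2 kb
window covers an even number of 100 bp bins, the window is grid-asymmetric:
offsets run from -flank_bins to +flank_bins-1 (default -10..+9) relative to
the center bin, and the offset of every column is recorded in ``column_map``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import ReadSet

logger = logging.getLogger(__name__)


@dataclass
class BinnedTrack:
    """Per-chromosome fixed-width bin values (RPKM units) for one histone mark."""

    mark: str
    bin_width: int
    values: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        for chrom, arr in self.values.items():
            if np.any(arr < 0):
                raise ValueError(f"negative track values on {chrom}")

    def n_bins(self, chrom: str) -> int:
        return self.values[chrom].size


@dataclass(frozen=True)
class FeatureSpec:
    """Which marks are used and how each mark's spatial window is laid out."""

    marks: tuple[str, ...]
    flank_bins: int = 10
    bin_width: int = 100

    def __post_init__(self) -> None:
        if not self.marks:
            raise ValueError("FeatureSpec needs at least one mark")
        if self.flank_bins < 1:
            raise ValueError("flank_bins must be >= 1")

    @property
    def window_bins(self) -> int:
        return 2 * self.flank_bins

    @property
    def n_features(self) -> int:
        return len(self.marks) * self.window_bins

    @property
    def offsets(self) -> range:
        """Spatial offsets (in bins) of the window relative to the center bin."""
        return range(-self.flank_bins, self.flank_bins)


@dataclass
class FeatureMatrix:
    """n_samples x n_features matrix with per-row locations and a column map.

    ``column_map[j]`` is the ``(mark, offset)`` pair for column j, mark-major
    (all offsets of mark 1, then mark 2, ...).  ``edge_padded`` flags rows whose
    window ran off a chromosome end and was zero-padded.
    """

    X: np.ndarray
    locations: list[tuple[str, int]]
    column_map: list[tuple[str, int]]
    edge_padded: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if self.X.shape[1] != len(self.column_map):
            raise ValueError("column_map length must equal the number of columns")
        if self.X.shape[0] != len(self.locations):
            raise ValueError("locations length must equal the number of rows")
        if len(set(self.column_map)) != len(self.column_map):
            raise ValueError("column_map entries must be unique")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def select_columns(self, indices: Sequence[int]) -> "FeatureMatrix":
        """Project onto a subset of columns (kept in the given order)."""
        indices = list(indices)
        return FeatureMatrix(
            X=self.X[:, indices],
            locations=list(self.locations),
            column_map=[self.column_map[i] for i in indices],
            edge_padded=self.edge_padded,
        )

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"{m}@{o:+d}" for m, o in self.column_map]
        df = pd.DataFrame(self.X, columns=cols)
        df.insert(0, "chrom", [c for c, _ in self.locations])
        df.insert(1, "bin", [b for _, b in self.locations])
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def bin_reads(
    reads: ReadSet,
    chrom_sizes: Mapping[str, int],
    bin_width: int = 100,
    position: str = "start",
) -> tuple[dict[str, np.ndarray], int]:
    """Count reads per bin; each read increments exactly one bin.

    The assigned bin contains the read's 5'-most coordinate by default
    (``position="start"``) or its midpoint (``position="midpoint"``).  Reads
    beyond the chromosome length (or on chromosomes absent from
    ``chrom_sizes``) are dropped and counted.

    Returns
    -------
    (counts, n_dropped)
        ``counts[chrom]`` is an integer array of length ``ceil(length/bin_width)``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if position not in ("start", "midpoint"):
        raise ValueError("position must be 'start' or 'midpoint'")
    counts: dict[str, np.ndarray] = {}
    n_dropped = 0
    for chrom, length in chrom_sizes.items():
        n_bins = -(-length // bin_width)
        starts = reads.starts.get(chrom)
        if starts is None:
            counts[chrom] = np.zeros(n_bins, dtype=np.int64)
            continue
        if position == "start":
            pos = starts
        else:
            pos = (starts + reads.ends[chrom]) // 2
        in_bounds = pos < length
        n_dropped += int(np.sum(~in_bounds))
        counts[chrom] = np.bincount(pos[in_bounds] // bin_width, minlength=n_bins).astype(np.int64)
    for chrom in reads.starts:
        if chrom not in chrom_sizes:
            n_dropped += int(reads.starts[chrom].size)
    if n_dropped:
        logger.warning("bin_reads dropped %d out-of-bounds reads", n_dropped)
    return counts, n_dropped


def rpkm_normalize(
    counts: Mapping[str, np.ndarray],
    total_mapped: int,
    bin_width: int = 100,
    mark: str = "",
) -> BinnedTrack:
    """RPKM-normalize per-bin counts: count / (bin_width/1000) / (total/1e6).

    For 100 bp bins this is ``count * 1e7 / total_mapped``.
    """
    if total_mapped <= 0:
        raise ValueError("cannot RPKM-normalize with total_mapped <= 0")
    scale = 1.0 / (bin_width / 1000.0) / (total_mapped / 1e6)
    values = {c: np.asarray(a, dtype=float) * scale for c, a in counts.items()}
    return BinnedTrack(mark=mark, bin_width=bin_width, values=values)


def average_replicates(tracks: Sequence[BinnedTrack]) -> BinnedTrack:
    """Element-wise mean of replicate tracks for one mark."""
    if not tracks:
        raise ValueError("need at least one replicate track")
    first = tracks[0]
    for t in tracks[1:]:
        if t.mark != first.mark:
            raise ValueError(f"mark mismatch: {t.mark!r} vs {first.mark!r}")
        if t.bin_width != first.bin_width:
            raise ValueError("bin_width mismatch between replicates")
        if set(t.values) != set(first.values):
            raise ValueError("chromosome sets differ between replicates")
        for c in first.values:
            if t.values[c].shape != first.values[c].shape:
                raise ValueError(f"shape mismatch on {c}")
    values = {
        c: np.mean([t.values[c] for t in tracks], axis=0) for c in first.values
    }
    return BinnedTrack(mark=first.mark, bin_width=first.bin_width, values=values)


def subtract_control(track: BinnedTrack, control: BinnedTrack) -> BinnedTrack:
    """Optional input-control normalization: per-bin RPKM subtraction, floored at 0."""
    if set(track.values) != set(control.values):
        raise ValueError("chromosome sets differ between track and control")
    values = {
        c: np.maximum(track.values[c] - control.values[c], 0.0) for c in track.values
    }
    return BinnedTrack(mark=track.mark, bin_width=track.bin_width, values=values)


def extract_window(
    track: BinnedTrack,
    chrom: str,
    center_bin: int,
    flank_bins: int = 10,
) -> np.ndarray:
    """Window of 2*flank_bins values at offsets -flank..+flank-1; zero-padded at edges."""
    arr = track.values[chrom]
    if not (0 <= center_bin < arr.size):
        raise ValueError(f"center_bin {center_bin} out of range for {chrom}")
    lo = center_bin - flank_bins
    hi = center_bin + flank_bins
    out = np.zeros(2 * flank_bins, dtype=float)
    src_lo = max(lo, 0)
    src_hi = min(hi, arr.size)
    out[src_lo - lo : src_hi - lo] = arr[src_lo:src_hi]
    return out


def assemble_features(
    tracks: Mapping[str, BinnedTrack],
    spec: FeatureSpec,
    locations: Sequence[tuple[str, int]],
) -> FeatureMatrix:
    """Assemble the mark-major windowed feature matrix at the given bin locations."""
    for mark in spec.marks:
        if mark not in tracks:
            raise ValueError(f"no track supplied for mark {mark!r}")
    column_map = [(m, o) for m in spec.marks for o in spec.offsets]
    n = len(locations)
    X = np.zeros((n, spec.n_features), dtype=float)
    edge_padded = np.zeros(n, dtype=bool)

    by_chrom: dict[str, list[int]] = {}
    for i, (chrom, b) in enumerate(locations):
        by_chrom.setdefault(chrom, []).append(i)

    offsets = np.arange(-spec.flank_bins, spec.flank_bins)
    for chrom, row_idx in by_chrom.items():
        rows = np.asarray(row_idx)
        centers = np.asarray([locations[i][1] for i in row_idx], dtype=np.int64)
        for m_i, mark in enumerate(spec.marks):
            arr = tracks[mark].values[chrom]
            if np.any((centers < 0) | (centers >= arr.size)):
                bad = centers[(centers < 0) | (centers >= arr.size)][0]
                raise ValueError(f"bin {bad} out of range for {chrom}")
            padded = np.concatenate(
                [np.zeros(spec.flank_bins), arr, np.zeros(spec.flank_bins)]
            )
            window = padded[centers[:, None] + offsets[None, :] + spec.flank_bins]
            X[rows, m_i * spec.window_bins : (m_i + 1) * spec.window_bins] = window
        n_bins = tracks[spec.marks[0]].values[chrom].size
        edge_padded[rows] = (centers - spec.flank_bins < 0) | (
            centers + spec.flank_bins > n_bins
        )
    return FeatureMatrix(X=X, locations=list(locations), column_map=column_map,
                         edge_padded=edge_padded)


def track_to_tsv(track: BinnedTrack, path: str | Path) -> None:
    """Persist a binned track as (chrom, bin_start, value) rows."""
    with open(path, "w") as fh:
        fh.write("chrom\tbin_start\tvalue\n")
        for chrom in sorted(track.values):
            arr = track.values[chrom]
            for b in range(arr.size):
                fh.write(f"{chrom}\t{b * track.bin_width}\t{arr[b]:.6g}\n")
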