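"""Genomic interval primitives: peak calls, read sets, BED I/O, distance queries.

Coordinates are 0-based, half-open throughout (BED convention). Distances
between peaks are summit-to-summit; peaks on different chromosomes are at
infinite distance, so distal/validation rules never match across chromosomes.
Strand is ignored.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

_SKIP_PREFIXES = ("#", "track", "browser")


class ElementClass(str, Enum):
    """Functional-element class of a peak call."""

    DHS = "DHS"
    TSS = "TSS"
    P300 = "P300"
    CBP = "CBP"
    TFBS = "TFBS"
    UNKNOWN = "UNKNOWN"


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Any-bp overlap under half-open semantics."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class PeakCall:
    """A located functional element with a class label and a summit position."""

    interval: GenomicInterval
    element_class: ElementClass
    summit: int

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError(
                f"summit {self.summit} outside interval "
                f"{self.interval.chrom}:{self.interval.start}-{self.interval.end}"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


def make_peak(
    chrom: str,
    start: int,
    end: int,
    element_class: ElementClass | str = ElementClass.UNKNOWN,
    summit: int | None = None,
) -> PeakCall:
    """Build a PeakCall; summit defaults to the interval midpoint."""
    if summit is None:
        summit = (start + end) // 2
    return PeakCall(GenomicInterval(chrom, start, end), ElementClass(element_class), summit)


class BedParseError(ValueError):
    """Raised for malformed BED lines; carries the 1-based line number."""

    def __init__(self, path: str | Path, lineno: int, message: str):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


def read_bed(
    path: str | Path,
    element_class: ElementClass | str = ElementClass.UNKNOWN,
    summit_col: int | None = None,
) -> list[PeakCall]:
    """Read BED3+ peak calls, preserving input order.

    Parameters
    ----------
    path
        Tab-separated BED file; lines starting with ``#``, ``track`` or
        ``browser`` are skipped.
    element_class
        Class label assigned to every peak in the file.
    summit_col
        Optional 0-based column index holding the summit *offset from start*
        (narrowPeak convention).  When absent, the summit is the interval
        midpoint ``floor((start+end)/2)``.
    """
    element_class = ElementClass(element_class)
    peaks: list[PeakCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(path, lineno, f"expected >=3 fields, got {len(fields)}")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(path, lineno, f"non-integer coordinates: {exc}") from None
            if start >= end or start < 0:
                raise BedParseError(
                    path, lineno, f"invalid interval {chrom}:{start}-{end} (need 0 <= start < end)"
                )
            summit = None
            if summit_col is not None:
                if summit_col >= len(fields):
                    raise BedParseError(path, lineno, f"summit column {summit_col} missing")
                try:
                    summit = start + int(fields[summit_col])
                except ValueError as exc:
                    raise BedParseError(path, lineno, f"bad summit offset: {exc}") from None
            peaks.append(make_peak(chrom, start, end, element_class, summit))
    return peaks


def write_bed(peaks: Iterable[PeakCall], path: str | Path) -> None:
    """Write peaks as BED4 (name column = element class)."""
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.element_class.value}\n")


def center_distance(a: PeakCall, b: PeakCall) -> float:
    """Summit-to-summit distance in bp; +inf across chromosomes."""
    if a.chrom != b.chrom:
        return math.inf
    return abs(a.summit - b.summit)


class SummitIndex:
    """Per-chromosome sorted summit positions for fast nearest-summit queries."""

    def __init__(self, peaks: Iterable[PeakCall]):
        by_chrom: dict[str, list[int]] = {}
        for p in peaks:
            by_chrom.setdefault(p.chrom, []).append(p.summit)
        self._summits = {c: np.sort(np.asarray(s, dtype=np.int64)) for c, s in by_chrom.items()}

    def __bool__(self) -> bool:
        return bool(self._summits)

    def nearest_distance(self, chrom: str, pos: int) -> float:
        """Distance to the nearest indexed summit on `chrom`; +inf if none."""
        summits = self._summits.get(chrom)
        if summits is None or summits.size == 0:
            return math.inf
        i = np.searchsorted(summits, pos)
        best = math.inf
        if i < summits.size:
            best = min(best, abs(int(summits[i]) - pos))
        if i > 0:
            best = min(best, abs(int(summits[i - 1]) - pos))
        return best

    def nearest_distances(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Vectorized nearest-summit distances for many positions on one chromosome."""
        positions = np.asarray(positions, dtype=np.int64)
        summits = self._summits.get(chrom)
        if summits is None or summits.size == 0:
            return np.full(positions.shape, np.inf)
        i = np.searchsorted(summits, positions)
        left = np.abs(summits[np.clip(i - 1, 0, summits.size - 1)] - positions).astype(float)
        right = np.abs(summits[np.clip(i, 0, summits.size - 1)] - positions).astype(float)
        left[i == 0] = np.inf
        right[i == summits.size] = np.inf
        return np.minimum(left, right)


def _as_index(reference: Iterable[PeakCall] | SummitIndex) -> SummitIndex:
    return reference if isinstance(reference, SummitIndex) else SummitIndex(reference)


def is_distal(
    site: PeakCall,
    reference: Iterable[PeakCall] | SummitIndex,
    min_dist: int = 1000,
) -> bool:
    """True iff every reference summit is strictly more than `min_dist` bp away.

    An empty reference is vacuously distal (logged as a warning).
    """
    index = _as_index(reference)
    if not index:
        logger.warning("is_distal called with an empty reference set; returning True")
        return True
    return index.nearest_distance(site.chrom, site.summit) > min_dist


class IntervalIndex:
    """Per-chromosome interval arrays for any-bp overlap queries."""

    def __init__(self, peaks: Iterable[PeakCall]):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for p in peaks:
            by_chrom.setdefault(p.chrom, []).append((p.start, p.end))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for c, pairs in by_chrom.items():
            arr = np.asarray(pairs, dtype=np.int64)
            self._starts[c] = arr[:, 0]
            self._ends[c] = arr[:, 1]

    def overlaps(self, interval: GenomicInterval) -> bool:
        starts = self._starts.get(interval.chrom)
        if starts is None:
            return False
        ends = self._ends[interval.chrom]
        return bool(np.any((starts < interval.end) & (ends > interval.start)))

    def contains_point(self, chrom: str, pos: int) -> bool:
        starts = self._starts.get(chrom)
        if starts is None:
            return False
        return bool(np.any((starts <= pos) & (self._ends[chrom] > pos)))


def overlaps_any(
    site: PeakCall,
    reference: Iterable[PeakCall] | IntervalIndex,
    summit_containment: bool = False,
) -> bool:
    """True iff the site shares >=1 bp with any reference interval.

    With ``summit_containment=True`` the test is instead whether the site's
    summit falls inside a reference interval.
    """
    index = reference if isinstance(reference, IntervalIndex) else IntervalIndex(reference)
    if summit_containment:
        return index.contains_point(site.chrom, site.summit)
    return index.overlaps(site.interval)


@dataclass
class ReadSet:
    """Aligned reads for one library, stored as per-chromosome coordinate arrays.

    ``total_mapped`` is the library size used for RPKM normalization; it equals
    the number of stored reads unless reads were filtered upstream.
    """

    starts: dict[str, np.ndarray] = field(default_factory=dict)
    ends: dict[str, np.ndarray] = field(default_factory=dict)
    total_mapped: int = 0

    def __post_init__(self) -> None:
        if self.total_mapped < 0:
            raise ValueError("total_mapped must be >= 0")

    @property
    def n_reads(self) -> int:
        return int(sum(v.size for v in self.starts.values()))

    @classmethod
    def from_arrays(cls, starts: Mapping[str, np.ndarray], ends: Mapping[str, np.ndarray],
                    total_mapped: int | None = None) -> "ReadSet":
        starts = {c: np.asarray(v, dtype=np.int64) for c, v in starts.items()}
        ends = {c: np.asarray(v, dtype=np.int64) for c, v in ends.items()}
        rs = cls(starts=starts, ends=ends, total_mapped=0)
        rs.total_mapped = rs.n_reads if total_mapped is None else int(total_mapped)
        return rs

    @classmethod
    def from_bed(cls, path: str | Path) -> "ReadSet":
        """Load reads from a BED3 file (one line per read)."""
        starts: dict[str, list[int]] = {}
        ends: dict[str, list[int]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip() or line.startswith(_SKIP_PREFIXES):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise BedParseError(path, lineno, f"expected >=3 fields, got {len(fields)}")
                try:
                    s, e = int(fields[1]), int(fields[2])
                except ValueError as exc:
                    raise BedParseError(path, lineno, f"non-integer coordinates: {exc}") from None
                if s >= e or s < 0:
                    raise BedParseError(path, lineno, f"invalid interval {fields[0]}:{s}-{e}")
                starts.setdefault(fields[0], []).append(s)
                ends.setdefault(fields[0], []).append(e)
        return cls.from_arrays(
            {c: np.asarray(v) for c, v in starts.items()},
            {c: np.asarray(v) for c, v in ends.items()},
        )

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.starts):
                for s, e in zip(self.starts[chrom], self.ends[chrom]):
                    fh.write(f"{chrom}\t{s}\t{e}\n")


def deduplicate_peaks(peaks: Sequence[PeakCall], bin_width: int = 100) -> list[PeakCall]:
    """Drop peaks sharing a (chrom, summit bin), keeping the first occurrence."""
    seen: set[tuple[str, int]] = set()
    out: list[PeakCall] = []
    for p in peaks:
        key = (p.chrom, p.summit // bin_width)
        if key not in seen:
            seen.add(key)
            out.append(p)
    return out
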