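"""Synthetic epigenomes with planted enhancer/promoter histone-mark signatures.

The generator plants functional sites (p300-class enhancers, TSS, optionally
CBP/TFBS) uniformly at random with a minimum inter-site spacing, then draws
per-mark, per-bin read counts from a Poisson whose mean is

    background_rate + sum over sites of amplitude(class, mark) * exp(-d^2 / (2 sigma^2)),

with d the distance from the bin center to the site summit.  Reads are
materialized as bin-width intervals.  DNase-hypersensitivity (DHS) peaks are
co-placed at every enhancer-class site, and by default also at TSS (promoters
are open chromatin; this is what makes the "TSS overlapping DHS" negative
selection rule non-empty on synthetic data).

The default mark models encode class identity in profile *shape*: informative
marks carry broad, moderate bumps at enhancers and sharp, strong bumps at
promoters (the familiar H3K4me1-vs-H3K4me3 width contrast), while
non-informative marks are flat Poisson background.  Everything is
reproducible from the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .intervals import ElementClass, PeakCall, ReadSet, make_peak, read_bed

#: classes that may carry planted sites; UNKNOWN models distal non-DHS sites
#: with mark enrichment that are *not* enhancers (predicting one is an error)
_SITE_CLASSES = (ElementClass.P300, ElementClass.CBP, ElementClass.TFBS,
                 ElementClass.TSS, ElementClass.UNKNOWN)
_ENHANCER_CLASSES = (ElementClass.P300, ElementClass.CBP, ElementClass.TFBS)


@dataclass(frozen=True)
class MarkModel:
    """Per-class Gaussian enrichment parameters for one histone mark.

    ``amplitudes[cls]`` is the expected extra reads in the summit bin of a
    site of that class; ``sigmas[cls]`` the Gaussian width in bp.  Classes
    absent from the mapping contribute nothing.
    """

    name: str
    amplitudes: Mapping[str, float] = field(default_factory=dict)
    sigmas: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cls, amp in self.amplitudes.items():
            if amp < 0:
                raise ValueError(f"negative amplitude for {self.name}/{cls}")
            if self.sigmas.get(cls, 0) <= 0:
                raise ValueError(f"non-positive sigma for {self.name}/{cls}")

    @property
    def is_informative(self) -> bool:
        """True when the mark's class-conditional profiles differ across site classes."""
        profiles = set()
        for c in _SITE_CLASSES:
            amp = round(self.amplitudes.get(c.value, 0.0), 9)
            sig = round(self.sigmas[c.value], 9) if amp > 0 else None
            profiles.add((amp, sig))
        return len(profiles) > 1


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic epigenome."""

    chrom_sizes: Mapping[str, int]
    n_sites: Mapping[str, int]          # element class -> count (P300/TSS/CBP/TFBS)
    marks: tuple[MarkModel, ...]
    background_rate: float = 1.0
    bin_width: int = 100
    min_spacing: int = 5000
    replicates: int = 1
    dhs_at_enhancers: bool = True
    dhs_at_tss: bool = True
    site_half_width: int = 150
    amplitude_cv: float = 0.0
    center_jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.n_sites.values()):
            raise ValueError("site counts must be >= 0")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.amplitude_cv < 0:
            raise ValueError("amplitude_cv must be >= 0")

    @property
    def mark_names(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.marks)

    @property
    def informative_marks(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.marks if m.is_informative)


@dataclass
class SyntheticTruth:
    """Generated site registry, per-mark read sets (one per replicate), and the spec."""

    sites: dict[ElementClass, list[PeakCall]]
    read_sets: dict[str, list[ReadSet]]
    spec: SyntheticSpec

    def sites_of(self, element_class: ElementClass | str) -> list[PeakCall]:
        return self.sites.get(ElementClass(element_class), [])


def _place_sites(spec: SyntheticSpec, rng: np.random.Generator) -> list[tuple[str, int, ElementClass]]:
    """Uniform site placement with minimum spacing, via the spacing-removal trick."""
    total = sum(spec.n_sites.get(c.value, 0) for c in _SITE_CLASSES)
    placements: list[tuple[str, int]] = []
    lengths = {c: l for c, l in spec.chrom_sizes.items()}
    genome = sum(lengths.values())
    # apportion sites to chromosomes proportionally to length
    per_chrom = {c: int(round(total * l / genome)) for c, l in lengths.items()}
    drift = total - sum(per_chrom.values())
    if drift != 0:
        largest = max(lengths, key=lengths.get)
        per_chrom[largest] += drift
    margin = spec.min_spacing
    for chrom, n in per_chrom.items():
        if n == 0:
            continue
        usable = lengths[chrom] - 2 * margin - n * spec.min_spacing
        if usable <= 0:
            raise ValueError(
                f"{chrom} ({lengths[chrom]} bp) too small for {n} sites "
                f"at {spec.min_spacing} bp spacing"
            )
        u = np.sort(rng.uniform(0, usable, size=n))
        positions = (u + spec.min_spacing * np.arange(1, n + 1) + margin - spec.min_spacing // 2)
        placements.extend((chrom, int(p)) for p in positions)
    classes: list[ElementClass] = []
    for c in _SITE_CLASSES:
        classes.extend([c] * spec.n_sites.get(c.value, 0))
    order = rng.permutation(total)
    return [(placements[i][0], placements[i][1], classes[order[i]]) for i in range(total)]


def generate(spec: SyntheticSpec) -> SyntheticTruth:
    """Generate a synthetic epigenome; fully reproducible from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    placed = _place_sites(spec, rng)

    sites: dict[ElementClass, list[PeakCall]] = {c: [] for c in _SITE_CLASSES}
    sites[ElementClass.DHS] = []
    hw = spec.site_half_width
    for chrom, summit, cls in placed:
        start = max(summit - hw, 0)
        end = min(summit + hw, spec.chrom_sizes[chrom])
        sites[cls].append(make_peak(chrom, start, end, cls, summit))
        wants_dhs = (cls in _ENHANCER_CLASSES and spec.dhs_at_enhancers) or (
            cls == ElementClass.TSS and spec.dhs_at_tss
        )
        if wants_dhs:
            dstart = max(summit - 2 * hw, 0)
            dend = min(summit + 2 * hw, spec.chrom_sizes[chrom])
            sites[ElementClass.DHS].append(
                make_peak(chrom, dstart, dend, ElementClass.DHS, summit)
            )

    # per-chromosome site summits for fast lambda evaluation
    by_chrom: dict[str, list[tuple[int, ElementClass, int]]] = {}
    for s_i, (chrom, summit, cls) in enumerate(placed):
        by_chrom.setdefault(chrom, []).append((summit, cls, s_i))

    # per-(site, mark) amplitude multipliers model signature heterogeneity:
    # a site may be strong in one mark and nearly bare in another, so class
    # identity is combinatorial across marks rather than readable from any
    # single mark.  Gamma(1/cv^2, cv^2) has mean 1 and the requested CV.
    if spec.amplitude_cv > 0:
        shape = 1.0 / spec.amplitude_cv**2
        site_scales = rng.gamma(shape, spec.amplitude_cv**2,
                                size=(len(placed), len(spec.marks)))
    else:
        site_scales = np.ones((len(placed), len(spec.marks)))

    # per-(site, mark) displacement of the enrichment peak from the summit:
    # emulates variable nucleosome positioning, so the informative bins sit
    # at different window offsets for different sites
    if spec.center_jitter_sd > 0:
        site_jitter = rng.normal(0.0, spec.center_jitter_sd,
                                 size=(len(placed), len(spec.marks)))
    else:
        site_jitter = np.zeros((len(placed), len(spec.marks)))

    read_sets: dict[str, list[ReadSet]] = {}
    for m_i, mark in enumerate(spec.marks):
        replicate_sets = []
        for _ in range(spec.replicates):
            starts: dict[str, np.ndarray] = {}
            ends: dict[str, np.ndarray] = {}
            for chrom, length in spec.chrom_sizes.items():
                n_bins = -(-length // spec.bin_width)
                centers = np.arange(n_bins) * spec.bin_width + spec.bin_width / 2.0
                lam = np.full(n_bins, float(spec.background_rate))
                for summit, cls, s_i in by_chrom.get(chrom, []):
                    amp = mark.amplitudes.get(cls.value, 0.0) * site_scales[s_i, m_i]
                    if amp == 0.0:
                        continue
                    sigma = mark.sigmas[cls.value]
                    center = summit + site_jitter[s_i, m_i]
                    lo = max(int((center - 4 * sigma) // spec.bin_width), 0)
                    hi = min(int((center + 4 * sigma) // spec.bin_width) + 1, n_bins)
                    d = centers[lo:hi] - center
                    lam[lo:hi] += amp * np.exp(-(d**2) / (2 * sigma**2))
                counts = rng.poisson(lam)
                bin_starts = np.repeat(
                    np.arange(n_bins, dtype=np.int64) * spec.bin_width, counts
                )
                starts[chrom] = bin_starts
                ends[chrom] = np.minimum(bin_starts + spec.bin_width, length)
            replicate_sets.append(ReadSet.from_arrays(starts, ends))
        read_sets[mark.name] = replicate_sets
    return SyntheticTruth(sites=sites, read_sets=read_sets, spec=spec)


def export(truth: SyntheticTruth, directory: str | Path) -> dict[str, Path]:
    """Write per-class site BEDs and per-mark/replicate read BEDs; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for cls, peaks in truth.sites.items():
        if not peaks:
            continue
        path = directory / f"sites_{cls.value}.bed"
        with open(path, "w") as fh:
            for p in peaks:
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{cls.value}\t{p.summit - p.start}\n")
        written[f"sites_{cls.value}"] = path
    for mark, replicates in truth.read_sets.items():
        for r, rs in enumerate(replicates):
            path = directory / f"reads_{mark}_rep{r}.bed"
            rs.to_bed(path)
            written[f"reads_{mark}_rep{r}"] = path
    return written


def load_sites(directory: str | Path, element_class: ElementClass | str) -> list[PeakCall]:
    """Re-read an exported per-class site BED (summit offset in column 5)."""
    element_class = ElementClass(element_class)
    path = Path(directory) / f"sites_{element_class.value}.bed"
    if not path.exists():
        return []
    return read_bed(path, element_class, summit_col=4)
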