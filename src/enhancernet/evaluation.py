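"""Validation-rate evaluation, threshold sweeps, and distribution-overlap statistics.

Precision/recall are deliberately avoided: genome-wide, most functional sites
are unannotated, so recall against known positives misrepresents performance.
Instead a predicted enhancer is *validated* when it lies within 2.5 kb
(summit-to-summit, inclusive) of a true-positive marker (TPM): a distal DHS,
p300, CBP or TFBS more than 1 kb from every TSS.  Predictions with no TPM
nearby count as errors.  The validation rate is the validated fraction of
predictions; at zero predictions it is reported as undefined, never 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import PeakCall, SummitIndex


@dataclass
class PredictionSet:
    """Thresholded predictions: (chrom, bin) locations with raw scores."""

    locations: list[tuple[str, int]]
    scores: np.ndarray
    threshold: float
    bin_width: int = 100

    def __post_init__(self) -> None:
        if len(self.locations) != self.scores.size:
            raise ValueError("locations and scores must align")
        if self.scores.size and not np.all(self.scores > self.threshold):
            raise ValueError("every listed prediction must have score > threshold")

    def summits(self) -> list[tuple[str, int]]:
        """Bin-center summit positions of the predictions."""
        return [(c, b * self.bin_width + self.bin_width // 2) for c, b in self.locations]

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for (chrom, b), s in zip(self.locations, self.scores):
                fh.write(f"{chrom}\t{b * self.bin_width}\t{(b + 1) * self.bin_width}\t{s:.6g}\n")


@dataclass
class ValidationResult:
    """Counts of predictions and validated predictions; rate is None when undefined."""

    n_predictions: int
    n_validated: int

    @property
    def rate(self) -> float | None:
        if self.n_predictions == 0:
            return None
        return self.n_validated / self.n_predictions


def make_prediction_set(
    locations: Sequence[tuple[str, int]],
    scores: np.ndarray,
    threshold: float,
    bin_width: int = 100,
) -> PredictionSet:
    """Apply a strict score > threshold cut to candidate locations."""
    scores = np.asarray(scores, dtype=float)
    keep = scores > threshold
    return PredictionSet(
        locations=[loc for loc, k in zip(locations, keep) if k],
        scores=scores[keep],
        threshold=threshold,
        bin_width=bin_width,
    )


def build_tpm_set(
    dhs: Sequence[PeakCall],
    p300: Sequence[PeakCall],
    cbp: Sequence[PeakCall],
    tfbs: Sequence[PeakCall],
    tss: Sequence[PeakCall],
    min_dist: int = 1000,
) -> list[PeakCall]:
    """True positive markers: DHS/p300/CBP/TFBS summits >min_dist from every TSS summit."""
    tss_index = SummitIndex(tss)
    return [
        p for p in list(dhs) + list(p300) + list(cbp) + list(tfbs)
        if tss_index.nearest_distance(p.chrom, p.summit) > min_dist
    ]


def validate_predictions(
    preds: PredictionSet,
    tpm: Sequence[PeakCall] | SummitIndex,
    radius: int = 2500,
) -> ValidationResult:
    """A prediction is validated iff a TPM summit is within `radius` bp (inclusive)."""
    index = tpm if isinstance(tpm, SummitIndex) else SummitIndex(tpm)
    n_validated = 0
    by_chrom: dict[str, list[int]] = {}
    for chrom, pos in preds.summits():
        by_chrom.setdefault(chrom, []).append(pos)
    for chrom, positions in by_chrom.items():
        d = index.nearest_distances(chrom, np.asarray(positions))
        n_validated += int(np.sum(d <= radius))
    return ValidationResult(n_predictions=len(preds.locations), n_validated=n_validated)


def threshold_sweep(
    locations: Sequence[tuple[str, int]],
    scores: np.ndarray,
    tpm: Sequence[PeakCall] | SummitIndex,
    thresholds: Sequence[float],
    radius: int = 2500,
    bin_width: int = 100,
) -> pd.DataFrame:
    """Validation-rate curve over a strictly descending threshold list.

    Returns one row per threshold with (threshold, n_predictions, n_validated,
    validation_rate); the rate is NaN where no predictions were made.
    """
    thresholds = list(thresholds)
    if np.any(np.diff(thresholds) >= 0):
        raise ValueError("thresholds must be strictly descending")
    index = tpm if isinstance(tpm, SummitIndex) else SummitIndex(tpm)
    rows = []
    for t in thresholds:
        preds = make_prediction_set(locations, scores, t, bin_width=bin_width)
        res = validate_predictions(preds, index, radius=radius)
        rows.append({
            "threshold": t,
            "n_predictions": res.n_predictions,
            "n_validated": res.n_validated,
            "validation_rate": np.nan if res.rate is None else res.rate,
        })
    return pd.DataFrame(rows)


def evaluate_at_count(
    scores: np.ndarray,
    locations: Sequence[tuple[str, int]],
    tpm: Sequence[PeakCall] | SummitIndex,
    n_top: int,
    radius: int = 2500,
    bin_width: int = 100,
) -> tuple[ValidationResult, float]:
    """Validate the ~n_top highest-scoring locations (matched-count operating point).

    The threshold is set to the (n_top+1)-th largest score, so ties at the cut
    are excluded by the strict > rule and the realized count can be slightly
    below ``n_top``.  Returns (result, threshold).
    """
    scores = np.asarray(scores, dtype=float)
    if not (0 < n_top <= scores.size):
        raise ValueError("n_top must be in (0, n_scores]")
    order = np.sort(scores)[::-1]
    threshold = order[n_top] if n_top < scores.size else order[-1] - 1.0
    preds = make_prediction_set(locations, scores, float(threshold), bin_width=bin_width)
    return validate_predictions(preds, tpm, radius=radius), float(threshold)


def distribution_overlap(
    values_a: np.ndarray,
    values_b: np.ndarray,
    n_bins: int = 100,
) -> float:
    """Histogram-intersection overlap of two samples, in [0, 1].

    Both samples are histogrammed on a shared equal-width binning over the
    pooled range; the overlap is sum_b min(p_a(b), p_b(b)) of the normalized
    frequencies.  1.0 for identical samples, 0.0 for disjoint supports.
    """
    a = np.asarray(values_a, dtype=float).ravel()
    b = np.asarray(values_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if lo == hi:  # all values identical across both samples
        return 1.0
    edges = np.linspace(lo, hi, n_bins + 1)
    pa, _ = np.histogram(a, bins=edges)
    pb, _ = np.histogram(b, bins=edges)
    return float(np.minimum(pa / a.size, pb / b.size).sum())


def neighborhood_average_overlap(
    windows_a: np.ndarray,
    windows_b: np.ndarray,
    n_bins: int = 100,
) -> float:
    """Overlap statistic on per-site window means instead of peak-bin values.

    ``windows_*`` are (n_sites, window_bins) arrays of track values around
    each site; a single-bin window reduces to ``distribution_overlap`` on the
    peak values.
    """
    a = np.atleast_2d(np.asarray(windows_a, dtype=float)).mean(axis=1)
    b = np.atleast_2d(np.asarray(windows_b, dtype=float)).mean(axis=1)
    return distribution_overlap(a, b, n_bins=n_bins)


@dataclass
class EvaluationInputs:
    """Bundle handed to the top-k sweep: candidates, their features, and TPMs."""

    features: "FeatureMatrix"
    tpm: SummitIndex
    n_predictions: int
    radius: int = 2500
    bin_width: int = 100
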