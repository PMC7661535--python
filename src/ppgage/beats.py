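"""Systolic peak detection, RR intervals, and signal-quality scoring.

Peaks are found by a voting scheme over six moving-average window widths:
a sample is a *partial peak* under a given width when it is the maximum of a
maximal run of samples strictly above the aligned CMA; points labelled by all
six widths are candidate peaks; candidates closer than 400 ms are merged by
discarding the smaller one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import SignalError
from .preprocess import ProcessedSignal, centered_moving_average, odd_window

__all__ = [
    "PeakSet",
    "RRSeries",
    "QualityReport",
    "WINDOW_FACTORS",
    "MIN_PEAK_SEPARATION_S",
    "detect_peaks",
    "merge_close_peaks",
    "rr_intervals",
    "quality_score",
    "q_from_counts",
    "valley_indices",
    "count_local_extrema",
]

#: CMA window widths used for voting, as multiples of the sampling frequency.
WINDOW_FACTORS = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0)

#: Two peaks closer than this are merged (the smaller one is dropped).
MIN_PEAK_SEPARATION_S = 0.4


@dataclass
class PeakSet:
    """Detected systolic peaks on a processed signal."""

    indices: np.ndarray  # sample positions
    times: np.ndarray  # seconds
    heights: np.ndarray  # signal values at the peaks

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=int)
        self.times = np.asarray(self.times, dtype=float)
        self.heights = np.asarray(self.heights, dtype=float)

    def __len__(self) -> int:
        return self.indices.size


@dataclass
class RRSeries:
    """Inter-beat intervals in milliseconds."""

    intervals: np.ndarray

    def __post_init__(self):
        self.intervals = np.asarray(self.intervals, dtype=float)

    def __len__(self) -> int:
        return self.intervals.size


@dataclass
class QualityReport:
    """Quality score and the counts that enter it.

    ``q = variance_peak_heights * (n_local_extrema - n_detected_extrema + 2)
    / n_points``; lower is better, 0 is perfect. ``n_detected_extrema`` counts
    detected peaks plus the valleys between consecutive peaks.
    """

    q: float
    variance_peak_heights: float
    n_local_extrema: int
    n_detected_extrema: int
    n_points: int
    threshold: float
    passed: bool


def _partial_peaks(values: np.ndarray, window: int) -> set[int]:
    """Argmax of each maximal run of samples strictly above the CMA."""
    cma = centered_moving_average(values, window)
    above = values > cma
    peaks: set[int] = set()
    n = values.size
    i = 0
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            run = values[i : j + 1]
            peaks.add(i + int(np.argmax(run)))  # argmax keeps the earliest tie
            i = j + 1
        else:
            i += 1
    return peaks


def merge_close_peaks(
    indices: np.ndarray, heights: np.ndarray, sf: float,
    min_separation_s: float = MIN_PEAK_SEPARATION_S,
) -> np.ndarray:
    """Repeatedly drop the smaller of any two peaks closer than ``min_separation_s``.

    Scans left to right until stable; height ties keep the earlier peak.
    Returns the surviving positions into ``indices``.
    """
    order = np.argsort(indices)
    idx = list(np.asarray(indices)[order])
    hts = list(np.asarray(heights)[order])
    min_gap = min_separation_s * sf
    changed = True
    while changed:
        changed = False
        k = 0
        while k + 1 < len(idx):
            if idx[k + 1] - idx[k] < min_gap:
                # drop the smaller; ties keep the earlier
                drop = k if hts[k] < hts[k + 1] else k + 1
                del idx[drop], hts[drop]
                changed = True
            else:
                k += 1
    return np.asarray(idx, dtype=int)


def detect_peaks(signal: ProcessedSignal) -> PeakSet:
    """Six-window voting peak detector; see module docstring."""
    values = signal.values
    sf = signal.sf
    if values.size <= 3 * sf:
        raise SignalError("signal too short for peak detection (need > 3 s)")
    label_sets = []
    for factor in WINDOW_FACTORS:
        w = odd_window(factor * sf)
        if w > values.size:
            raise SignalError("voting window exceeds signal length")
        label_sets.append(_partial_peaks(values, w))
    candidates = set.intersection(*label_sets)
    if not candidates:
        return PeakSet(np.array([], dtype=int), np.array([]), np.array([]))
    cand = np.sort(np.fromiter(candidates, dtype=int))
    surviving = merge_close_peaks(cand, values[cand], sf)
    return PeakSet(surviving, signal.t0 + surviving / sf, values[surviving])


def rr_intervals(peaks: PeakSet) -> RRSeries:
    """Milliseconds between consecutive peak times."""
    if len(peaks) < 2:
        raise SignalError("need at least 2 peaks to form RR intervals")
    return RRSeries(np.diff(peaks.times) * 1000.0)


def valley_indices(values: np.ndarray, peak_indices: np.ndarray) -> np.ndarray:
    """Index of the signal minimum between each pair of consecutive peaks."""
    peak_indices = np.asarray(peak_indices, dtype=int)
    valleys = np.empty(max(len(peak_indices) - 1, 0), dtype=int)
    for k in range(len(peak_indices) - 1):
        lo, hi = peak_indices[k], peak_indices[k + 1]
        seg = values[lo : hi + 1]
        valleys[k] = lo + int(np.argmin(seg))
    return valleys


def count_local_extrema(values: np.ndarray) -> int:
    """Count strict local extrema; a plateau of equal values counts once."""
    values = np.asarray(values, dtype=float)
    # compress runs of equal consecutive values to their first element
    if values.size < 3:
        return 0
    keep = np.concatenate(([True], np.diff(values) != 0))
    comp = values[keep]
    if comp.size < 3:
        return 0
    d = np.sign(np.diff(comp))
    return int(np.sum(d[:-1] != d[1:]))


def q_from_counts(
    variance_peak_heights: float, n_local_extrema: int,
    n_detected_extrema: int, n_points: int,
) -> float:
    """The quality formula itself, on pre-computed counts."""
    return variance_peak_heights * (n_local_extrema - n_detected_extrema + 2) / n_points


def quality_score(
    signal: ProcessedSignal, peaks: PeakSet, threshold: float = 0.01
) -> QualityReport:
    """Quality score: peak-height variance scaled by undetected-extrema excess.

    Fewer than 2 peaks yields ``q = inf`` (variance undefined → fail).
    """
    n_points = len(signal)
    if len(peaks) < 2:
        return QualityReport(
            q=float("inf"), variance_peak_heights=float("nan"),
            n_local_extrema=count_local_extrema(signal.values),
            n_detected_extrema=len(peaks), n_points=n_points,
            threshold=threshold, passed=False,
        )
    var = float(np.var(peaks.heights, ddof=1))
    n_extrema = count_local_extrema(signal.values)
    n_valleys = len(valley_indices(signal.values, peaks.indices))
    n_detected = len(peaks) + n_valleys
    q = q_from_counts(var, n_extrema, n_detected, n_points)
    return QualityReport(
        q=q, variance_peak_heights=var, n_local_extrema=n_extrema,
        n_detected_extrema=n_detected, n_points=n_points,
        threshold=threshold, passed=bool(q < threshold),
    )
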