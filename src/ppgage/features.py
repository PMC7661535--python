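"""The 38 waveform features: RR statistics, RR-difference statistics, and
second-derivative (SDPPG) a–e wave quantities.

Feature registry
----------------
RR family (9): ibi, medianRR, madRR, sdnn, cvRR, rangeRR, tpr, skewnessRR,
kurtosisRR.

RR-difference family (7): sdsd, rmssd, pnn20, pnn50, tpr_diff, skewness_diff,
kurtosis_diff.

SDPPG family (22): amplitude ratios b_a, c_a, d_a, e_a and the aging index
agi = (b - c - d - e) / a; absolute wave amplitudes a, b, c, d, e; slopes
slope_ab, slope_ac, slope_ad, slope_ae, slope_bc, slope_be; time distances
t_ab, t_ac, t_ad, t_ae, t_bc, t_be.  Per-beat values are aggregated across
valid beats by the median (at least 5 valid beats required).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .beats import PeakSet, RRSeries, valley_indices
from .errors import FeatureMissingError, SignalError
from .preprocess import ProcessedSignal, centered_moving_average, odd_window

__all__ = [
    "RR_FEATURES",
    "RRDIFF_FEATURES",
    "SDPPG_FEATURES",
    "FEATURE_NAMES",
    "FiducialPoints",
    "turning_point_ratio",
    "rr_features",
    "rrdiff_features",
    "sdppg",
    "fdppg",
    "detect_fiducials",
    "sdppg_features",
    "extract_features",
]

RR_FEATURES = (
    "ibi", "medianRR", "madRR", "sdnn", "cvRR", "rangeRR",
    "tpr", "skewnessRR", "kurtosisRR",
)
RRDIFF_FEATURES = (
    "sdsd", "rmssd", "pnn20", "pnn50", "tpr_diff",
    "skewness_diff", "kurtosis_diff",
)
_WAVE_PAIRS = ("ab", "ac", "ad", "ae", "bc", "be")
SDPPG_FEATURES = (
    "b_a", "c_a", "d_a", "e_a", "agi",
    "a", "b", "c", "d", "e",
    *(f"slope_{p}" for p in _WAVE_PAIRS),
    *(f"t_{p}" for p in _WAVE_PAIRS),
)
FEATURE_NAMES = RR_FEATURES + RRDIFF_FEATURES + SDPPG_FEATURES
assert len(FEATURE_NAMES) == 38


@dataclass
class FiducialPoints:
    """Per-beat SDPPG wave locations and values (a, b, c, d, e).

    ``times`` and ``values`` are (n_beats, 5) arrays in a–e order; ``valid``
    flags beats in which all five waves were located with the expected
    max/min alternation and time ordering.
    """

    times: np.ndarray
    values: np.ndarray
    valid: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float).reshape(-1, 5)
        self.values = np.asarray(self.values, dtype=float).reshape(-1, 5)
        self.valid = np.asarray(self.valid, dtype=bool).reshape(-1)

    @property
    def n_valid(self) -> int:
        return int(np.sum(self.valid))

    def __len__(self) -> int:
        return self.valid.size


def turning_point_ratio(series: np.ndarray) -> float:
    """Strict interior local extrema count divided by series length.

    An index of randomness in [0, 1); an i.i.d. continuous series has
    expectation (2/3)(n-2)/n.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 3:
        raise SignalError("turning point ratio needs at least 3 samples")
    interior = x[1:-1]
    extrema = ((interior > x[:-2]) & (interior > x[2:])) | (
        (interior < x[:-2]) & (interior < x[2:])
    )
    return float(np.sum(extrema)) / x.size


def _skew_kurt(x: np.ndarray) -> tuple[float, float]:
    # moment-based skewness and excess kurtosis; degenerate input -> (0, 0)
    if np.ptp(x) == 0 or x.size < 3:
        return 0.0, 0.0
    return float(stats.skew(x, bias=True)), float(stats.kurtosis(x, bias=True))


def rr_features(rr: RRSeries) -> dict[str, float]:
    """The 9 RR-family features (intervals in ms; dispersion with ddof=1)."""
    x = rr.intervals
    if x.size < 4:
        raise FeatureMissingError("rr", f"only {x.size} intervals (need >= 4)")
    med = float(np.median(x))
    skew, kurt = _skew_kurt(x)
    return {
        "ibi": float(np.mean(x)),
        "medianRR": med,
        "madRR": float(np.median(np.abs(x - med))),
        "sdnn": float(np.std(x, ddof=1)),
        "cvRR": float(np.std(x, ddof=1) / np.mean(x)),
        "rangeRR": float(np.ptp(x)),
        "tpr": turning_point_ratio(x),
        "skewnessRR": skew,
        "kurtosisRR": kurt,
    }


def rrdiff_features(rr: RRSeries) -> dict[str, float]:
    """The 7 successive-difference features; pnn20/pnn50 use strict |diff| > x ms."""
    x = rr.intervals
    if x.size < 4:
        raise FeatureMissingError("rr_diff", f"only {x.size} intervals (need >= 4)")
    d = np.diff(x)
    skew, kurt = _skew_kurt(d)
    return {
        "sdsd": float(np.std(d, ddof=1)),
        "rmssd": float(np.sqrt(np.mean(d**2))),
        "pnn20": float(np.mean(np.abs(d) > 20.0)),
        "pnn50": float(np.mean(np.abs(d) > 50.0)),
        "tpr_diff": turning_point_ratio(d),
        "skewness_diff": skew,
        "kurtosis_diff": kurt,
    }


def _smoothed(signal: ProcessedSignal, smooth_frac: float = 0.05) -> np.ndarray:
    w = odd_window(smooth_frac * signal.sf)
    return centered_moving_average(signal.values, w)


def sdppg(signal: ProcessedSignal, smooth_frac: float = 0.05) -> np.ndarray:
    """Second derivative of the (lightly smoothed) signal, in units of 1/s^2.

    Two applications of centered first differences on the CMA-smoothed
    signal (window ~ ``smooth_frac * sf`` samples, forced odd).
    """
    if len(signal) < 5:
        raise SignalError("signal too short for a second derivative")
    smooth = _smoothed(signal, smooth_frac)
    return np.gradient(np.gradient(smooth)) * signal.sf**2


def fdppg(signal: ProcessedSignal, smooth_frac: float = 0.05) -> np.ndarray:
    """Fourth derivative: two more difference passes over the SDPPG."""
    d2 = sdppg(signal, smooth_frac)
    return np.gradient(np.gradient(d2)) * signal.sf**2


def _segment_extrema(seg: np.ndarray) -> list[tuple[int, int]]:
    """(index, kind) of strict interior extrema; kind +1 max, -1 min."""
    out = []
    for i in range(1, seg.size - 1):
        if seg[i] > seg[i - 1] and seg[i] > seg[i + 1]:
            out.append((i, +1))
        elif seg[i] < seg[i - 1] and seg[i] < seg[i + 1]:
            out.append((i, -1))
    return out


def _cycle_candidates(d2: np.ndarray, d4: np.ndarray, lo: int, hi: int):
    """Extrema of the SDPPG inside [lo, hi), one per inflection interval.

    Zero crossings of the fourth derivative delimit intervals in which at
    most one SDPPG extremum can live; within each interval the largest-
    magnitude strict extremum is kept.
    """
    seg4 = d4[lo:hi]
    sign = np.sign(seg4)
    crossings = [lo]
    for i in range(seg4.size - 1):
        if sign[i] != 0 and sign[i + 1] != 0 and sign[i] != sign[i + 1]:
            crossings.append(lo + i)  # crossing placed at the left sample
    crossings.append(hi - 1)
    candidates: list[tuple[int, int]] = []  # (absolute index, kind)
    for a, b in zip(crossings[:-1], crossings[1:]):
        if b - a < 2:
            continue
        seg = d2[a : b + 2]  # include right endpoint's neighbour for strictness
        ext = _segment_extrema(seg[: b - a + 2])
        if not ext:
            continue
        best = max(ext, key=lambda e: abs(d2[a + e[0]]))
        candidates.append((a + best[0], best[1]))
    # deduplicate (adjacent intervals can repeat a boundary extremum)
    seen, uniq = set(), []
    for idx, kind in sorted(candidates):
        if idx not in seen:
            seen.add(idx)
            uniq.append((idx, kind))
    return uniq


def detect_fiducials(
    signal: ProcessedSignal, peaks: PeakSet, smooth_frac: float = 0.05
) -> FiducialPoints:
    """Locate the a–e SDPPG waves in each beat cycle.

    A cycle spans from the valley preceding peak ``k`` to the valley
    preceding peak ``k+1``.  ``a`` is the highest candidate maximum of the
    cycle; ``b``–``e`` are the subsequent alternating minima and maxima.
    Beats missing any wave are flagged invalid, never fatal.
    """
    d2 = sdppg(signal, smooth_frac)
    d4 = fdppg(signal, smooth_frac)
    valleys = valley_indices(signal.values, peaks.indices)
    n_cycles = max(len(valleys) - 1, 0)
    times = np.full((n_cycles, 5), np.nan)
    values = np.full((n_cycles, 5), np.nan)
    valid = np.zeros(n_cycles, dtype=bool)
    for k in range(n_cycles):
        lo, hi = valleys[k], valleys[k + 1]
        cand = _cycle_candidates(d2, d4, lo, hi)
        maxima = [c for c in cand if c[1] == +1]
        if not maxima:
            continue
        a_idx = max(maxima, key=lambda c: d2[c[0]])[0]
        waves = [a_idx]
        want = -1  # alternate min, max, min, max after a
        pos = next(i for i, c in enumerate(cand) if c[0] == a_idx)
        for idx, kind in cand[pos + 1 :]:
            if kind == want:
                waves.append(idx)
                want = -want
            if len(waves) == 5:
                break
        if len(waves) < 5:
            continue
        w = np.asarray(waves)
        times[k] = signal.t0 + w / signal.sf
        values[k] = d2[w]
        # a must dominate the cycle's SDPPG and alternation must hold
        valid[k] = values[k, 0] >= np.max(d2[lo:hi]) - 1e-12
    return FiducialPoints(times, values, valid)


def sdppg_features(fp: FiducialPoints) -> dict[str, float]:
    """The 22 SDPPG-family features, medians across valid beats."""
    if fp.n_valid < 5:
        raise FeatureMissingError("sdppg", f"only {fp.n_valid} valid beats (need >= 5)")
    t = fp.times[fp.valid]
    v = fp.values[fp.valid]
    a, b, c, d, e = (v[:, i] for i in range(5))
    ta, tb, tc, td, te = (t[:, i] for i in range(5))
    per_beat = {
        "b_a": b / a, "c_a": c / a, "d_a": d / a, "e_a": e / a,
        "agi": (b - c - d - e) / a,
        "a": a, "b": b, "c": c, "d": d, "e": e,
    }
    pair_pts = {"a": (ta, a), "b": (tb, b), "c": (tc, c), "d": (td, d), "e": (te, e)}
    for pair in _WAVE_PAIRS:
        (tx, vx), (ty, vy) = pair_pts[pair[0]], pair_pts[pair[1]]
        per_beat[f"slope_{pair}"] = (vy - vx) / (ty - tx)
        per_beat[f"t_{pair}"] = ty - tx
    return {name: float(np.median(per_beat[name])) for name in SDPPG_FEATURES}


@dataclass
class FeatureVector:
    """38 named PPG features for one subject, plus provenance counters."""

    features: dict[str, float]
    n_beats: int = 0
    n_valid_beats: int = 0

    def as_array(self) -> np.ndarray:
        return np.array([self.features[k] for k in FEATURE_NAMES])


def extract_features(signal: ProcessedSignal, peaks: PeakSet) -> FeatureVector:
    """Concatenate the three families into the fixed 38-feature vector."""
    from .beats import rr_intervals  # local import avoids a cycle at module load

    if len(peaks) < 2:
        raise FeatureMissingError("rr", "fewer than 2 peaks detected")
    rr = rr_intervals(peaks)
    feats: dict[str, float] = {}
    feats.update(rr_features(rr))
    feats.update(rrdiff_features(rr))
    fp = detect_fiducials(signal, peaks)
    feats.update(sdppg_features(fp))
    assert len(feats) == 38
    return FeatureVector(feats, n_beats=len(peaks), n_valid_beats=fp.n_valid)
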