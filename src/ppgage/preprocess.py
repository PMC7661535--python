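"""Signal conditioning: uniform resampling, CMA detrending, envelope demodulation.

The processing chain mirrors the standard fingertip-PPG recipe: estimate the
average sampling frequency, resample onto a uniform grid, subtract a centered
moving average (one-second window) to remove the slow trend, and divide by the
smoothed Hilbert envelope to stabilise the beat-to-beat amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

from .errors import SignalError

__all__ = [
    "ProcessedSignal",
    "estimate_sampling_frequency",
    "resample_uniform",
    "centered_moving_average",
    "detrend",
    "demodulate",
    "preprocess_recording",
]


@dataclass
class ProcessedSignal:
    """A uniformly sampled signal plus its provenance through the chain.

    Attributes
    ----------
    values : ndarray
        Signal samples (unitless intensity).
    sf : float
        Sampling frequency of the uniform grid, samples/second.
    t0 : float
        Time of the first sample, seconds.
    provenance : str
        One of ``raw``, ``detrended``, ``demodulated``.
    floored : ndarray of bool, optional
        Marks samples where the demodulation envelope hit the floor guard.
    """

    values: np.ndarray
    sf: float
    t0: float = 0.0
    provenance: str = "raw"
    floored: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.sf <= 0:
            raise SignalError("sampling frequency must be positive")
        if not np.all(np.isfinite(self.values)):
            raise SignalError("signal contains non-finite values")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.sf

    def __len__(self) -> int:
        return self.values.size


def estimate_sampling_frequency(time: np.ndarray) -> float:
    """Average sampling frequency ``(n - 1) / (t[-1] - t[0])`` of a time vector."""
    time = np.asarray(time, dtype=float)
    if time.size < 2:
        raise SignalError("need at least 2 timestamps to estimate a sampling frequency")
    if np.any(np.diff(time) <= 0):
        raise SignalError("timestamps must be strictly increasing")
    span = time[-1] - time[0]
    if span <= 0:
        raise SignalError("zero time span")
    return (time.size - 1) / span


def resample_uniform(time: np.ndarray, values: np.ndarray, sf: float) -> ProcessedSignal:
    """Linearly interpolate ``values`` onto the uniform grid ``t0 + k/sf``."""
    time = np.asarray(time, dtype=float)
    values = np.asarray(values, dtype=float)
    if time.shape != values.shape:
        raise SignalError("time and values must have the same length")
    if time.size < 2:
        raise SignalError("need at least 2 samples to resample")
    if np.any(np.diff(time) <= 0):
        raise SignalError("time must be strictly increasing")
    n_out = int(np.floor((time[-1] - time[0]) * sf)) + 1
    grid = time[0] + np.arange(n_out) / sf
    out = np.interp(grid, time, values)
    return ProcessedSignal(out, sf=sf, t0=float(time[0]), provenance="raw")


def odd_window(w: float) -> int:
    """Round a window length to the nearest odd integer >= 1 (add 1 if even)."""
    w = int(round(w))
    if w < 1:
        w = 1
    if w % 2 == 0:
        w += 1
    return w


def centered_moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with shrinking (clipped) windows at the edges.

    Interior sample ``i`` is the mean of ``values[i-h : i+h+1]`` with
    ``h = (window - 1) // 2``; near the edges the window is clipped to the
    signal so no data is fabricated.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if window < 1:
        raise SignalError("window must be >= 1")
    if window > n:
        raise SignalError(f"window ({window}) exceeds signal length ({n})")
    if window % 2 == 0:
        window += 1
    h = (window - 1) // 2
    if h == 0:
        return values.copy()
    csum = np.concatenate(([0.0], np.cumsum(values)))
    idx = np.arange(n)
    lo = np.maximum(idx - h, 0)
    hi = np.minimum(idx + h + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def detrend(signal: ProcessedSignal) -> ProcessedSignal:
    """High-pass the signal by subtracting its one-second CMA."""
    w = odd_window(signal.sf)
    if len(signal) <= w:
        raise SignalError("signal shorter than the detrending window")
    out = signal.values - centered_moving_average(signal.values, w)
    return ProcessedSignal(out, sf=signal.sf, t0=signal.t0, provenance="detrended")


def demodulate(signal: ProcessedSignal, floor_frac: float = 1e-3) -> ProcessedSignal:
    """Divide a detrended signal by its smoothed instantaneous-amplitude envelope.

    The envelope is the modulus of the analytic signal (via the Hilbert
    transform), smoothed with the same one-second CMA used for detrending.
    A relative floor ``max(envelope) * floor_frac`` guards against division
    blow-up on flat stretches; floored samples are flagged.
    """
    s = signal.values
    if not np.any(s):
        raise SignalError("cannot demodulate an all-zero signal")
    envelope = np.abs(hilbert(s))
    w = odd_window(signal.sf)
    smoothed = centered_moving_average(envelope, w)
    floor = float(np.max(smoothed)) * floor_frac
    floored = smoothed < floor
    out = s / np.maximum(smoothed, floor)
    result = ProcessedSignal(out, sf=signal.sf, t0=signal.t0, provenance="demodulated")
    result.floored = floored
    return result


def preprocess_recording(time: np.ndarray, values: np.ndarray) -> ProcessedSignal:
    """Full chain: estimate sf, resample, detrend, demodulate."""
    time = np.asarray(time, dtype=float)
    values = np.asarray(values, dtype=float)
    # drop duplicated timestamps, keeping the first occurrence
    keep = np.concatenate(([True], np.diff(time) > 0))
    sf = estimate_sampling_frequency(time[keep])
    raw = resample_uniform(time[keep], values[keep], sf)
    return demodulate(detrend(raw))
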