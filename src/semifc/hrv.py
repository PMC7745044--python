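"""Heart-rate-variability extraction from photoplethysmography.

The autonomic validation path: smooth the PPG pulse waveform with a one-
second moving average, pick systolic peaks under physiological heart-rate
bounds (60-180 bpm), reject abnormal normal-to-normal (NN) intervals with a
median-deviation filter, and summarize parasympathetic tone with

    RMSSD = sqrt( (1/(n-1)) * sum_i (NN_{i+1} - NN_i)^2 )   [ms].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

__all__ = [
    "PPGTrace",
    "NNSeries",
    "HRVResult",
    "smooth_ppg",
    "detect_beats",
    "filter_nn",
    "rmssd",
    "ppg_to_hrv",
]

HR_BOUNDS_BPM = (60.0, 180.0)


def _nn_bounds_ms(hr_bounds: tuple[float, float]) -> tuple[float, float]:
    lo_bpm, hi_bpm = hr_bounds
    return 60000.0 / hi_bpm, 60000.0 / lo_bpm


@dataclass
class PPGTrace:
    """Single-channel pulse waveform, arbitrary amplitude units."""

    samples: np.ndarray
    fs: float = 200.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("PPG trace contains non-finite samples")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


@dataclass
class NNSeries:
    """Accepted normal-to-normal intervals (ms) and their beat times (s).

    ``indices`` are the positions of the accepted intervals in the raw
    interval sequence; consecutive indices mark genuinely successive beats
    (differences across artifact gaps are not successive differences).
    """

    intervals: np.ndarray
    beat_times: np.ndarray
    n_rejected: int = 0
    indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float).ravel()
        self.beat_times = np.asarray(self.beat_times, dtype=float).ravel()
        if self.indices is not None:
            self.indices = np.asarray(self.indices, dtype=int).ravel()

    @property
    def n(self) -> int:
        return self.intervals.size


@dataclass
class HRVResult:
    rmssd: float  # ms
    n_beats: int
    n_rejected: int


def smooth_ppg(ppg: PPGTrace, window: int | None = None) -> PPGTrace:
    """Centered moving average with window = one second of samples."""
    w = int(round(ppg.fs)) if window is None else int(window)
    if ppg.samples.size <= w:
        raise ValueError(
            f"trace of {ppg.samples.size} samples shorter than window {w}"
        )
    sm = uniform_filter1d(ppg.samples, size=w, mode="nearest")
    return PPGTrace(sm, ppg.fs)


def _adaptive_threshold(x: np.ndarray, fs: float) -> np.ndarray:
    """0.5 x rolling 90th percentile (5 s windows on a 1 s grid)."""
    n = x.size
    step = max(1, int(round(fs)))
    half = max(1, int(round(2.5 * fs)))
    centers = np.arange(0, n, step)
    perc = np.array(
        [np.percentile(x[max(0, c - half) : min(n, c + half)], 90.0) for c in centers]
    )
    return 0.5 * np.interp(np.arange(n), centers, perc)


def detect_beats(
    ppg: PPGTrace,
    hr_bounds: tuple[float, float] = HR_BOUNDS_BPM,
    refine_on: PPGTrace | None = None,
) -> np.ndarray:
    """Systolic-peak times (s) via thresholded local-maximum picking.

    The trace is first detrended by subtracting a 2 s moving-average
    baseline (so slow gain and baseline drift cannot push ripple above the
    threshold); peaks then need amplitude above half the rolling 90th
    percentile of the detrended trace and a separation of at least the NN
    interval of the maximum heart rate. When ``refine_on`` (typically the
    unsmoothed waveform) is given, each peak is moved to the local maximum
    of that trace within a quarter of the minimum NN interval — heavy
    smoothing blurs beat-to-beat timing, which would bias RMSSD down.
    """
    base_w = max(3, int(round(2.0 * ppg.fs)))
    x = ppg.samples - uniform_filter1d(ppg.samples, size=base_w, mode="nearest")
    min_sep = int(round(ppg.fs * 60.0 / hr_bounds[1]))
    thr = _adaptive_threshold(x, ppg.fs)
    peaks, _ = find_peaks(x, distance=max(1, min_sep))
    peaks = peaks[x[peaks] > thr[peaks]]
    if peaks.size == 0:
        raise ValueError("no heartbeats detected (flat or sub-threshold trace)")
    if refine_on is not None:
        y = refine_on.samples - uniform_filter1d(
            refine_on.samples, size=base_w, mode="nearest"
        )
        # light smoothing at the systolic-peak scale (~100 ms) so sensor
        # noise cannot jitter the argmax
        y = uniform_filter1d(y, size=max(1, int(round(0.1 * ppg.fs))), mode="nearest")
        # the moving average delays/inverts the pulse ripple; estimate the
        # systematic smoothed-vs-raw peak lag by cross-correlation first
        max_lag = int(round(ppg.fs))
        lags = np.arange(-max_lag, max_lag + 1)
        xc = [np.dot(x[max(0, -d) : x.size - max(0, d)],
                     y[max(0, d) : y.size - max(0, -d)]) for d in lags]
        lag = int(lags[int(np.argmax(xc))])
        raw_peaks, _ = find_peaks(y, distance=max(1, min_sep))
        if raw_peaks.size:
            # snap each lag-corrected approximate peak to the nearest raw
            # peak; duplicates (several approximations, one pulse) collapse
            targets = np.clip(peaks + lag, 0, y.size - 1)
            pos = np.searchsorted(raw_peaks, targets)
            refined = []
            for t, k in zip(targets, pos):
                cands = raw_peaks[max(0, k - 1) : k + 1]
                best = cands[np.argmin(np.abs(cands - t))]
                if abs(best - t) <= max(1, min_sep // 3):
                    refined.append(int(best))
            if refined:
                peaks = np.unique(refined)
    return peaks / ppg.fs


def filter_nn(
    raw_intervals_ms: np.ndarray,
    threshold: float = 0.2,
    context: int = 5,
    hr_bounds: tuple[float, float] = HR_BOUNDS_BPM,
    beat_times: np.ndarray | None = None,
) -> NNSeries:
    """Reject abnormal NN intervals.

    An interval is dropped when it falls outside the heart-rate-bound range
    or deviates from the median of its surrounding ``context``-interval
    window by more than ``threshold`` (relative). Reports the rejected count.
    """
    nn = np.asarray(raw_intervals_ms, dtype=float).ravel()
    if nn.size < 1:
        raise ValueError("no NN intervals to filter")
    lo, hi = _nn_bounds_ms(hr_bounds)
    half = max(1, context // 2)
    keep = np.ones(nn.size, dtype=bool)
    for i in range(nn.size):
        med = np.median(nn[max(0, i - half) : min(nn.size, i + half + 1)])
        if not (lo <= nn[i] <= hi) or abs(nn[i] - med) > threshold * med:
            keep[i] = False
    if not keep.any():
        raise ValueError("all NN intervals rejected; recording unusable")
    times = np.asarray(beat_times)[1:][keep] if beat_times is not None else np.array([])
    return NNSeries(
        nn[keep], times, n_rejected=int((~keep).sum()), indices=np.flatnonzero(keep)
    )


def rmssd(nn: NNSeries) -> HRVResult:
    """Root mean square of successive NN-interval differences (ms).

    When rejection gaps are recorded (``nn.indices``), only differences
    between genuinely successive intervals enter the sum; the divisor is
    the number of such pairs, matching the contiguous-series formula
    sqrt(sum(diff^2) / (n - 1)) when nothing was rejected.
    """
    if nn.n < 2:
        raise ValueError(f"RMSSD needs at least 2 intervals, got {nn.n}")
    diff = np.diff(nn.intervals)
    if nn.indices is not None:
        successive = np.diff(nn.indices) == 1
        if not successive.any():
            raise ValueError("no successive NN pairs left after filtering")
        diff = diff[successive]
    value = float(np.sqrt((diff**2).sum() / diff.size))
    return HRVResult(value, n_beats=nn.n + 1, n_rejected=nn.n_rejected)


def ppg_to_hrv(
    ppg: PPGTrace,
    hr_bounds: tuple[float, float] = HR_BOUNDS_BPM,
    threshold: float = 0.2,
    context: int = 5,
) -> HRVResult:
    """Full chain: smooth -> detect beats -> NN filter -> RMSSD."""
    sm = smooth_ppg(ppg)
    beats = detect_beats(sm, hr_bounds, refine_on=ppg)
    if beats.size < 3:
        raise ValueError("too few beats for HRV analysis")
    nn = filter_nn(np.diff(beats) * 1000.0, threshold, context, hr_bounds, beats)
    return rmssd(nn)
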