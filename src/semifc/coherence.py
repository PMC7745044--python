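"""Wavelet-transform-coherence functional connectivity.

Pairwise channel coupling is estimated with the squared wavelet transform
coherence (WTC)

    R^2(s, t) = |S(W_xy / s)|^2 / ( S(|W_x|^2 / s) * S(|W_y|^2 / s) )

where W_x is the analytic Morlet continuous wavelet transform, W_xy the
cross-spectrum, and S the canonical two-stage smoothing: a Gaussian in time
with width proportional to scale, then a fixed-width (0.6 octave) boxcar
across scales. R^2 is averaged over the band of interest (0.01-0.2 Hz by
default) and over task blocks to yield one edge weight in [0, 1] per channel
pair; doing this for all pairs builds a symmetric weighted FC matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d

from .preprocess import HemoSignals

__all__ = [
    "TaskParadigm",
    "CoherenceMap",
    "FCMatrix",
    "cwt_morlet",
    "wtc",
    "band_task_average",
    "build_fc_matrix",
]


@dataclass
class TaskParadigm:
    """Block design: ordered (onset s, duration s, label) with labels rest/task."""

    blocks: list[tuple[float, float, str]]

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for onset, duration, label in self.blocks:
            if label not in ("rest", "task"):
                raise ValueError(f"unknown block label {label!r}")
            if duration <= 0:
                raise ValueError("block duration must be positive")
            if onset < prev_end - 1e-9:
                raise ValueError("blocks overlap or are out of order")
            prev_end = onset + duration
        durs = {d for _, d, lab in self.blocks if lab == "task"}
        if len(durs) > 1:
            raise ValueError("task blocks must share one duration")

    @classmethod
    def block_design(
        cls,
        initial_rest: float = 20.0,
        n_task_blocks: int = 5,
        task_duration: float = 60.0,
        rest_duration: float = 30.0,
    ) -> "TaskParadigm":
        """Initial rest followed by alternating task/rest periods.

        Defaults give the validation paradigm: 20 s rest then five 60 s task
        blocks separated by 30 s rests.
        """
        blocks = [(0.0, initial_rest, "rest")]
        t = initial_rest
        for i in range(n_task_blocks):
            blocks.append((t, task_duration, "task"))
            t += task_duration
            if i < n_task_blocks - 1:
                blocks.append((t, rest_duration, "rest"))
                t += rest_duration
        return cls(blocks)

    @property
    def task_blocks(self) -> list[tuple[float, float]]:
        return [(o, d) for o, d, lab in self.blocks if lab == "task"]

    @property
    def total_duration(self) -> float:
        onset, duration, _ = self.blocks[-1]
        return onset + duration

    def task_block_slices(self, fs: float, n_samples: int) -> list[slice]:
        """Per-task-block sample ranges clipped to the recording."""
        out = []
        for onset, duration in self.task_blocks:
            a = int(round(onset * fs))
            b = min(int(round((onset + duration) * fs)), n_samples)
            if b > a:
                out.append(slice(a, b))
        return out


@dataclass
class CoherenceMap:
    """Scale x time squared-coherence field for one channel pair."""

    values: np.ndarray  # (n_scales, n_times) in [0, 1]
    periods: np.ndarray  # seconds, strictly increasing
    coi: np.ndarray  # max trustworthy period (s) per time sample
    fs: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.periods = np.asarray(self.periods, dtype=float)
        if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-12):
            raise ValueError("coherence values outside [0, 1]")
        if np.any(np.diff(self.periods) <= 0):
            raise ValueError("periods must be strictly increasing")


@dataclass
class FCMatrix:
    """Symmetric weighted undirected FC network (edge weights in [0, 1])."""

    weights: np.ndarray
    channel_ids: list[str]
    roi_map: dict[str, str] | None = None  # channel id -> ROI name
    hemisphere_excluded: set[str] = field(default_factory=lambda: {"ch16", "ch37"})

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if not np.all(np.isfinite(w)):
            raise ValueError("weights contain non-finite entries")
        asym = np.abs(w - w.T)
        if asym.max() > 1e-9:
            i, j = np.unravel_index(np.argmax(asym), asym.shape)
            raise ValueError(
                f"matrix not symmetric at pair ({self.channel_ids[i] if self.channel_ids else i}, "
                f"{self.channel_ids[j] if self.channel_ids else j})"
            )
        off = ~np.eye(w.shape[0], dtype=bool)
        if np.any(w[off] < 0) or np.any(w[off] > 1):
            raise ValueError("off-diagonal weights must lie in [0, 1]")
        self.weights = w
        if self.channel_ids is None:
            self.channel_ids = [f"ch{i + 1}" for i in range(w.shape[0])]
        if len(self.channel_ids) != w.shape[0]:
            raise ValueError("channel_ids length does not match matrix")

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    def roi_indices(self, apply_exclusions: bool = False) -> dict[str, list[int]]:
        """Node indices per ROI, optionally dropping the hemisphere-contrast
        exclusion channels."""
        if self.roi_map is None:
            raise ValueError("FCMatrix has no roi_map")
        out: dict[str, list[int]] = {}
        for idx, ch in enumerate(self.channel_ids):
            roi = self.roi_map.get(ch)
            if roi is None:
                continue
            if apply_exclusions and ch in self.hemisphere_excluded:
                continue
            out.setdefault(roi, []).append(idx)
        return out


def _morlet_params(omega0: float) -> float:
    # Fourier period per unit scale for the analytic Morlet wavelet.
    return 4.0 * np.pi / (omega0 + np.sqrt(2.0 + omega0**2))


def cwt_morlet(
    sig: np.ndarray,
    fs: float,
    omega0: float = 6.0,
    voices_per_octave: int = 12,
    period_limits: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Analytic Morlet continuous wavelet transform (FFT implementation).

    Scales are dyadic with ``voices_per_octave`` voices, spanning Fourier
    periods from 2/fs up to n/(2*fs) unless narrowed by ``period_limits``.

    Returns ``(coeffs, periods, coi)`` where ``coeffs`` is complex with shape
    (n_scales, n_samples), ``periods`` the Fourier period (s) per scale, and
    ``coi`` the cone-of-influence boundary: the largest period at each time
    sample unaffected by edge effects (e-folding criterion).
    """
    x = np.asarray(sig, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("signal too short for a wavelet transform (need >= 4)")
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    dt = 1.0 / fs
    ff = _morlet_params(omega0)

    pmin_full, pmax_full = 2 * dt, n * dt / 2.0
    if period_limits is None:
        pmin, pmax = pmin_full, pmax_full
    else:
        pmin = max(period_limits[0], pmin_full)
        pmax = min(period_limits[1], pmax_full)
        if pmax <= pmin:
            raise ValueError("period_limits outside the resolvable range")
    s0 = pmin / ff
    n_oct = np.log2(pmax / pmin)
    j = np.arange(int(np.floor(n_oct * voices_per_octave)) + 1)
    scales = s0 * 2.0 ** (j / voices_per_octave)
    periods = scales * ff

    npad = int(2 ** np.ceil(np.log2(n)))
    xf = np.fft.fft(x - x.mean(), npad)
    omega = 2.0 * np.pi * np.fft.fftfreq(npad, d=dt)
    pos = omega > 0
    coeffs = np.empty((scales.size, n), dtype=complex)
    norm_base = np.sqrt(2.0 * np.pi / dt) * np.pi**-0.25
    for i, s in enumerate(scales):
        psi_hat = np.zeros(npad)
        psi_hat[pos] = norm_base * np.sqrt(s) * np.exp(-0.5 * (s * omega[pos] - omega0) ** 2)
        coeffs[i] = np.fft.ifft(xf * psi_hat)[:n]

    t_idx = np.arange(n)
    edge = np.minimum(t_idx, n - 1 - t_idx) * dt
    coi = ff / np.sqrt(2.0) * edge
    return coeffs, periods, coi


def _smooth_time(field: np.ndarray, scales_samples: np.ndarray) -> np.ndarray:
    """Gaussian smoothing in time, std = scale, vectorized across scales."""
    if np.iscomplexobj(field):
        return _smooth_time(field.real, scales_samples) + 1j * _smooth_time(
            field.imag, scales_samples
        )
    n = field.shape[1]
    # zero-pad past the widest kernel's 4-sigma reach to kill wraparound
    pad = int(min(4 * scales_samples.max(), 4 * n)) + 1
    nfft = int(2 ** np.ceil(np.log2(n + pad)))
    omega = 2.0 * np.pi * np.fft.rfftfreq(nfft)
    gain = np.exp(-0.5 * (scales_samples[:, None] * omega[None, :]) ** 2)
    return np.fft.irfft(np.fft.rfft(field, nfft, axis=1) * gain, nfft, axis=1)[:, :n]


def _smooth_scale(field: np.ndarray, voices_per_octave: int, octaves: float = 0.6) -> np.ndarray:
    size = max(1, int(round(octaves * voices_per_octave)))
    if field.shape[0] == 1 or size == 1:
        return field
    return uniform_filter1d(field, size=size, axis=0, mode="nearest")


def _smoothed_power(W, scales_samples, voices):
    return _smooth_scale(_smooth_time(np.abs(W) ** 2 / scales_samples[:, None], scales_samples), voices)


def _smoothed_cross(Wx, Wy, scales_samples, voices):
    cross = Wx * np.conj(Wy) / scales_samples[:, None]
    sm = _smooth_time(cross.real, scales_samples) + 1j * _smooth_time(cross.imag, scales_samples)
    return _smooth_scale(sm.real, voices) + 1j * _smooth_scale(sm.imag, voices)


def wtc(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    omega0: float = 6.0,
    voices_per_octave: int = 12,
    period_limits: tuple[float, float] | None = None,
) -> CoherenceMap:
    """Squared wavelet transform coherence between two equal-length signals."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    Wx, periods, coi = cwt_morlet(x, fs, omega0, voices_per_octave, period_limits)
    Wy, _, _ = cwt_morlet(y, fs, omega0, voices_per_octave, period_limits)
    ff = _morlet_params(omega0)
    scales_samples = periods / ff * fs
    sx = _smoothed_power(Wx, scales_samples, voices_per_octave)
    sy = _smoothed_power(Wy, scales_samples, voices_per_octave)
    sxy = _smoothed_cross(Wx, Wy, scales_samples, voices_per_octave)
    denom = sx * sy
    r2 = np.zeros_like(sx)
    ok = denom > 0
    r2[ok] = np.abs(sxy[ok]) ** 2 / denom[ok]
    return CoherenceMap(np.clip(r2, 0.0, 1.0), periods, coi, fs)


def band_task_average(
    cmap: CoherenceMap,
    paradigm: TaskParadigm,
    band: tuple[float, float] = (0.01, 0.2),
    include_coi: bool = True,
) -> float:
    """Mean coherence over in-band scales and task-block samples.

    Each task block is averaged separately (over its samples and the selected
    scales), then blocks are averaged with equal weight. With
    ``include_coi=False``, scale/time cells whose period exceeds the
    cone-of-influence boundary are dropped from the average.
    """
    freqs = 1.0 / cmap.periods
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if not sel.any():
        raise ValueError(
            f"band {band} Hz selects no scales; available "
            f"{freqs.min():.4g}-{freqs.max():.4g} Hz"
        )
    n = cmap.values.shape[1]
    slices = paradigm.task_block_slices(cmap.fs, n)
    if not slices:
        raise ValueError("paradigm has no task samples inside the recording")
    block_means = []
    for sl in slices:
        vals = cmap.values[sel, sl]
        if include_coi:
            block_means.append(vals.mean())
        else:
            inside = cmap.periods[sel, None] <= cmap.coi[None, sl]
            if not inside.any():
                continue
            block_means.append(vals[inside].mean())
    if not block_means:
        raise ValueError("no coherence samples survive the COI mask")
    return float(np.mean(block_means))


def build_fc_matrix(
    hemo: HemoSignals,
    paradigm: TaskParadigm,
    band: tuple[float, float] = (0.01, 0.2),
    signal_choice: str = "hbo",
    omega0: float = 6.0,
    voices_per_octave: int = 12,
    include_coi: bool = True,
    restrict_scales: bool = True,
    roi_map: dict[str, str] | None = None,
) -> FCMatrix:
    """All-pairs WTC reduced to one symmetric task-band FC matrix.

    Per-channel wavelet transforms and smoothed auto-spectra are computed
    once and reused across the N(N-1)/2 pairs. With ``restrict_scales`` the
    transform covers the analysis band plus a one-octave smoothing margin on
    each side (the full dyadic range otherwise).
    """
    if signal_choice not in ("hbo", "hbr"):
        raise ValueError("signal_choice must be 'hbo' or 'hbr'")
    data = hemo.hbo if signal_choice == "hbo" else hemo.hbr
    n_ch = data.shape[1]
    if n_ch < 2:
        raise ValueError("need at least 2 channels")
    limits = None
    if restrict_scales:
        limits = (0.5 / band[1], 2.0 / band[0])

    Ws, autos = [], []
    periods = coi = None
    ff = _morlet_params(omega0)
    for ch in range(n_ch):
        W, periods, coi = cwt_morlet(data[:, ch], hemo.fs, omega0, voices_per_octave, limits)
        scales_samples = periods / ff * hemo.fs
        Ws.append(W)
        autos.append(_smoothed_power(W, scales_samples, voices_per_octave))
    scales_samples = periods / ff * hemo.fs

    weights = np.zeros((n_ch, n_ch))
    for i in range(n_ch):
        for j in range(i + 1, n_ch):
            sxy = _smoothed_cross(Ws[i], Ws[j], scales_samples, voices_per_octave)
            denom = autos[i] * autos[j]
            r2 = np.zeros_like(denom)
            ok = denom > 0
            r2[ok] = np.abs(sxy[ok]) ** 2 / denom[ok]
            cmap = CoherenceMap(np.clip(r2, 0.0, 1.0), periods, coi, hemo.fs)
            try:
                w = band_task_average(cmap, paradigm, band, include_coi)
            except ValueError as err:
                raise ValueError(
                    f"FC failed for pair ({hemo.channel_ids[i]}, "
                    f"{hemo.channel_ids[j]}): {err}"
                ) from err
            weights[i, j] = weights[j, i] = w
    return FCMatrix(weights, list(hemo.channel_ids), roi_map=roi_map)
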