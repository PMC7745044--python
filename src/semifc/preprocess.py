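"""Raw fNIRS intensity to functional hemoglobin signals.

The chain implemented here converts dual-wavelength continuous-wave light
intensity into oxy-/deoxy-hemoglobin concentration changes suitable for
connectivity analysis:

    intensity -> optical density -> wavelet motion correction
              -> modified Beer-Lambert inversion -> 1 Hz low-pass
              -> hemodynamic modality separation (functional vs systemic)

All stages preserve the (time, channel) layout and operate per channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pywt
from scipy.signal import butter, filtfilt

__all__ = [
    "RawIntensity",
    "OpticalDensity",
    "HemoSignals",
    "BeerLambertConfig",
    "intensity_to_od",
    "wavelet_motion_correct",
    "lowpass",
    "od_to_hemoglobin",
    "hms_separate",
    "preprocess_pipeline",
]

#: Specific extinction coefficients epsilon(lambda, chromophore) in 1/(mM*mm),
#: compiled from the Gratzer hemoglobin spectra. Rows follow the instrument's
#: wavelength order (695 nm, 830 nm); columns are (HbO, HbR). Editable.
DEFAULT_EXTINCTION = np.array(
    [
        [0.0350, 0.1802],  # 695 nm
        [0.0974, 0.0693],  # 830 nm
    ]
)


def _as_time_channel_wavelength(data: np.ndarray) -> np.ndarray:
    a = np.asarray(data, dtype=float)
    if a.ndim != 3 or a.shape[2] != 2:
        raise ValueError(
            f"expected a (time, channel, 2-wavelength) array, got shape {a.shape}"
        )
    return a


@dataclass
class RawIntensity:
    """Dual-wavelength light-intensity recording (arbitrary units)."""

    data: np.ndarray  # (n_times, n_channels, 2)
    fs: float = 10.0
    wavelengths: tuple[float, float] = (695.0, 830.0)
    channel_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = _as_time_channel_wavelength(self.data)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.wavelengths) != 2:
            raise ValueError("exactly two wavelengths are required")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensity contains non-finite samples")
        bad = np.argwhere(self.data <= 0)
        if bad.size:
            t, ch, wl = bad[0]
            raise ValueError(
                f"non-positive intensity at sample {t}, channel index {ch}, "
                f"wavelength index {wl}"
            )
        if self.channel_ids is None:
            self.channel_ids = [f"ch{i + 1}" for i in range(self.data.shape[1])]
        if len(self.channel_ids) != self.data.shape[1]:
            raise ValueError("channel_ids length does not match data")

    @property
    def n_times(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


@dataclass
class OpticalDensity:
    """Optical-density change Delta-OD (dimensionless) per channel/wavelength."""

    data: np.ndarray  # (n_times, n_channels, 2)
    fs: float
    wavelengths: tuple[float, float]
    channel_ids: list[str]

    def __post_init__(self) -> None:
        self.data = _as_time_channel_wavelength(self.data)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("optical density contains non-finite samples")


@dataclass
class HemoSignals:
    """Hemoglobin concentration changes in uM, (time, channel) per chromophore.

    ``component_tag`` records which hemodynamic component the arrays carry:
    ``total`` (straight Beer-Lambert output), ``functional`` (neuronal,
    anti-phase HbR) or ``systemic`` (circulatory, in-phase HbR).
    """

    hbo: np.ndarray
    hbr: np.ndarray
    fs: float
    channel_ids: list[str]
    component_tag: str = "total"

    _TAGS = ("total", "functional", "systemic")

    def __post_init__(self) -> None:
        self.hbo = np.atleast_2d(np.asarray(self.hbo, dtype=float))
        self.hbr = np.atleast_2d(np.asarray(self.hbr, dtype=float))
        if self.hbo.shape != self.hbr.shape:
            raise ValueError("hbo and hbr must share shape")
        if not (np.all(np.isfinite(self.hbo)) and np.all(np.isfinite(self.hbr))):
            raise ValueError("hemoglobin signals contain non-finite samples")
        if self.component_tag not in self._TAGS:
            raise ValueError(f"component_tag must be one of {self._TAGS}")

    @property
    def n_times(self) -> int:
        return self.hbo.shape[0]

    @property
    def n_channels(self) -> int:
        return self.hbo.shape[1]


@dataclass
class BeerLambertConfig:
    """Modified Beer-Lambert constants.

    extinction : (2, 2) array, rows = wavelengths (same order as the
        recording), columns = (HbO, HbR), units 1/(mM*mm).
    dpf : differential pathlength factor per wavelength (dimensionless).
    distance : source-detector separation in mm.
    """

    extinction: np.ndarray = field(default_factory=lambda: DEFAULT_EXTINCTION.copy())
    dpf: tuple[float, float] = (6.0, 6.0)
    distance: float = 30.0

    def __post_init__(self) -> None:
        self.extinction = np.asarray(self.extinction, dtype=float)
        if self.extinction.shape != (2, 2):
            raise ValueError("extinction must be a 2x2 matrix")
        if np.abs(np.linalg.det(self.extinction)) < 1e-12:
            raise ValueError("extinction matrix is singular")
        if any(d <= 0 for d in self.dpf):
            raise ValueError("DPF must be positive")
        if self.distance <= 0:
            raise ValueError("source-detector distance must be positive")

    @property
    def system_matrix(self) -> np.ndarray:
        """Effective 2x2 matrix mapping (HbO, HbR) in mM to Delta-OD."""
        return self.extinction * (self.distance * np.asarray(self.dpf)[:, None])


def intensity_to_od(
    raw: RawIntensity, reference: tuple[int, int] | None = None
) -> OpticalDensity:
    """Convert intensity to optical-density change.

    OD(t) = -ln(I(t) / ref) per channel and wavelength, with ref the
    geometric mean of I over the reference window (default: the whole
    recording), so the OD averages to exactly zero over that window.

    Parameters
    ----------
    reference : (start, stop) sample indices of the baseline window,
        half-open; ``None`` uses the full recording.
    """
    if reference is None:
        reference = (0, raw.n_times)
    start, stop = reference
    if stop <= start or start < 0 or stop > raw.n_times:
        raise ValueError(f"empty or out-of-range reference window {reference}")
    log_i = np.log(raw.data)
    od = -(log_i - log_i[start:stop].mean(axis=0))
    return OpticalDensity(od, raw.fs, raw.wavelengths, list(raw.channel_ids))


def _correct_channel(
    sig: np.ndarray, wavelet: str, levels: int, iqr_factor: float
) -> np.ndarray:
    coeffs = pywt.wavedec(sig, wavelet, level=levels, mode="periodization")
    cleaned = [coeffs[0]]  # approximation untouched
    for detail in coeffs[1:]:
        med = np.median(detail)
        q75, q25 = np.percentile(detail, [75.0, 25.0])
        thr = iqr_factor * (q75 - q25)
        out = detail.copy()
        out[np.abs(detail - med) > thr] = 0.0
        cleaned.append(out)
    rec = pywt.waverec(cleaned, wavelet, mode="periodization")
    return rec[: sig.size]


def wavelet_motion_correct(
    od: OpticalDensity,
    iqr_factor: float = 1.5,
    levels: int | None = None,
    wavelet_name: str = "db5",
) -> OpticalDensity:
    """Suppress motion artifacts by interquartile-range wavelet thresholding.

    Each channel/wavelength trace is decomposed with an orthogonal discrete
    wavelet transform; detail coefficients deviating from their per-level
    median by more than ``iqr_factor`` times the interquartile range are
    zeroed (motion spikes concentrate energy in few large coefficients), and
    the signal is re-synthesized. The approximation level is never touched.
    """
    if iqr_factor <= 0:
        raise ValueError("iqr_factor must be positive")
    n = od.data.shape[0]
    if levels is None:
        levels = max(1, int(np.floor(np.log2(n))) - 4)
    if n < 2**levels:
        raise ValueError(
            f"signal length {n} too short for {levels} levels; need >= {2 ** levels}"
        )
    out = np.empty_like(od.data)
    for ch in range(od.data.shape[1]):
        for wl in range(2):
            out[:, ch, wl] = _correct_channel(
                od.data[:, ch, wl], wavelet_name, levels, iqr_factor
            )
    return replace(od, data=out)


def lowpass(sig: np.ndarray, fs: float, cutoff: float = 1.0) -> np.ndarray:
    """Zero-phase 3rd-order Butterworth low-pass along the time axis."""
    if not 0 < cutoff < fs / 2:
        raise ValueError(f"cutoff {cutoff} Hz must lie in (0, Nyquist={fs / 2})")
    b, a = butter(3, cutoff, fs=fs)
    return filtfilt(b, a, np.asarray(sig, dtype=float), axis=0)


def od_to_hemoglobin(od: OpticalDensity, cfg: BeerLambertConfig) -> HemoSignals:
    """Invert the modified Beer-Lambert law.

    Solves, per time sample and channel, the 2x2 system
    Delta-OD(lambda) = [eps_HbO(lambda)*dHbO + eps_HbR(lambda)*dHbR] * d * DPF(lambda)
    with concentrations in mM, then reports uM.
    """
    inv = np.linalg.inv(cfg.system_matrix)
    conc_mM = od.data @ inv.T  # (time, channel, [HbO, HbR])
    hbo = conc_mM[:, :, 0] * 1e3
    hbr = conc_mM[:, :, 1] * 1e3
    return HemoSignals(hbo, hbr, od.fs, list(od.channel_ids), "total")


def hemoglobin_to_od(
    hemo: HemoSignals, cfg: BeerLambertConfig, wavelengths=(695.0, 830.0)
) -> OpticalDensity:
    """Forward Beer-Lambert model (inverse of :func:`od_to_hemoglobin`)."""
    conc_mM = np.stack([hemo.hbo, hemo.hbr], axis=-1) * 1e-3
    od = conc_mM @ cfg.system_matrix.T
    return OpticalDensity(od, hemo.fs, tuple(wavelengths), list(hemo.channel_ids))


def hms_separate(
    hemo: HemoSignals, k1: float = -0.6, k2: float = 2.0
) -> tuple[HemoSignals, HemoSignals]:
    """Hemodynamic modality separation into functional and systemic parts.

    Assumes the measured signals mix a functional (neuronal) component with
    anti-phase HbR, dHbR_f = k1*dHbO_f with k1 < 0, and a systemic
    (circulatory) component with in-phase HbR, dHbR_s = k2*dHbO_s with
    k2 > 0:

        dHbO = dHbO_f + dHbO_s
        dHbR = k1*dHbO_f + k2*dHbO_s

    The 2x2 system has the closed-form solution
    dHbO_f = (k2*dHbO - dHbR) / (k2 - k1), dHbO_s = dHbO - dHbO_f.
    The two outputs sum back to the input exactly.
    """
    if not (k1 < 0 < k2):
        raise ValueError("HMS requires k1 < 0 < k2")
    hbo_f = (k2 * hemo.hbo - hemo.hbr) / (k2 - k1)
    hbo_s = hemo.hbo - hbo_f
    functional = HemoSignals(
        hbo_f, k1 * hbo_f, hemo.fs, list(hemo.channel_ids), "functional"
    )
    systemic = HemoSignals(
        hbo_s, k2 * hbo_s, hemo.fs, list(hemo.channel_ids), "systemic"
    )
    return functional, systemic


def preprocess_pipeline(
    raw: RawIntensity,
    cfg: BeerLambertConfig | None = None,
    iqr_factor: float = 1.5,
    cutoff: float = 1.0,
    k1: float = -0.6,
    k2: float = 2.0,
    reference: tuple[int, int] | None = None,
) -> tuple[HemoSignals, HemoSignals]:
    """Full chain: OD -> motion correction -> Beer-Lambert -> low-pass -> HMS.

    Returns the (functional, systemic) hemoglobin signals.
    """
    cfg = cfg or BeerLambertConfig()
    od = intensity_to_od(raw, reference)
    od = wavelet_motion_correct(od, iqr_factor=iqr_factor)
    hemo = od_to_hemoglobin(od, cfg)
    hemo = HemoSignals(
        lowpass(hemo.hbo, hemo.fs, cutoff),
        lowpass(hemo.hbr, hemo.fs, cutoff),
        hemo.fs,
        list(hemo.channel_ids),
        "total",
    )
    return hms_separate(hemo, k1=k1, k2=k2)
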