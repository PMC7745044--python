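"""Readers and writers for the pipeline's on-disk formats.

Delimited text is the primary interchange: time x channel TSV for signals,
a symmetric TSV with channel headers for FC matrices, a 3-column events
file for paradigms, 2-column text for PPG, JSON for result summaries.
A minimal SNIRF (HDF5) reader/writer covers continuous-wave intensity
recordings (dataTimeSeries + measurementList + probe wavelengths).
"""

from __future__ import annotations

import importlib.resources
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .coherence import FCMatrix, TaskParadigm
from .hrv import PPGTrace
from .preprocess import HemoSignals, RawIntensity

__all__ = [
    "write_timeseries_tsv",
    "read_timeseries_tsv",
    "write_intensity_text",
    "read_intensity_text",
    "write_hemo_text",
    "read_hemo_text",
    "write_fc_tsv",
    "read_fc_tsv",
    "write_events",
    "read_events",
    "write_ppg_text",
    "read_ppg_text",
    "load_roi_map",
    "write_snirf",
    "read_snirf",
    "write_json",
]


def write_timeseries_tsv(path, time_s, data, channel_ids) -> None:
    """First column time in seconds, remaining columns one channel each."""
    df = pd.DataFrame(np.asarray(data), columns=list(channel_ids))
    df.insert(0, "time", np.asarray(time_s))
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_timeseries_tsv(path):
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected a time column plus channel columns")
    time = df.iloc[:, 0].to_numpy(dtype=float)
    data = df.iloc[:, 1:].to_numpy(dtype=float)
    return time, data, list(df.columns[1:])


def _fs_from_time(time: np.ndarray, path) -> float:
    dt = np.diff(time)
    if dt.size == 0 or dt.min() <= 0:
        raise ValueError(f"{path}: time column must be strictly increasing")
    return 1.0 / float(np.median(dt))


def write_intensity_text(prefix, raw: RawIntensity) -> tuple[Path, Path]:
    """One TSV per wavelength: ``<prefix>_wl<nm>.tsv``."""
    prefix = Path(prefix)
    t = np.arange(raw.n_times) / raw.fs
    paths = []
    for k, wl in enumerate(raw.wavelengths):
        p = prefix.with_name(f"{prefix.name}_wl{int(wl)}.tsv")
        write_timeseries_tsv(p, t, raw.data[:, :, k], raw.channel_ids)
        paths.append(p)
    return tuple(paths)


def read_intensity_text(path_wl1, path_wl2, wavelengths=(695.0, 830.0)) -> RawIntensity:
    t1, d1, ids1 = read_timeseries_tsv(path_wl1)
    t2, d2, ids2 = read_timeseries_tsv(path_wl2)
    if ids1 != ids2 or d1.shape != d2.shape:
        raise ValueError("wavelength files disagree on channels or length")
    fs = _fs_from_time(t1, path_wl1)
    return RawIntensity(np.stack([d1, d2], axis=-1), fs, tuple(wavelengths), ids1)


def write_hemo_text(prefix, hemo: HemoSignals) -> tuple[Path, Path]:
    prefix = Path(prefix)
    t = np.arange(hemo.n_times) / hemo.fs
    p_hbo = prefix.with_name(f"{prefix.name}_hbo.tsv")
    p_hbr = prefix.with_name(f"{prefix.name}_hbr.tsv")
    write_timeseries_tsv(p_hbo, t, hemo.hbo, hemo.channel_ids)
    write_timeseries_tsv(p_hbr, t, hemo.hbr, hemo.channel_ids)
    return p_hbo, p_hbr


def read_hemo_text(path_hbo, path_hbr, component_tag="total") -> HemoSignals:
    t, hbo, ids = read_timeseries_tsv(path_hbo)
    _, hbr, ids2 = read_timeseries_tsv(path_hbr)
    if ids != ids2:
        raise ValueError("HbO/HbR files disagree on channels")
    return HemoSignals(hbo, hbr, _fs_from_time(t, path_hbo), ids, component_tag)


def write_fc_tsv(path, fc: FCMatrix) -> None:
    pd.DataFrame(fc.weights, index=fc.channel_ids, columns=fc.channel_ids).to_csv(
        path, sep="\t", float_format="%.12g"
    )


def read_fc_tsv(path, roi_map=None) -> FCMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column channel labels differ")
    return FCMatrix(df.to_numpy(dtype=float), list(df.columns), roi_map=roi_map)


def write_events(path, paradigm: TaskParadigm) -> None:
    pd.DataFrame(paradigm.blocks, columns=["onset", "duration", "label"]).to_csv(
        path, sep="\t", index=False
    )


def read_events(path) -> TaskParadigm:
    df = pd.read_csv(path, sep="\t")
    need = ["onset", "duration", "label"]
    if list(df.columns[:3]) != need:
        raise ValueError(f"{path}: expected columns {need}")
    return TaskParadigm(
        [(float(r.onset), float(r.duration), str(r.label)) for r in df.itertuples()]
    )


def write_ppg_text(path, ppg: PPGTrace) -> None:
    t = np.arange(ppg.samples.size) / ppg.fs
    pd.DataFrame({"time": t, "amplitude": ppg.samples}).to_csv(
        path, sep="\t", index=False, float_format="%.8g"
    )


def read_ppg_text(path) -> PPGTrace:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected (time, amplitude) columns")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    return PPGTrace(df.iloc[:, 1].to_numpy(dtype=float), _fs_from_time(t, path))


def load_roi_map(path=None) -> dict[str, str]:
    """Channel -> hemisphere table; the packaged 32-channel prefrontal
    layout (a replaceable convention) when no path is given."""
    if path is None:
        ref = importlib.resources.files("semifc") / "data" / "roi_map.tsv"
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["channel", "hemisphere"]:
        raise ValueError("ROI map needs 'channel' and 'hemisphere' columns")
    return dict(zip(df["channel"], df["hemisphere"]))


def write_snirf(path, raw: RawIntensity) -> None:
    """Minimal continuous-wave SNIRF file (one data block)."""
    n_t, n_ch, _ = raw.data.shape
    flat = raw.data.reshape(n_t, n_ch * 2, order="F")  # wavelength-major blocks
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data=np.bytes_("1.0"))
        nirs = f.create_group("nirs")
        data1 = nirs.create_group("data1")
        data1.create_dataset("dataTimeSeries", data=flat)
        data1.create_dataset("time", data=np.arange(n_t) / raw.fs)
        for m in range(n_ch * 2):
            wl_idx, ch = divmod(m, n_ch)
            ml = data1.create_group(f"measurementList{m + 1}")
            ml.create_dataset("sourceIndex", data=ch + 1)
            ml.create_dataset("detectorIndex", data=ch + 1)
            ml.create_dataset("wavelengthIndex", data=wl_idx + 1)
            ml.create_dataset("dataType", data=1)
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(raw.wavelengths))


def read_snirf(path) -> RawIntensity:
    with h5py.File(path, "r") as f:
        nirs = f["nirs"] if "nirs" in f else f["nirs1"]
        data1 = nirs["data1"]
        flat = np.asarray(data1["dataTimeSeries"])
        time = np.asarray(data1["time"]).ravel()
        wavelengths = tuple(np.asarray(nirs["probe"]["wavelengths"]).ravel()[:2])
        ml_names = sorted(
            (k for k in data1 if k.startswith("measurementList")),
            key=lambda k: int(k[len("measurementList"):]),
        )
        wl_idx = np.array([int(data1[k]["wavelengthIndex"][()]) for k in ml_names])
        src = np.array([int(data1[k]["sourceIndex"][()]) for k in ml_names])
    fs = _fs_from_time(time, path)
    n_ch = flat.shape[1] // 2
    data = np.empty((flat.shape[0], n_ch, 2))
    for wl in (1, 2):
        cols = np.flatnonzero(wl_idx == wl)
        order = cols[np.argsort(src[cols])]
        data[:, :, wl - 1] = flat[:, order]
    return RawIntensity(data, fs, wavelengths, [f"ch{i + 1}" for i in range(n_ch)])


def write_json(path, obj) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default, sort_keys=True))
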