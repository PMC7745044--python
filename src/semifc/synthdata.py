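"""Seed-deterministic synthetic data with known ground truth.

Generates everything the pipeline consumes so each stage can be verified
without real recordings:

* fNIRS block-design recordings in which chosen channel groups share a
  band-limited (0.01-0.2 Hz) latent oscillation amplified during task
  blocks — the minimal generative structure wavelet coherence assumes;
* PPG pulse trains rendered from an NN-interval sequence whose RMSSD is
  calibrated to a requested target;
* toy FC networks whose semi-metric edge set (hence SMP) is known exactly
  by construction;
* whole two-group, two-session studies with optional planted group x state
  effects, returning the long-format study table.

Every generator takes a seed and returns identical output when re-run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .coherence import TaskParadigm, FCMatrix, build_fc_matrix
from .hrv import PPGTrace, NNSeries, ppg_to_hrv
from .preprocess import BeerLambertConfig, HemoSignals, hemoglobin_to_od, RawIntensity
from . import semimetric

__all__ = ["SimSpec", "gen_fnirs", "gen_ppg", "gen_toy_network", "gen_study"]


@dataclass
class SimSpec:
    """Conditions of a simulated recording / study.

    Defaults reproduce the validation-study conditions: 10 Hz dual-
    wavelength fNIRS over 32 prefrontal channels, a 20 s initial rest
    followed by five 60 s task blocks separated by 30 s rests, coupling in
    the 0.01-0.2 Hz band, 200 Hz PPG at 75 bpm with 50 ms target RMSSD,
    and two groups of 19 subjects.
    """

    seed: int = 0
    n_channels: int = 32
    fs: float = 10.0
    paradigm: TaskParadigm = field(default_factory=TaskParadigm.block_design)
    coupling_blocks: list[list[int]] | None = None  # channel index groups
    coupling_strength: float = 0.8  # latent mixing weight in [0, 1]
    task_gain: float = 2.0  # latent amplitude multiplier during task
    band: tuple[float, float] = (0.01, 0.2)
    noise_sd: float = 1.0
    k1: float = -0.6
    k2: float = 2.0
    systemic_amp: float = 0.5
    signal_amp: float = 1.0  # uM scale of the functional HbO signal
    ppg_fs: float = 200.0
    mean_hr_bpm: float = 75.0
    target_rmssd_ms: float = 50.0
    group_sizes: tuple[int, int] = (19, 19)  # (students, nurses)

    def rng(self, *salt: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, *salt])


def _bandlimited_noise(
    rng: np.random.Generator, n: int, fs: float, band: tuple[float, float]
) -> np.ndarray:
    """Unit-variance Gaussian noise restricted to a frequency band."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(freqs < band[0]) | (freqs > band[1])] = 0.0
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def gen_fnirs(spec: SimSpec) -> tuple[RawIntensity, HemoSignals]:
    """Simulate a dual-wavelength intensity recording plus its ground truth.

    Channels within one coupling block share a latent in-band oscillation
    (mixing weight ``coupling_strength``) amplified by ``task_gain`` during
    task blocks; the rest of each channel is independent in-band noise plus
    white sensor noise. HbR is built from the HMS mixing model
    (dHbR = k1*dHbO_f + k2*dHbO_s) and both chromophores are pushed through
    the forward Beer-Lambert model to intensities.

    Returns (raw intensity, ground-truth functional HemoSignals).
    """
    n = int(round(spec.paradigm.total_duration * spec.fs))
    n_ch = spec.n_channels
    blocks = spec.coupling_blocks
    if blocks is None:
        blocks = [[c] for c in range(n_ch)]
    seen: set[int] = set()
    for blk in blocks:
        if any(c in seen for c in blk):
            raise ValueError("coupling blocks must be disjoint")
        seen.update(blk)
    if seen - set(range(n_ch)):
        raise ValueError("coupling block channel index out of range")

    task = np.zeros(n)
    for sl in spec.paradigm.task_block_slices(spec.fs, n):
        task[sl] = 1.0
    envelope = 1.0 + (spec.task_gain - 1.0) * task

    rho = np.sqrt(np.clip(spec.coupling_strength, 0.0, 1.0))
    hbo_f = np.empty((n, n_ch))
    for b_idx, blk in enumerate(blocks):
        latent = _bandlimited_noise(spec.rng(1, b_idx), n, spec.fs, spec.band) * envelope
        for c in blk:
            own = _bandlimited_noise(spec.rng(2, c), n, spec.fs, spec.band) * envelope
            white = spec.rng(3, c).standard_normal(n)
            hbo_f[:, c] = spec.signal_amp * (
                rho * latent + np.sqrt(1 - rho**2) * own
            ) + spec.noise_sd * 0.1 * white

    systemic = _bandlimited_noise(spec.rng(4), n, spec.fs, (0.05, min(0.4, spec.fs / 2 * 0.9)))
    hbo_s = spec.systemic_amp * systemic[:, None] * np.ones((1, n_ch))

    channel_ids = [f"ch{i + 1}" for i in range(n_ch)]
    truth = HemoSignals(hbo_f, spec.k1 * hbo_f, spec.fs, channel_ids, "functional")
    total = HemoSignals(
        hbo_f + hbo_s,
        spec.k1 * hbo_f + spec.k2 * hbo_s,
        spec.fs,
        channel_ids,
        "total",
    )
    cfg = BeerLambertConfig()
    od = hemoglobin_to_od(total, cfg)
    intensity = 1000.0 * np.exp(-od.data)
    raw = RawIntensity(intensity, spec.fs, od.wavelengths, channel_ids)
    return raw, truth


def gen_nn_intervals(spec: SimSpec, n_beats: int | None = None) -> np.ndarray:
    """NN-interval sequence (ms) with exact target RMSSD and mean HR."""
    if not 60.0 < spec.mean_hr_bpm < 180.0:
        raise ValueError("mean heart rate must lie strictly inside (60, 180) bpm")
    mean_nn = 60000.0 / spec.mean_hr_bpm
    if n_beats is None:
        duration = spec.paradigm.total_duration
        n_beats = int(duration * 1000.0 / mean_nn) + 1
    rng = spec.rng(5)
    dev = rng.standard_normal(n_beats)
    dev -= dev.mean()
    if spec.target_rmssd_ms > 0:
        realized = np.sqrt((np.diff(dev) ** 2).sum() / (n_beats - 1))
        if realized == 0:
            raise ValueError("degenerate deviation draw")
        dev *= spec.target_rmssd_ms / realized
    else:
        dev[:] = 0.0
    nn = mean_nn + dev
    lo, hi = 60000.0 / 180.0, 60000.0 / 60.0
    if nn.min() < lo or nn.max() > hi:
        raise ValueError(
            f"target RMSSD {spec.target_rmssd_ms} ms infeasible at "
            f"{spec.mean_hr_bpm} bpm within the 60-180 bpm bounds"
        )
    return nn


def gen_ppg(spec: SimSpec, duration: float | None = None) -> tuple[PPGTrace, NNSeries]:
    """Render a PPG pulse train from a calibrated NN sequence.

    Each beat contributes an asymmetric Gaussian pulse (fast 80 ms rise,
    slow 180 ms decay); mild baseline wander and sensor noise are added.
    Returns the trace and the ground-truth NN series.
    """
    if duration is None:
        duration = spec.paradigm.total_duration
    mean_nn = 60000.0 / spec.mean_hr_bpm
    n_beats = int(duration * 1000.0 / mean_nn) + 2
    nn = gen_nn_intervals(spec, n_beats)
    beat_times = 0.5 + np.concatenate([[0.0], np.cumsum(nn)]) / 1000.0
    beat_times = beat_times[beat_times < duration - 0.3]
    fs = spec.ppg_fs
    t = np.arange(int(duration * fs)) / fs
    x = np.zeros_like(t)
    for tb in beat_times:
        sel = (t > tb - 0.5) & (t < tb + 0.8)
        dt = t[sel] - tb
        sigma = np.where(dt < 0, 0.08, 0.18)
        x[sel] += np.exp(-0.5 * (dt / sigma) ** 2)
    rng = spec.rng(6)
    drift = 0.1 * np.sin(2 * np.pi * 0.05 * t + rng.uniform(0, 2 * np.pi))
    noise = 0.01 * rng.standard_normal(t.size)
    truth_nn = np.diff(beat_times) * 1000.0
    return PPGTrace(x + drift + noise, fs), NNSeries(truth_nn, beat_times[1:])


def gen_toy_network(
    n: int,
    planted_semimetric: list[tuple[int, int]] | None = None,
    seed: int = 0,
    jitter: bool = True,
) -> FCMatrix:
    """Complete FC matrix with an exactly known semi-metric edge set.

    Backbone edges carry coherence near 0.5 (distance ~ 1), so every
    two-hop detour costs ~ 2 and all backbone edges are metric. Planted
    edges carry coherence near 0.2 (distance ~ 4 > 2), making exactly those
    edges semi-metric: SMP = len(planted) / C(n, 2) by construction.
    """
    if n < 3:
        raise ValueError("toy network needs at least 3 nodes")
    planted = [tuple(sorted(e)) for e in (planted_semimetric or [])]
    if len(set(planted)) != len(planted):
        raise ValueError("duplicate planted edges")
    pset = set(planted)
    for i, j in planted:
        if not (0 <= i < n and 0 <= j < n and i != j):
            raise ValueError(f"invalid planted edge ({i}, {j})")
        detours = [
            k
            for k in range(n)
            if k not in (i, j)
            and tuple(sorted((i, k))) not in pset
            and tuple(sorted((j, k))) not in pset
        ]
        if not detours:
            raise ValueError(
                f"planted edge ({i}, {j}) has no backbone detour; infeasible"
            )
    rng = np.random.default_rng(seed)
    w = np.full((n, n), 0.5)
    if jitter:
        u = rng.uniform(-0.05, 0.05, size=(n, n))
        w += np.triu(u, 1) + np.triu(u, 1).T
    for i, j in planted:
        val = rng.uniform(0.15, 0.25) if jitter else 0.2
        w[i, j] = w[j, i] = val
    np.fill_diagonal(w, 0.0)
    return FCMatrix(w, [f"n{i}" for i in range(n)])


def gen_study(
    spec: SimSpec,
    planted_effects: dict[tuple[str, str], dict[str, float]] | None = None,
    compute_hrv: bool = True,
    compute_graph: bool = False,
    n_coupling_blocks: int = 2,
) -> tuple[pd.DataFrame, dict]:
    """Simulate a full two-group, two-state study through the real pipeline.

    For each subject x state a recording is generated at the hemoglobin
    level (``gen_fnirs`` ground-truth path), the FC matrix is built by
    wavelet coherence, semi-metric analysis yields global and hemispheric
    SMP, and (optionally) a PPG trace yields RMSSD. ``planted_effects``
    maps (group, state) to overrides of SimSpec fields (e.g.
    ``{"coupling_strength": 0.4, "target_rmssd_ms": 30.0}``); absent keys
    leave the defaults, so an empty dict is a null study.

    Returns the long-format study table and the ground-truth description.
    """
    planted_effects = planted_effects or {}
    n_ch = spec.n_channels
    half = n_ch // 2
    roi_map = {f"ch{i + 1}": ("left_PFC" if i < half else "right_PFC") for i in range(n_ch)}
    block_size = max(1, n_ch // n_coupling_blocks)
    coupling = [
        list(range(b, min(b + block_size, n_ch))) for b in range(0, n_ch, block_size)
    ]
    rows = []
    subj_counter = 0
    for g_idx, (group, size) in enumerate(
        zip(("student", "nurse"), spec.group_sizes)
    ):
        if size < 2:
            raise ValueError("group sizes must be at least 2")
        for s in range(size):
            subj_counter += 1
            sid = f"{group[0]}{subj_counter:02d}"
            for st_idx, state in enumerate(("affective", "neutral")):
                overrides = dict(planted_effects.get((group, state), {}))
                sub_spec = replace(
                    spec,
                    seed=int(
                        np.random.default_rng(
                            [spec.seed, 7, g_idx, s, st_idx]
                        ).integers(2**31)
                    ),
                    coupling_blocks=coupling,
                    **overrides,
                )
                _, hemo = gen_fnirs(sub_spec)
                fc = build_fc_matrix(
                    hemo, sub_spec.paradigm, band=sub_spec.band, roi_map=roi_map
                )
                fc.hemisphere_excluded = set()
                res = semimetric.analyze(fc)
                rows.append((sid, group, state, "global", "SMP", res.smp_global))
                for roi, val in res.smp_regional.items():
                    rows.append((sid, group, state, roi, "SMP", val))
                if compute_graph:
                    from .graphmetrics import compute_graph_metrics

                    gm = compute_graph_metrics(fc, apply_exclusions=False)
                    for name, val in (
                        ("CC", gm.cc),
                        ("lambda", gm.lam),
                        ("E_global", gm.e_global),
                        ("E_local", gm.e_local),
                    ):
                        rows.append((sid, group, state, "global", name, val))
                    for roi, vals in gm.regional.items():
                        rows.append((sid, group, state, roi, "CC", vals["cc"]))
                        rows.append((sid, group, state, roi, "lambda", vals["lam"]))
                        rows.append((sid, group, state, roi, "E_nodal", vals["e_nodal"]))
                if compute_hrv:
                    ppg, _ = gen_ppg(sub_spec)
                    hrv = ppg_to_hrv(ppg)
                    rows.append((sid, group, state, "global", "RMSSD", hrv.rmssd))
    table = pd.DataFrame(
        rows, columns=["subject", "group", "state", "region", "index", "value"]
    )
    truth = {
        "planted_effects": planted_effects,
        "coupling_blocks": coupling,
        "roi_map": roi_map,
    }
    return table, truth
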