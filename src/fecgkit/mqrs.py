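"""Maternal R-peak detection: peak-enhancing transform + adaptive dual
threshold (ADT).

The transform converts the noise-canceled signal into a train of single
positive humps, one per QRS complex: a stationary wavelet decomposition
keeps only the detail scales spanning roughly 10-30 Hz (the QRS energy
band), the result is rectified by absolute value, then smoothed with a
moving-average window of about one QRS width.

The ADT detector keeps a low and a high threshold (thr_L < thr_H) derived
from the mean of the last 10 accepted peak amplitudes. A candidate peak P is
accepted outright when P >= thr_H; when thr_L < P < thr_H it is accepted
provisionally if it also exceeds 0.45 times the last accepted amplitude, in
which case thr_L is re-anchored at 0.45 * P and thr_H at
thr_L + |P - mean(history)| / 2. Every acceptance pushes P into the history
(FIFO of 10) and refreshes thr_L = 0.3 * mean, thr_H = 0.7 * mean. Both
thresholds are clamped from below (lim_L, lim_H) so a run of small noise
peaks cannot drag them to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import signal as sps

from .io import BeatAnnotation, MultichannelRecording, PipelineConfig

__all__ = ["ADTState", "peak_transform", "adt_detect", "detect_mqrs"]


@dataclass
class ADTState:
    """Mutable detector state; a snapshot is recorded at every acceptance."""

    thr_L: float
    thr_H: float
    lim_L: float
    lim_H: float
    peak_history: list[float] = field(default_factory=list)
    refractory_ms: float = 250.0

    def _mean_history(self) -> float:
        return float(np.mean(self.peak_history)) if self.peak_history else 0.0

    def push(self, amplitude: float, max_len: int = 10) -> None:
        self.peak_history.append(float(amplitude))
        if len(self.peak_history) > max_len:
            del self.peak_history[: len(self.peak_history) - max_len]

    def refresh(self) -> None:
        """Post-acceptance threshold update from the stored peak history."""
        mean = self._mean_history()
        self.thr_L = 0.3 * mean
        self.thr_H = 0.7 * mean
        self.clamp()

    def clamp(self) -> None:
        self.thr_L = max(self.thr_L, self.lim_L)
        self.thr_H = max(self.thr_H, self.lim_H)
        if self.thr_H <= self.thr_L:  # keep the dual-threshold ordering
            self.thr_H = self.thr_L * (0.7 / 0.3)

    def snapshot(self) -> dict:
        return {"thr_L": self.thr_L, "thr_H": self.thr_H,
                "lim_L": self.lim_L, "lim_H": self.lim_H}


def _swt_band_levels(fs: float, low_hz: float, high_hz: float,
                     max_level: int) -> list[int]:
    """SWT detail levels whose dyadic band [fs/2^(j+1), fs/2^j] intersects
    [low_hz, high_hz]."""
    levels = []
    for j in range(1, max_level + 1):
        band_lo, band_hi = fs / 2 ** (j + 1), fs / 2 ** j
        if band_hi > low_hz and band_lo < high_hz:
            levels.append(j)
    return levels or [max_level]


def peak_transform(
    x: np.ndarray, fs: float, config: PipelineConfig | None = None
) -> np.ndarray:
    """Map an ECG channel to a non-negative single-hump-per-beat envelope.

    Stationary wavelet decomposition -> reconstruct only the detail scales
    covering the QRS band -> absolute value -> moving-average smoothing.
    Output has the same length as the input.
    """
    if config is None:
        config = PipelineConfig()
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 2 * fs:
        raise ValueError("signal shorter than 2 s")

    # decompose just deep enough that the coarsest detail reaches the low
    # edge of the QRS band
    needed = int(np.ceil(np.log2(fs / config.mqrs_band_low_hz))) - 1
    max_level = max(1, min(config.wavelet_levels, needed))

    n = x.size
    pad_to = int(np.ceil(n / 2 ** max_level)) * 2 ** max_level
    xp = np.pad(x, (0, pad_to - n), mode="edge")
    coeffs = pywt.swt(xp, config.wavelet_name, level=max_level,
                      norm=True, trim_approx=False)
    # coeffs[k] = (cA_j, cD_j) with j = max_level - k
    keep = set(_swt_band_levels(fs, config.mqrs_band_low_hz,
                                config.mqrs_band_high_hz, max_level))
    filtered = []
    for k, (ca, cd) in enumerate(coeffs):
        j = max_level - k
        filtered.append((np.zeros_like(ca),
                         cd if j in keep else np.zeros_like(cd)))
    band = pywt.iswt(filtered, config.wavelet_name, norm=True)[:n]

    rectified = np.abs(band)
    win = max(1, int(round(config.mqrs_smooth_ms * fs / 1000.0)))
    kernel = np.ones(win) / win
    smoothed = sps.convolve(rectified, kernel, mode="same")
    return smoothed


def _local_maxima(y: np.ndarray, min_distance: int) -> np.ndarray:
    peaks, _ = sps.find_peaks(y, distance=max(1, min_distance))
    return peaks


def adt_detect(
    transformed: np.ndarray,
    fs: float,
    config: PipelineConfig | None = None,
    raw: np.ndarray | None = None,
) -> tuple[BeatAnnotation, list[dict]]:
    """Adaptive dual-threshold peak acceptance on a transformed envelope.

    Candidates are the local maxima of ``transformed`` outside the
    refractory window. Initialization uses the first 2 s: the mean of the 5
    largest local maxima seeds the thresholds and the peak history; the
    clamps lim_L and lim_H are fixed fractions of that estimate. When
    ``raw`` is given, each accepted index is refined to the extremum of the
    raw channel within +/-40 ms. Returns the annotation and a list of state
    snapshots, one per accepted beat.
    """
    if config is None:
        config = PipelineConfig()
    y = np.asarray(transformed, dtype=float).ravel()
    refractory = int(round(config.adt_refractory_ms * fs / 1000.0))
    peaks = _local_maxima(y, refractory)

    init_end = int(2.0 * fs)
    init_peaks = peaks[peaks < init_end]
    if init_peaks.size == 0:
        # fall back to the global structure of the first 5 s
        init_peaks = peaks[peaks < int(5.0 * fs)]
    if init_peaks.size == 0:
        raise RuntimeError("ADT initialization failed: no candidate peak "
                           "in the first 5 s")
    amps = np.sort(y[init_peaks])[::-1][:5]
    m_hat = float(np.mean(amps))
    state = ADTState(
        thr_L=0.3 * m_hat,
        thr_H=0.7 * m_hat,
        lim_L=config.adt_lim_L * m_hat,
        lim_H=config.adt_lim_H * m_hat,
        refractory_ms=config.adt_refractory_ms,
    )
    for a in amps[::-1]:
        state.push(float(a), config.adt_history)
    state.clamp()

    accepted: list[int] = []
    trace: list[dict] = []
    last_amp = m_hat
    last_idx = -refractory - 1
    for idx in peaks:
        if idx - last_idx < refractory:
            continue
        p = float(y[idx])
        accept = False
        if p >= state.thr_H:
            accept = True
        elif p > state.thr_L:
            # provisional path: require consistency with the last beat
            if p > 0.45 * last_amp:
                accept = True
                state.thr_L = 0.45 * p
                state.thr_H = state.thr_L + abs(p - state._mean_history()) / 2
                state.clamp()
        if not accept:
            continue
        state.push(p, config.adt_history)
        state.refresh()
        accepted.append(int(idx))
        trace.append(state.snapshot())
        last_amp = p
        last_idx = idx

    indices = np.asarray(accepted, dtype=np.int64)
    if raw is not None and indices.size:
        half = int(round(0.040 * fs))
        raw = np.asarray(raw, dtype=float).ravel()
        refined = []
        for i in indices:
            lo, hi = max(0, i - half), min(raw.size, i + half + 1)
            refined.append(lo + int(np.argmax(np.abs(raw[lo:hi]))))
        indices = np.asarray(refined, dtype=np.int64)
        # refinement can collapse neighbours; deduplicate preserving order
        keep = np.concatenate([[True], np.diff(indices) > 0])
        indices = indices[keep]
        trace = [t for t, k in zip(trace, keep) if k]

    ann = BeatAnnotation(indices=indices, beat_class="maternal",
                         provenance="detected", fs=fs)
    return ann, trace


def _fuse_majority(
    per_channel: list[np.ndarray], fs: float, window_ms: float = 50.0
) -> np.ndarray:
    """Majority-vote fusion of per-channel detections.

    All detections are pooled and clustered greedily with single-linkage at
    the matching window; clusters supported by at least half the channels
    survive, represented by their median index.
    """
    n_ch = len(per_channel)
    if n_ch == 1:
        return per_channel[0]
    window = window_ms * fs / 1000.0
    events = sorted(
        (int(i), ch) for ch, idx in enumerate(per_channel) for i in idx)
    fused = []
    cluster: list[tuple[int, int]] = []
    need = (n_ch // 2) + 1
    for ev in events:
        if cluster and ev[0] - cluster[-1][0] > window:
            chans = {c for _, c in cluster}
            if len(chans) >= need:
                fused.append(int(np.median([i for i, _ in cluster])))
            cluster = []
        cluster.append(ev)
    if cluster:
        chans = {c for _, c in cluster}
        if len(chans) >= need:
            fused.append(int(np.median([i for i, _ in cluster])))
    out = np.asarray(sorted(set(fused)), dtype=np.int64)
    return out


def detect_mqrs(
    rec: MultichannelRecording, config: PipelineConfig | None = None
) -> tuple[BeatAnnotation, list[list[dict]]]:
    """Run peak_transform + ADT on every channel and fuse by majority vote.

    Returns the fused maternal annotation and the per-channel state traces.
    """
    if config is None:
        config = PipelineConfig()
    per_channel = []
    traces = []
    for ch in range(rec.n_channels):
        env = peak_transform(rec.data[ch], rec.fs, config)
        ann, trace = adt_detect(env, rec.fs, config, raw=rec.data[ch])
        per_channel.append(ann.indices)
        traces.append(trace)
    fused = _fuse_majority(per_channel, rec.fs, config.match_window_ms)
    return (BeatAnnotation(indices=fused, beat_class="maternal",
                           provenance="detected", fs=rec.fs), traces)
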