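"""Signal preprocessing: invalid-sample repair, sample-entropy channel
quality assessment, and noise canceling.

Channel quality is scored with sample entropy (SampEn): each channel is cut
into non-overlapping 10 s segments, SampEn(m=2, r=0.2*SD) is computed per
segment, and the per-channel mean is compared against a fixed threshold of
1.5 — channels above it are considered too irregular (noise-dominated) and
excluded. If fewer than two channels survive, the two channels with the
smallest mean SampEn are retained instead, so blind source separation always
has at least two sensors.

Noise canceling applies, in order: a zero-phase IIR notch at the power-line
frequency, a zero-phase Butterworth high-pass against baseline drift, and a
short sliding median filter against single-sample impulsive artifacts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .io import MultichannelRecording, PipelineConfig

__all__ = [
    "QualityReport",
    "repair_invalid_samples",
    "sample_entropy",
    "assess_quality",
    "cancel_noise",
]


@dataclass
class QualityReport:
    """Per-channel SampEn scores and the retain/exclude decision."""

    per_channel_segment_sampen: np.ndarray  # (n_channels, n_segments)
    per_channel_mean: np.ndarray
    threshold: float
    retained: np.ndarray                    # boolean, per channel
    fallback_used: bool = False
    single_channel_warning: bool = False

    @property
    def retained_indices(self) -> np.ndarray:
        return np.flatnonzero(self.retained)


# --------------------------------------------------------------------------
# Invalid-sample repair


def _invalid_mask(x: np.ndarray, fs: float, saturation_uv: float | None,
                  flat_run_ms: float = 200.0) -> np.ndarray:
    """Samples considered invalid: NaN, |x| at the saturation limit, and
    members of constant runs of at least ``flat_run_ms``."""
    bad = np.isnan(x)
    if saturation_uv is not None:
        bad |= np.abs(x) >= saturation_uv
    # flat runs: consecutive equal samples lasting >= flat_run_ms
    min_run = max(2, int(round(flat_run_ms * fs / 1000.0)))
    with np.errstate(invalid="ignore"):
        same = np.concatenate([[False], np.diff(x) == 0.0])
    run_start = 0
    i = 1
    n = x.size
    while i <= n:
        if i == n or not same[i]:
            run_len = i - run_start
            if run_len >= min_run:
                bad[run_start:i] = True
            run_start = i
        i += 1
    return bad


def repair_invalid_samples(
    rec: MultichannelRecording,
    saturation_uv: float | None = None,
    flat_run_ms: float = 200.0,
    max_invalid_fraction: float = 0.5,
) -> tuple[MultichannelRecording, np.ndarray]:
    """Replace invalid samples by cubic-spline interpolation.

    Invalid samples are NaN values, samples at the declared saturation
    limit, and flat (constant) runs of at least ``flat_run_ms``. Valid
    samples are left untouched; runs at the signal boundary are filled by
    the spline's natural extrapolation. Returns the repaired recording and a
    boolean vector marking channels whose invalid fraction exceeded
    ``max_invalid_fraction`` (reported as unusable, still repaired).
    """
    data = rec.data.copy()
    unusable = np.zeros(rec.n_channels, dtype=bool)
    for ch in range(rec.n_channels):
        x = data[ch]
        bad = _invalid_mask(x, rec.fs, saturation_uv, flat_run_ms)
        if not bad.any():
            continue
        frac = bad.mean()
        if frac > max_invalid_fraction:
            unusable[ch] = True
        good = np.flatnonzero(~bad)
        if good.size < 4:  # not enough support for a cubic spline
            data[ch] = np.where(bad, 0.0 if good.size == 0 else
                                float(np.mean(x[good])), x)
            continue
        spline = CubicSpline(good, x[good], extrapolate=True)
        idx_bad = np.flatnonzero(bad)
        data[ch, idx_bad] = spline(idx_bad)
    return dataclasses.replace(rec, data=data), unusable


# --------------------------------------------------------------------------
# Sample entropy


def sample_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Sample entropy SampEn(m, r) of a 1-D series.

    Template vectors of length ``m`` are compared under the Chebyshev
    (maximum absolute difference) distance; ``B`` counts pairs matching at
    length ``m`` and ``A`` pairs still matching at length ``m + 1``,
    excluding self-matches. SampEn = -ln(A / B). Returns ``+inf`` when no
    pair matches at length ``m + 1`` and ``nan`` when none matches even at
    length ``m`` (ratio undefined).

    ``r`` defaults to 0.2 times the SD of ``x``.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if n <= m + 1:
        raise ValueError(f"series length {n} must exceed m + 1 = {m + 1}")
    if r is None:
        r = 0.2 * float(np.std(x))
    if r <= 0:
        raise ValueError("tolerance r must be positive")

    # Embed at m+1 once; length-m distances are the max over the first m
    # coordinate differences, so both counts come from one distance pass.
    n_templates = n - m  # number of (m+1)-length templates
    emb = np.lib.stride_tricks.sliding_window_view(x, m + 1)[:n_templates]
    b_count = 0
    a_count = 0
    # row-wise pass keeps memory at O(n * m) instead of O(n^2 * m)
    for i in range(n_templates - 1):
        diff = np.abs(emb[i + 1:] - emb[i])
        d_m = diff[:, :m].max(axis=1)
        match_m = d_m <= r
        b_count += int(match_m.sum())
        a_count += int((match_m & (diff[:, m] <= r)).sum())
    if b_count == 0:
        return float("nan")
    if a_count == 0:
        return float("inf")
    return float(-np.log(a_count / b_count))


def assess_quality(
    rec: MultichannelRecording, config: PipelineConfig | None = None
) -> QualityReport:
    """Score channels by mean segment SampEn and gate them at the threshold.

    Only full segments are scored, at most ``sampen_max_segments`` of them
    (six 10 s segments by default, i.e. the first minute of a longer
    recording). Channels whose mean exceeds the threshold
    are excluded; if fewer than two survive, the two smallest-mean channels
    are retained and ``fallback_used`` is set. A single-channel recording is
    always retained, with a warning flag.
    """
    if config is None:
        config = PipelineConfig()
    seg_len = int(round(config.sampen_segment_s * rec.fs))
    n_segments = min(rec.n_samples // seg_len, config.sampen_max_segments)
    if n_segments < 2:
        raise ValueError(
            f"recording too short for quality assessment: {rec.duration_s:.1f} s "
            f"< 2 segments of {config.sampen_segment_s:g} s")

    step = max(1, int(round(rec.fs / config.sampen_downsample_hz)))
    scores = np.empty((rec.n_channels, n_segments))
    for ch in range(rec.n_channels):
        for s in range(n_segments):
            seg = rec.data[ch, s * seg_len:(s + 1) * seg_len:step]
            sd = float(np.std(seg))
            if sd == 0.0:
                scores[ch, s] = 0.0  # constant segment: perfectly regular
                continue
            v = sample_entropy(seg, m=config.sampen_m,
                               r=config.sampen_r_factor * sd)
            scores[ch, s] = v if np.isfinite(v) else np.log(seg.size)  # cap inf
    means = scores.mean(axis=1)

    retained = means <= config.sampen_threshold
    fallback = False
    single_warn = False
    if rec.n_channels == 1:
        retained = np.array([True])
        single_warn = True
    elif retained.sum() < 2:
        order = np.argsort(means, kind="stable")
        retained = np.zeros(rec.n_channels, dtype=bool)
        retained[order[:2]] = True
        fallback = True
    return QualityReport(
        per_channel_segment_sampen=scores,
        per_channel_mean=means,
        threshold=config.sampen_threshold,
        retained=retained,
        fallback_used=fallback,
        single_channel_warning=single_warn,
    )


# --------------------------------------------------------------------------
# Noise canceling


def cancel_noise(
    rec: MultichannelRecording, config: PipelineConfig | None = None
) -> MultichannelRecording:
    """Remove power-line interference, baseline drift and impulsive artifacts.

    Order of operations: zero-phase IIR notch at ``notch_freq_hz``;
    zero-phase Butterworth high-pass at ``butter_highpass_hz``; sliding
    median filter of ``median_window_ms``. All three are (near) phase-neutral
    so QRS apex positions are preserved. Output length equals input length.
    """
    if config is None:
        config = PipelineConfig()
    if rec.fs <= 2 * config.notch_freq_hz:
        raise ValueError(
            f"fs={rec.fs} Hz cannot notch at {config.notch_freq_hz} Hz")
    b_notch, a_notch = sps.iirnotch(config.notch_freq_hz, config.notch_q,
                                    fs=rec.fs)
    sos_hp = sps.butter(config.butter_order, config.butter_highpass_hz,
                        btype="highpass", fs=rec.fs, output="sos")
    med_len = int(round(config.median_window_ms * rec.fs / 1000.0))
    med_len = max(3, med_len | 1)  # odd, at least 3

    data = np.empty_like(rec.data)
    for ch in range(rec.n_channels):
        x = sps.filtfilt(b_notch, a_notch, rec.data[ch])
        x = sps.sosfiltfilt(sos_hp, x)
        # median filter targets isolated impulses: subtract the deviation of
        # each sample from its local median only where it is an outlier, so
        # QRS peaks (wider than the window) pass through unchanged
        med = sps.medfilt(x, kernel_size=med_len)
        resid = x - med
        mad = np.median(np.abs(resid)) / 0.6745 + 1e-12
        impulsive = np.abs(resid) > 8.0 * mad
        x = np.where(impulsive, med, x)
        data[ch] = x
    return dataclasses.replace(rec, data=data)
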