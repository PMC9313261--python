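"""Beat-detection benchmarking: matching, metrics, summaries, agreement.

Detected beats are matched one-to-one to reference beats inside a +/-50 ms
window (greedy, nearest absolute time difference first, each beat used at
most once). From the TP/FP/FN counts:

    Se  = TP / (TP + FN)          sensitivity
    PPV = TP / (TP + FP)          positive predictive value
    ACC = TP / (TP + FP + FN)     accuracy
    F1  = 2 TP / (2 TP + FN + FP) harmonic mean of Se and PPV

reported as percentages rounded half-up to two decimals at the reporting
boundary only; full precision is retained internally. Fetal heart rate
series are 60/RR in bpm, and agreement between an estimated and a reference
FHR series is assessed Bland-Altman style with 95% limits of agreement at
bias +/- 1.96 SD of the paired differences.

The module also bundles the per-recording detection-count table of a
published three-posture abdominal-ECG benchmark (twelve two-minute
recordings from three subjects; printed counts are inputs here) so pooled
and per-posture summaries can be recomputed from counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import numpy as np
import pandas as pd

from .io import BeatAnnotation

__all__ = [
    "DetectionMetrics",
    "BlandAltmanResult",
    "match_beats",
    "compute_metrics",
    "summarize",
    "fhr_series",
    "bland_altman",
    "load_benchmark_counts",
]


def round_half_up(x: float, decimals: int = 2) -> float:
    """Decimal half-up rounding (0.005 -> 0.01), used only for reporting."""
    if not math.isfinite(x):
        return x
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class DetectionMetrics:
    """TP/FP/FN counts and the four derived percentages (full precision)."""

    tp: int
    fp: int
    fn: int
    se: float = field(init=False)
    ppv: float = field(init=False)
    acc: float = field(init=False)
    f1: float = field(init=False)

    def __post_init__(self) -> None:
        tp, fp, fn = self.tp, self.fp, self.fn
        if min(tp, fp, fn) < 0:
            raise ValueError("counts must be non-negative")
        self.se = 100.0 * tp / (tp + fn) if tp + fn > 0 else math.nan
        self.ppv = 100.0 * tp / (tp + fp) if tp + fp > 0 else math.nan
        self.acc = (100.0 * tp / (tp + fp + fn)
                    if tp + fp + fn > 0 else math.nan)
        self.f1 = (100.0 * 2 * tp / (2 * tp + fn + fp)
                   if 2 * tp + fn + fp > 0 else math.nan)

    @property
    def undefined(self) -> list[str]:
        """Metrics whose denominator was zero (flagged, never silently 0)."""
        out = []
        if self.tp + self.fn == 0:
            out.append("se")
        if self.tp + self.fp == 0:
            out.append("ppv")
        if self.tp + self.fp + self.fn == 0:
            out.append("acc")
        if 2 * self.tp + self.fn + self.fp == 0:
            out.append("f1")
        return out

    def rounded(self, decimals: int = 2) -> dict:
        return {k: round_half_up(getattr(self, k), decimals)
                for k in ("se", "ppv", "acc", "f1")}


@dataclass
class BlandAltmanResult:
    """Agreement between paired FHR estimates (bpm)."""

    pairs: np.ndarray      # (n, 2): estimated, reference
    bias: float
    sd: float
    loa_low: float
    loa_high: float


def match_beats(
    detected: BeatAnnotation,
    reference: BeatAnnotation,
    window_ms: float = 50.0,
) -> tuple[int, int, int, list[tuple[int, int]]]:
    """One-to-one greedy beat matching inside a +/-``window_ms`` window.

    All (detection, reference) pairs within the window are sorted by
    absolute time difference and assigned greedily, each index used at most
    once. Returns ``(TP, FP, FN, matched_pairs)`` where pairs hold
    (detected index position, reference index position).
    """
    if detected.fs != reference.fs:
        raise ValueError("annotations must share a sampling rate")
    window = window_ms * detected.fs / 1000.0
    det = detected.indices
    ref = reference.indices
    pairs = []
    for i, d in enumerate(det):
        lo = np.searchsorted(ref, d - window, side="left")
        hi = np.searchsorted(ref, d + window, side="right")
        for j in range(lo, hi):
            pairs.append((abs(int(d) - int(ref[j])), i, j))
    pairs.sort()
    used_d = np.zeros(det.size, dtype=bool)
    used_r = np.zeros(ref.size, dtype=bool)
    matched = []
    for _, i, j in pairs:
        if not used_d[i] and not used_r[j]:
            used_d[i] = used_r[j] = True
            matched.append((i, j))
    tp = len(matched)
    fp = int(det.size - tp)
    fn = int(ref.size - tp)
    return tp, fp, fn, sorted(matched)


def compute_metrics(tp: int, fp: int, fn: int) -> DetectionMetrics:
    """Se/PPV/ACC/F1 from counts; undefined ratios are NaN-flagged."""
    return DetectionMetrics(tp=tp, fp=fp, fn=fn)


def summarize(
    per_recording: list[DetectionMetrics],
    postures: list[str] | None = None,
) -> dict:
    """Pooled and macro-averaged summaries, overall and per posture group.

    Pooled metrics come from summed counts; macro averages are arithmetic
    means of the per-recording percentages with their population SD
    (n divisor — the convention is recorded in the output).
    """
    if not per_recording:
        raise ValueError("empty metrics list")
    if postures is None:
        postures = ["unknown"] * len(per_recording)
    if len(postures) != len(per_recording):
        raise ValueError("one posture label per recording required")

    def macro(group: list[DetectionMetrics]) -> dict:
        out = {}
        for k in ("se", "ppv", "acc", "f1"):
            vals = np.array([getattr(m, k) for m in group], dtype=float)
            out[f"{k}_mean"] = float(np.nanmean(vals))
            out[f"{k}_sd"] = float(np.sqrt(np.nanmean(
                (vals - np.nanmean(vals)) ** 2)))
        return out

    pooled = compute_metrics(
        sum(m.tp for m in per_recording),
        sum(m.fp for m in per_recording),
        sum(m.fn for m in per_recording))
    summary = {
        "pooled": pooled,
        "macro": macro(per_recording),
        "by_posture": {},
        "sd_convention": "population",
        "n_recordings": len(per_recording),
    }
    for pos in sorted(set(postures)):
        group = [m for m, p in zip(per_recording, postures) if p == pos]
        summary["by_posture"][pos] = {
            "pooled": compute_metrics(sum(m.tp for m in group),
                                      sum(m.fp for m in group),
                                      sum(m.fn for m in group)),
            "macro": macro(group),
            "n": len(group),
        }
    return summary


def fhr_series(ann: BeatAnnotation) -> np.ndarray:
    """Instantaneous heart rate in bpm, one value per RR interval.

    FHR_i = 60 / RR_i, attributed to the later beat of each interval; the
    returned vector has length ``len(ann) - 1``.
    """
    if len(ann) < 2:
        raise ValueError("need at least 2 beats for a rate series")
    return 60.0 / ann.rr_s


def bland_altman(
    estimated: np.ndarray, reference: np.ndarray
) -> BlandAltmanResult:
    """Bland-Altman agreement on paired rate estimates.

    ``bias`` is the mean of (estimated - reference); the 95% limits of
    agreement are bias +/- 1.96 SD of the differences (population SD).
    """
    est = np.asarray(estimated, dtype=float).ravel()
    ref = np.asarray(reference, dtype=float).ravel()
    if est.size != ref.size or est.size == 0:
        raise ValueError("estimated and reference series must be paired")
    diff = est - ref
    bias = float(np.mean(diff))
    sd = float(np.std(diff))
    return BlandAltmanResult(
        pairs=np.column_stack([est, ref]),
        bias=bias, sd=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd)


def matched_fhr_pairs(
    detected: BeatAnnotation,
    reference: BeatAnnotation,
    window_ms: float = 50.0,
) -> tuple[np.ndarray, np.ndarray]:
    """FHR pairs from beat-matched consecutive intervals.

    An interval contributes a pair only when both of its bounding beats are
    matched and the matches are consecutive on both sides.
    """
    _, _, _, pairs = match_beats(detected, reference, window_ms)
    if len(pairs) < 2:
        raise ValueError("fewer than 2 matched beats; no rate pairs")
    est, ref = [], []
    for (i0, j0), (i1, j1) in zip(pairs[:-1], pairs[1:]):
        if i1 == i0 + 1 and j1 == j0 + 1:
            rr_d = (detected.indices[i1] - detected.indices[i0]) / detected.fs
            rr_r = (reference.indices[j1] - reference.indices[j0]) / reference.fs
            est.append(60.0 / rr_d)
            ref.append(60.0 / rr_r)
    if len(est) < 2:
        raise ValueError("fewer than 2 matched consecutive intervals")
    return np.asarray(est), np.asarray(ref)


def load_benchmark_counts() -> pd.DataFrame:
    """Bundled per-recording fQRS detection counts of the three-posture
    abdominal-ECG benchmark (columns: subject, recording, posture, tp, fp,
    fn)."""
    with resources.files("fecgkit.data").joinpath(
            "ds_recording_counts.csv").open() as f:
        return pd.read_csv(f)
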