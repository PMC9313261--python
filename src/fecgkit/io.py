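"""Core data types and file I/O for abdominal-ECG processing.

The canonical in-memory containers are :class:`MultichannelRecording` (a
channels x samples matrix in microvolts with its sampling rate) and
:class:`BeatAnnotation` (strictly increasing 0-based R-peak sample indices).
All modules in the package consume and produce these types; all indexing is
0-based with half-open ranges, and conversion to seconds happens only at
reporting time.

Supported on-disk formats:

* CSV recordings — header row of channel labels, one sample per row, values
  in microvolts, with a JSON sidecar (``<path>.json``) carrying the sampling
  rate and metadata.
* WFDB records — a minimal MIT-format reader/writer (``.hea`` header plus
  format-16 ``.dat`` signal file) sufficient for single-segment records;
  amplitudes are converted to microvolts using the header's gain/baseline
  and units.
* Annotations — plain text, one sample index per line, a one-line header
  naming the beat class, provenance and sampling rate.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import yaml

__all__ = [
    "MultichannelRecording",
    "BeatAnnotation",
    "PipelineConfig",
    "read_recording",
    "write_recording",
    "read_annotation",
    "write_annotation",
    "load_config",
    "save_config",
]

Posture = Literal["supine", "seated", "standing", "unknown"]
BeatClass = Literal["maternal", "fetal"]
Provenance = Literal["reference", "detected"]


class FormatError(ValueError):
    """Raised when a file violates its declared on-disk format."""


@dataclass
class MultichannelRecording:
    """A multichannel sampled signal in microvolts.

    Parameters
    ----------
    fs : float
        Sampling rate in Hz (positive).
    data : ndarray, shape (n_channels, n_samples)
        Amplitudes in microvolts. Raw recordings may contain NaN until
        :func:`fecgkit.preprocessing.repair_invalid_samples` is applied.
    """

    fs: float
    data: np.ndarray
    channel_labels: list[str] = field(default_factory=list)
    posture: Posture = "unknown"
    subject_id: str = ""
    record_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.data.ndim != 2 or self.data.shape[0] < 1:
            raise ValueError("data must be a (n_channels, n_samples) matrix")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i + 1}" for i in range(self.n_channels)]
        if len(self.channel_labels) != self.n_channels:
            raise ValueError("one label per channel required")
        if self.posture not in ("supine", "seated", "standing", "unknown"):
            raise ValueError(f"unknown posture {self.posture!r}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def select_channels(self, idx) -> "MultichannelRecording":
        """Return a copy restricted to the given channel indices."""
        idx = np.atleast_1d(np.asarray(idx, dtype=int))
        return dataclasses.replace(
            self,
            data=self.data[idx].copy(),
            channel_labels=[self.channel_labels[i] for i in idx],
        )


@dataclass
class BeatAnnotation:
    """Ordered R-peak sample indices for one beat class.

    ``indices`` are strictly increasing 0-based sample positions; ``fs`` is
    copied from the recording the annotation refers to so that times in
    seconds can be recovered without the recording at hand.
    """

    indices: np.ndarray
    beat_class: BeatClass = "fetal"
    provenance: Provenance = "detected"
    fs: float = 500.0

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64).ravel()
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.indices.size and np.any(np.diff(self.indices) <= 0):
            raise ValueError("annotation indices must be strictly increasing")
        if self.indices.size and self.indices[0] < 0:
            raise ValueError("annotation indices must be non-negative")

    def __len__(self) -> int:
        return int(self.indices.size)

    @property
    def times_s(self) -> np.ndarray:
        return self.indices / self.fs

    @property
    def rr_s(self) -> np.ndarray:
        """RR intervals in seconds (length ``len(self) - 1``)."""
        return np.diff(self.indices) / self.fs

    def mean_rate_bpm(self) -> float:
        rr = self.rr_s
        if rr.size == 0:
            return math.nan
        return float(np.mean(60.0 / rr))


# --------------------------------------------------------------------------
# Configuration


@dataclass
class PipelineConfig:
    """All tunable parameters of the extraction pipeline, with defaults.

    Time-like parameters are expressed in milliseconds or seconds (never in
    samples) and converted per-recording, so the same configuration drives
    500 Hz and 1 kHz records alike.
    """

    # --- sample-entropy channel quality gate
    sampen_m: int = 2                    # embedding dimension
    sampen_r_factor: float = 0.2         # tolerance as a fraction of segment SD
    sampen_segment_s: float = 10.0       # non-overlapping segment length
    sampen_threshold: float = 1.5        # mean-SampEn rejection threshold
    sampen_max_segments: int = 6         # segments scored per channel
    sampen_downsample_hz: float = 125.0  # rate SampEn is computed at (bounds O(N^2))

    # --- noise canceling
    notch_freq_hz: float = 50.0
    notch_q: float = 35.0
    butter_order: int = 4
    butter_highpass_hz: float = 1.0
    median_window_ms: float = 10.0

    # --- maternal QRS (adaptive dual threshold)
    mqrs_band_low_hz: float = 10.0
    mqrs_band_high_hz: float = 30.0
    mqrs_smooth_ms: float = 150.0
    adt_lim_L: float = 0.1               # lower clamp for thr_L, x init estimate
    adt_lim_H: float = 0.3               # lower clamp for thr_H, x init estimate
    adt_refractory_ms: float = 250.0
    adt_history: int = 10                # accepted-peak amplitudes retained

    # --- fetal QRS
    fetal_refractory_ms: float = 100.0
    fetal_rr_min_s: float = 0.375        # 160 bpm
    fetal_rr_max_s: float = 0.545        # 110 bpm
    fqrs_trapezoid_plateau_ms: float = 25.0
    fqrs_trapezoid_ramp_ms: float = 100.0
    fqrs_trapezoid_floor: float = 0.1
    fqrs_enforce_refractory: bool = True

    # --- wavelets
    wavelet_name: str = "db4"
    wavelet_levels: int = 5

    # --- evaluation
    match_window_ms: float = 50.0

    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.sampen_m < 1:
            raise ValueError("sampen_m must be >= 1")
        for name in ("sampen_r_factor", "sampen_segment_s", "sampen_threshold",
                     "notch_freq_hz", "notch_q", "butter_highpass_hz",
                     "median_window_ms", "mqrs_smooth_ms", "adt_refractory_ms",
                     "fetal_refractory_ms", "fetal_rr_min_s", "fetal_rr_max_s",
                     "match_window_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.adt_lim_L < self.adt_lim_H:
            raise ValueError("require 0 < adt_lim_L < adt_lim_H")
        if self.fetal_rr_min_s >= self.fetal_rr_max_s:
            raise ValueError("fetal_rr_min_s must be < fetal_rr_max_s")
        if self.mqrs_band_low_hz >= self.mqrs_band_high_hz:
            raise ValueError("mqrs band limits inverted")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def load_config(path) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a flat YAML or JSON file.

    Unknown keys are an error: a silent typo in a tunable would invalidate
    every downstream result.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text)  # YAML is a superset of JSON
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise FormatError("config file must contain a flat mapping")
    return PipelineConfig.from_dict(data)


def save_config(config: PipelineConfig, path) -> None:
    p = Path(path)
    d = config.to_dict()
    if p.suffix == ".json":
        p.write_text(json.dumps(d, indent=2) + "\n")
    else:
        p.write_text(yaml.safe_dump(d, sort_keys=False))


# --------------------------------------------------------------------------
# Recording I/O


def read_recording(path, format: str = "csv") -> MultichannelRecording:
    """Read a multichannel recording from disk, converting to microvolts."""
    if format == "csv":
        return _read_csv(Path(path))
    if format == "wfdb":
        return _read_wfdb(Path(path))
    raise ValueError(f"unknown recording format {format!r}")


def write_recording(rec: MultichannelRecording, path, format: str = "csv") -> None:
    if format == "csv":
        _write_csv(rec, Path(path))
    elif format == "wfdb":
        _write_wfdb(rec, Path(path))
    else:
        raise ValueError(f"unknown recording format {format!r}")


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _read_csv(path: Path) -> MultichannelRecording:
    import pandas as pd

    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except OSError as e:
        raise IOError(f"cannot read recording {path}: {e}") from e
    meta_path = _sidecar(path)
    if not meta_path.exists():
        raise IOError(f"missing sampling-rate sidecar {meta_path}")
    meta = json.loads(meta_path.read_text())
    if "fs" not in meta:
        raise FormatError(f"sidecar {meta_path} lacks 'fs'")
    scale = {"uV": 1.0, "mV": 1000.0, "V": 1e6}.get(meta.get("units", "uV"))
    if scale is None:
        raise FormatError(f"unsupported units {meta.get('units')!r}")
    return MultichannelRecording(
        fs=float(meta["fs"]),
        data=df.to_numpy(dtype=float).T * scale,
        channel_labels=[str(c) for c in df.columns],
        posture=meta.get("posture", "unknown"),
        subject_id=meta.get("subject_id", ""),
        record_id=meta.get("record_id", path.stem),
    )


def _write_csv(rec: MultichannelRecording, path: Path) -> None:
    import pandas as pd

    pd.DataFrame(rec.data.T, columns=rec.channel_labels).to_csv(path, index=False)
    meta = {
        "fs": rec.fs,
        "units": "uV",
        "posture": rec.posture,
        "subject_id": rec.subject_id,
        "record_id": rec.record_id,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2) + "\n")


# Minimal MIT-format (WFDB) support: single-segment records, one .dat file,
# signal format 16 (little-endian int16). physical = (adc - baseline) / gain.
_WFDB_UNIT_UV = {"uV": 1.0, "uv": 1.0, "mV": 1000.0, "mv": 1000.0, "V": 1e6}


def _read_wfdb(path: Path) -> MultichannelRecording:
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea.exists():
        raise IOError(f"missing WFDB header {hea}")
    lines = [ln for ln in hea.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    rec_fields = lines[0].split()
    record_name = rec_fields[0]
    n_sig = int(rec_fields[1])
    fs = float(rec_fields[2]) if len(rec_fields) > 2 else 250.0
    n_samples = int(rec_fields[3]) if len(rec_fields) > 3 else 0
    if len(lines) < 1 + n_sig:
        raise FormatError(f"{hea}: expected {n_sig} signal lines")

    dat_names, gains, baselines, scales, labels = [], [], [], [], []
    for ln in lines[1 : 1 + n_sig]:
        parts = ln.split()
        dat_names.append(parts[0])
        if int(parts[1]) != 16:
            raise FormatError(f"only WFDB signal format 16 supported, got {parts[1]}")
        gain_spec = parts[2] if len(parts) > 2 else "200"
        units = "mV"
        if "/" in gain_spec:
            gain_spec, units = gain_spec.split("/", 1)
        baseline = 0
        if "(" in gain_spec:
            gain_spec, rest = gain_spec.split("(", 1)
            baseline = int(rest.rstrip(")"))
        gain = float(gain_spec) or 200.0
        if units not in _WFDB_UNIT_UV:
            raise FormatError(f"unsupported WFDB units {units!r}")
        gains.append(gain)
        baselines.append(baseline)
        scales.append(_WFDB_UNIT_UV[units])
        labels.append(parts[-1] if len(parts) > 3 else f"ch{len(labels) + 1}")

    if len(set(dat_names)) != 1:
        raise FormatError("multi-file WFDB records are not supported")
    dat = hea.parent / dat_names[0]
    raw = np.fromfile(dat, dtype="<i2")
    if n_samples and raw.size != n_samples * n_sig:
        raise FormatError(
            f"{dat}: expected {n_samples * n_sig} samples, found {raw.size}")
    adc = raw.reshape(-1, n_sig).T.astype(float)
    data = np.empty_like(adc)
    for i in range(n_sig):
        data[i] = (adc[i] - baselines[i]) / gains[i] * scales[i]
    return MultichannelRecording(
        fs=fs, data=data, channel_labels=labels, record_id=record_name)


def _write_wfdb(rec: MultichannelRecording, path: Path) -> None:
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    name = hea.stem
    dat_name = name + ".dat"
    # pick a per-channel gain that uses most of the int16 range
    peak = np.maximum(np.nanmax(np.abs(rec.data), axis=1), 1e-9)
    gains = 30000.0 / peak  # adc units per uV
    adc = np.round(rec.data * gains[:, None]).astype("<i2")
    lines = [f"{name} {rec.n_channels} {rec.fs:g} {rec.n_samples}"]
    for i in range(rec.n_channels):
        lines.append(
            f"{dat_name} 16 {gains[i]:.6f}(0)/uV 16 0 0 0 0 {rec.channel_labels[i]}")
    hea.write_text("\n".join(lines) + "\n")
    adc.T.tofile(hea.parent / dat_name)


# --------------------------------------------------------------------------
# Annotation I/O


def write_annotation(ann: BeatAnnotation, path) -> None:
    """Write an annotation as plain text, one 0-based sample index per line."""
    header = (f"# beat_class={ann.beat_class} provenance={ann.provenance} "
              f"fs={ann.fs:g}")
    body = "\n".join(str(int(i)) for i in ann.indices)
    Path(path).write_text(header + ("\n" + body if body else "") + "\n")


def read_annotation(path, fs: float | None = None) -> BeatAnnotation:
    """Read an annotation written by :func:`write_annotation`.

    ``fs`` overrides the header value when given (e.g. annotations produced
    by external tools that record indices only).
    """
    lines = Path(path).read_text().splitlines()
    beat_class, provenance, header_fs = "fetal", "reference", None
    data_lines = []
    for ln in lines:
        ln = ln.strip()
        if not ln:
            continue
        if ln.startswith("#"):
            for tok in ln[1:].split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    if k == "beat_class":
                        beat_class = v
                    elif k == "provenance":
                        provenance = v
                    elif k == "fs":
                        header_fs = float(v)
        else:
            data_lines.append(ln)
    try:
        indices = np.array([int(x) for x in data_lines], dtype=np.int64)
    except ValueError as e:
        raise FormatError(f"non-integer annotation line in {path}: {e}") from e
    if indices.size and np.any(np.diff(indices) <= 0):
        raise FormatError(f"annotation indices in {path} are not strictly increasing")
    use_fs = fs if fs is not None else (header_fs if header_fs is not None else 500.0)
    return BeatAnnotation(indices=indices, beat_class=beat_class,
                          provenance=provenance, fs=use_fs)
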