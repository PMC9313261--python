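"""Repair, sample entropy, quality gating and noise canceling."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fecgkit.io import MultichannelRecording, PipelineConfig
from fecgkit.preprocessing import (assess_quality, cancel_noise,
                                   repair_invalid_samples, sample_entropy)
from fecgkit.synthetic import SyntheticConfig, synthesize_aecg


def sampen_bruteforce(x, m, r):
    """O(N^2) double-loop reference, written independently of the
    vectorized implementation: full pairwise Chebyshev template counting
    with self-matches excluded."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    b = a = 0
    for i in range(n - m):
        for j in range(n - m):
            if i == j:
                continue
            d_m = max(abs(x[i + k] - x[j + k]) for k in range(m))
            if d_m <= r:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    if b == 0:
        return float("nan")
    if a == 0:
        return float("inf")
    return -np.log(a / b)


# --------------------------------------------------------------------------
# repair_invalid_samples


def test_repair_identity_on_clean_signal():
    rec = MultichannelRecording(fs=500, data=np.sin(np.arange(2000) * 0.01)[None])
    out, unusable = repair_invalid_samples(rec)
    np.testing.assert_array_equal(out.data, rec.data)
    assert not unusable.any()


def test_repair_recovers_cubic_polynomial():
    t = np.linspace(0, 1, 400)
    poly = 2 * t**3 - t**2 + 0.5 * t - 1
    x = poly.copy()
    x[200] = np.nan
    rec = MultichannelRecording(fs=500, data=x[None])
    out, _ = repair_invalid_samples(rec)
    assert out.data[0, 200] == pytest.approx(poly[200], abs=1e-6)
    np.testing.assert_array_equal(np.delete(out.data[0], 200),
                                  np.delete(poly, 200))


def test_repair_leading_nan_run_and_flat_run():
    rng = np.random.default_rng(0)
    x = rng.normal(0, 10, 3000)
    x[:50] = np.nan
    x[1000:1150] = 3.21  # 300 ms flat run at 500 Hz
    rec = MultichannelRecording(fs=500, data=x[None])
    out, _ = repair_invalid_samples(rec)
    assert np.isfinite(out.data).all()
    # flat run replaced by interpolation, no longer constant
    assert np.std(out.data[0, 1000:1150]) > 0


def test_repair_reports_mostly_invalid_channel():
    x = np.full(2000, np.nan)
    x[::10] = 1.0
    good = np.sin(np.arange(2000) * 0.05)
    rec = MultichannelRecording(fs=500, data=np.vstack([x, good]))
    out, unusable = repair_invalid_samples(rec)
    assert unusable[0] and not unusable[1]


# --------------------------------------------------------------------------
# sample_entropy


def test_sampen_constant_vector_is_zero():
    assert sample_entropy(np.ones(50), m=2, r=0.5) == 0.0


def test_sampen_alternating_sequence_matches_bruteforce():
    x = np.array([0, 1, 0, 1, 0, 1, 0, 1, 0, 1], dtype=float)
    expected = sampen_bruteforce(x, 2, 0.5)
    assert sample_entropy(x, m=2, r=0.5) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("n,m,seed", [(120, 2, 0), (200, 2, 1), (200, 3, 2),
                                      (150, 1, 3)])
def test_sampen_equals_bruteforce_on_noise(n, m, seed):
    x = np.random.default_rng(seed).normal(size=n)
    r = 0.2 * np.std(x)
    assert sample_entropy(x, m=m, r=r) == pytest.approx(
        sampen_bruteforce(x, m, r), abs=1e-12)


def test_sampen_parameter_errors():
    with pytest.raises(ValueError):
        sample_entropy(np.arange(3), m=2, r=0.1)
    with pytest.raises(ValueError):
        sample_entropy(np.arange(50), m=2, r=-1.0)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(shift=st.floats(-50, 50), scale=st.floats(0.1, 10),
       seed=st.integers(0, 100))
def test_sampen_invariant_to_shift_and_scale(shift, scale, seed):
    """Additive constants never change SampEn; positive rescaling does not
    when r scales with the data SD."""
    x = np.random.default_rng(seed).normal(size=150)
    r = 0.2 * np.std(x)
    base = sample_entropy(x, 2, r)
    assert sample_entropy(x + shift, 2, r) == pytest.approx(base, abs=1e-10)
    assert sample_entropy(scale * x, 2, scale * r) == pytest.approx(
        base, abs=1e-10)


# --------------------------------------------------------------------------
# assess_quality


def _recording_with_channels(channels, fs=500.0):
    return MultichannelRecording(fs=fs, data=np.vstack(channels))


def _sine(n, fs, f=1.3):
    return 100 * np.sin(2 * np.pi * f * np.arange(n) / fs)


def test_quality_gate_rule_and_segmentation(default_config):
    """Regular channels pass the 1.5 threshold, white-noise channels fail;
    a 120 s record is scored on exactly six 10 s segments."""
    fs, n = 500.0, 60_000
    rng = np.random.default_rng(1)
    rec = _recording_with_channels([
        _sine(n, fs), rng.normal(0, 50, n), _sine(n, fs, 0.9)], fs)
    rep = assess_quality(rec, default_config)
    assert rep.per_channel_segment_sampen.shape == (3, 6)
    assert list(rep.retained) == [True, False, True]
    assert not rep.fallback_used
    np.testing.assert_allclose(
        rep.per_channel_mean, rep.per_channel_segment_sampen.mean(axis=1))


def test_quality_fallback_keeps_two_best(default_config):
    fs, n = 500.0, 10_000
    rng = np.random.default_rng(2)
    cfg = dataclasses.replace(default_config, sampen_segment_s=2.0)
    rec = _recording_with_channels(
        [rng.normal(0, s, n) for s in (30, 10, 20)], fs)
    rep = assess_quality(rec, cfg)
    assert rep.fallback_used
    assert rep.retained.sum() == 2
    order = np.argsort(rep.per_channel_mean)
    assert set(rep.retained_indices) == set(order[:2])


def test_quality_single_channel_warning(default_config):
    rec = _recording_with_channels([_sine(15_000, 500.0)])
    rep = assess_quality(rec, default_config)
    assert rep.retained[0] and rep.single_channel_warning


def test_quality_permutation_equivariance(default_config):
    fs, n = 500.0, 25_000
    rng = np.random.default_rng(3)
    chans = [_sine(n, fs), rng.normal(0, 40, n), _sine(n, fs, 2.1)]
    rep = assess_quality(_recording_with_channels(chans, fs), default_config)
    perm = [2, 0, 1]
    rep_p = assess_quality(
        _recording_with_channels([chans[i] for i in perm], fs), default_config)
    np.testing.assert_allclose(rep_p.per_channel_mean,
                               rep.per_channel_mean[perm])
    np.testing.assert_array_equal(rep_p.retained, rep.retained[perm])


# --------------------------------------------------------------------------
# cancel_noise


def test_powerline_suppressed_by_40db(default_config):
    fs, n = 500.0, 30_000
    t = np.arange(n) / fs
    x = 50 * np.sin(2 * np.pi * 50.0 * t)
    rec = MultichannelRecording(fs=fs, data=x[None])
    out = cancel_noise(rec, default_config)
    k = int(round(50.0 * n / fs))
    mag_in = np.abs(np.fft.rfft(x))[k]
    mag_out = np.abs(np.fft.rfft(out.data[0]))[k]
    assert 20 * np.log10(mag_in / mag_out) >= 40.0
    assert out.n_samples == n


def test_baseline_drift_suppressed(default_config):
    fs, n = 500.0, 30_000
    t = np.arange(n) / fs
    x = 100 * np.sin(2 * np.pi * 0.1 * t)
    out = cancel_noise(MultichannelRecording(fs=fs, data=x[None]),
                       default_config)
    assert np.sqrt(np.mean(out.data[0] ** 2)) <= 0.1 * np.sqrt(np.mean(x**2))


def test_zero_in_zero_out(default_config):
    out = cancel_noise(MultichannelRecording(fs=500, data=np.zeros((2, 5000))),
                       default_config)
    np.testing.assert_allclose(out.data, 0.0, atol=1e-12)


def test_filtering_is_phase_neutral(default_config):
    """A clean synthetic QRS train's peak indices move by <= 1 sample."""
    rec, truth = synthesize_aecg(SyntheticConfig(
        duration_s=30, rng_seed=0, baseline_uv=0, powerline_uv=0,
        broadband_sd_uv=0, impulse_rate_per_s=0))
    out = cancel_noise(rec, default_config)
    for i in truth.maternal_r.indices:
        lo, hi = max(0, i - 20), min(rec.n_samples, i + 21)
        before = lo + np.argmax(np.abs(rec.data[0, lo:hi]))
        after = lo + np.argmax(np.abs(out.data[0, lo:hi]))
        assert abs(int(after) - int(before)) <= 1
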