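"""Whitening, JADE separation and maternal-ECG cancellation."""

import numpy as np
import pytest

from fecgkit.io import BeatAnnotation, MultichannelRecording, PipelineConfig
from fecgkit.mecg import (cancel_mecg, center_and_whiten,
                          identify_maternal_components, jade_separate,
                          subtract_mecg)
from fecgkit.mqrs import detect_mqrs
from fecgkit.preprocessing import cancel_noise
from fecgkit.synthetic import SyntheticConfig, synthesize_aecg


def two_nongaussian_sources(n=20_000, fs=1000.0):
    """Deterministic, non-Gaussian, zero-mean pair: 3 Hz square and 7 Hz
    sawtooth."""
    t = np.arange(n) / fs
    s1 = np.sign(np.sin(2 * np.pi * 3.0 * t))
    s2 = 2 * ((7.0 * t) % 1.0) - 1.0
    return np.vstack([s1, s2])


# --------------------------------------------------------------------------
# center_and_whiten


def test_whitening_centers_and_decorrelates():
    rng = np.random.default_rng(0)
    x = rng.normal(size=(3, 5000)) * np.array([[3.0], [1.0], [0.3]]) + 5.0
    x = np.array([[1.0, 0.2, 0.1], [0.0, 1.0, 0.5], [0.3, 0.1, 1.0]]) @ x
    w, wm, mean = center_and_whiten(x)
    np.testing.assert_allclose(w.mean(axis=1), 0.0, atol=1e-12)
    cov = w @ w.T / w.shape[1]
    np.testing.assert_allclose(cov, np.eye(3), atol=1e-8)


def test_whitening_known_diagonal_covariance():
    """2xN data constructed with covariance diag(4, 1): whitened covariance
    is the identity (direct covariance oracle)."""
    rng = np.random.default_rng(1)
    n = 200_000
    x = np.vstack([2.0 * rng.standard_normal(n), rng.standard_normal(n)])
    w, _, _ = center_and_whiten(x)
    np.testing.assert_allclose(w @ w.T / n, np.eye(2), atol=1e-8)


def test_whitening_reduces_rank_deficient_input():
    rng = np.random.default_rng(2)
    base = rng.normal(size=5000)
    x = np.vstack([base, base])  # identical channels
    w, wm, _ = center_and_whiten(x)
    assert w.shape[0] == 1


# --------------------------------------------------------------------------
# jade_separate


def test_jade_recovers_constructed_sources():
    s = two_nongaussian_sources()
    mix = np.array([[0.9, 0.4], [0.3, 0.8]])
    res = jade_separate(mix @ s)
    corr = np.abs(np.corrcoef(np.vstack([res.components, s]))[:2, 2:])
    # each component matches one distinct source
    best = corr.argmax(axis=1)
    assert sorted(best) == [0, 1]
    assert corr.max(axis=1).min() >= 0.95


def test_jade_identity_on_independent_input():
    s = two_nongaussian_sources(n=10_000)
    res = jade_separate(s)
    w_total = res.unmixing_matrix
    # undo the per-source scale left by whitening: rows should then be a
    # signed permutation
    scaled = w_total * s.std(axis=1)[None, :]
    scaled /= np.abs(scaled).max(axis=1, keepdims=True)
    for row in scaled:
        mags = np.sort(np.abs(row))
        assert mags[-1] == pytest.approx(1.0, abs=1e-6)
        assert mags[:-1].max() < 0.05


def test_back_projection_reconstructs_centered_input():
    rng = np.random.default_rng(3)
    s = two_nongaussian_sources(n=8000)
    x = np.array([[0.9, 0.4], [0.3, 0.8], [0.5, 0.6]]) @ s
    x += rng.normal(0, 0.05, size=x.shape)
    res = jade_separate(x)
    recon = res.back_projection @ res.components
    centered = x - x.mean(axis=1, keepdims=True)
    assert np.abs(recon - centered).max() <= 1e-8 * np.abs(centered).max()


def test_jade_agrees_with_fastica_cross_check():
    """An independent ICA route (sklearn FastICA) recovers components that
    match JADE's on a constructed mixture, up to permutation and sign."""
    from sklearn.decomposition import FastICA

    s = two_nongaussian_sources(n=12_000)
    x = np.array([[0.9, 0.4], [0.3, 0.8]]) @ s
    jade_comps = jade_separate(x).components
    fica = FastICA(n_components=2, whiten="unit-variance", random_state=0,
                   max_iter=2000)
    fica_comps = fica.fit_transform(x.T).T
    corr = np.abs(np.corrcoef(np.vstack([jade_comps, fica_comps]))[:2, 2:])
    assert sorted(corr.argmax(axis=1)) == [0, 1]
    assert corr.max(axis=1).min() >= 0.95


def test_jade_deterministic():
    s = two_nongaussian_sources(n=6000)
    x = np.array([[0.9, 0.4], [0.3, 0.8]]) @ s
    r1 = jade_separate(x)
    r2 = jade_separate(x)
    np.testing.assert_array_equal(r1.components, r2.components)


# --------------------------------------------------------------------------
# maternal component identification / subtraction


@pytest.fixture(scope="module")
def separated_aecg(default_aecg):
    cfg = PipelineConfig()
    rec, truth = default_aecg
    clean = cancel_noise(rec, cfg)
    mqrs, _ = detect_mqrs(clean, cfg)
    sep = jade_separate(clean.data)
    return cfg, clean, truth, mqrs, sep


def test_identify_maternal_component(separated_aecg):
    cfg, clean, truth, mqrs, sep = separated_aecg
    idx = identify_maternal_components(sep, mqrs, clean.fs, cfg)
    corr_m = [abs(np.corrcoef(c, truth.maternal_source)[0, 1])
              for c in sep.components]
    assert int(np.argmax(corr_m)) in idx
    # the fetal-dominant component is never labeled maternal
    corr_f = [abs(np.corrcoef(c, truth.fetal_source)[0, 1])
              for c in sep.components]
    assert int(np.argmax(corr_f)) not in idx


def test_identify_falls_back_to_best_match():
    """On pure noise no component crosses the 80% coincidence bar; exactly
    one (the best-matching) is still labeled."""
    rng = np.random.default_rng(4)
    x = rng.normal(size=(3, 30_000))
    sep = jade_separate(x)
    mqrs = BeatAnnotation(np.arange(200, 29_000, 400), beat_class="maternal",
                          fs=500.0)
    idx = identify_maternal_components(sep, mqrs, 500.0)
    assert len(idx) == 1


def test_subtract_removes_maternal_preserves_fetal(separated_aecg):
    cfg, clean, truth, mqrs, sep = separated_aecg
    idx = identify_maternal_components(sep, mqrs, clean.fs, cfg)
    residual, sep = subtract_mecg(clean, sep, idx)
    # reconstruction invariant
    np.testing.assert_allclose(sep.mecg_estimate + residual.data, clean.data,
                               rtol=0, atol=1e-8 * np.abs(clean.data).max())
    # maternal R amplitude drops to <= 20% of pre-subtraction
    mi = truth.maternal_r.indices
    for ch in range(clean.n_channels):
        before = np.mean(np.abs(clean.data[ch, mi]))
        after = np.mean(np.abs(residual.data[ch, mi]))
        assert after <= 0.2 * before
    # fetal content survives on the best channel
    corr_f = max(abs(np.corrcoef(residual.data[ch], truth.fetal_source)[0, 1])
                 for ch in range(residual.n_channels))
    assert corr_f >= 0.7


def test_subtract_maternal_only_input(default_config):
    """With fetal and noise amplitudes at zero the residual is empty."""
    rec, truth = synthesize_aecg(SyntheticConfig(
        duration_s=30, rng_seed=0, fetal_r_uv=0.0,
        allow_out_of_range_fetal=True, baseline_uv=0, powerline_uv=0,
        broadband_sd_uv=0, impulse_rate_per_s=0))
    mqrs, _ = detect_mqrs(rec, default_config)
    residual, sep = cancel_mecg(rec, mqrs, default_config)
    assert np.sqrt(np.mean(residual.data**2)) <= 0.05 * np.sqrt(
        np.mean(rec.data**2))


def test_subtract_all_components_leaves_nothing():
    s = two_nongaussian_sources(n=8000)
    x = np.array([[0.9, 0.4], [0.3, 0.8]]) @ s + np.array([[2.0], [-1.0]])
    rec = MultichannelRecording(fs=500.0, data=x)
    sep = jade_separate(x)
    residual, _ = subtract_mecg(rec, sep, list(range(len(sep.components))))
    np.testing.assert_allclose(residual.data, 0.0, atol=1e-8)


def test_residual_invariant_to_component_permutation(separated_aecg):
    cfg, clean, truth, mqrs, sep = separated_aecg
    idx = identify_maternal_components(sep, mqrs, clean.fs, cfg)
    res1, _ = subtract_mecg(clean, sep, idx)
    import copy
    perm = [2, 0, 1]
    signs = np.array([-1.0, 1.0, -1.0])
    sep2 = copy.deepcopy(sep)
    sep2.rotation = (signs[:, None] * sep.rotation)[perm]
    sep2.components = (signs[:, None] * sep.components)[perm]
    idx2 = [perm.index(i) for i in idx]
    res2, _ = subtract_mecg(clean, sep2, idx2)
    np.testing.assert_allclose(res2.data, res1.data, atol=1e-8)


def test_maternal_identification_accuracy_over_seeds():
    """Across seeds, the labeled set always contains the true maternal
    component (highest |corr| with the maternal source)."""
    cfg = PipelineConfig()
    hits = 0
    seeds = range(10)
    for seed in seeds:
        rec, truth = synthesize_aecg(SyntheticConfig(duration_s=40,
                                                     rng_seed=seed))
        clean = cancel_noise(rec, cfg)
        mqrs, _ = detect_mqrs(clean, cfg)
        sep = jade_separate(clean.data)
        idx = identify_maternal_components(sep, mqrs, clean.fs, cfg)
        corr = [abs(np.corrcoef(c, truth.maternal_source)[0, 1])
                for c in sep.components]
        hits += int(np.argmax(corr)) in idx
    assert hits == len(list(seeds))
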