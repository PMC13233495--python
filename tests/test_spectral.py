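import numpy as np
import pytest
from scipy import signal as sps

from eegfatigue import alpha_band_power, build_feature_tensor, detect_iaf, irasa_decompose
from eegfatigue.spectral import (DEFAULT_H_SET, FeatureTensor, _amp_spectrum,
                                 _hann_taps, _resample_rfft, _resampled_amp,
                                 _hann_windowed_amp)


RATE = 250.0


def _pink(shape, n, rng, exponent=1.3):
    freqs = np.fft.rfftfreq(n, d=1.0 / RATE)
    gain = np.ones_like(freqs)
    above = freqs >= 1.0
    gain[above] = freqs[above] ** (-exponent / 2.0)
    gain[0] = 0.0
    x = np.fft.irfft(np.fft.rfft(rng.standard_normal(shape + (n,))) * gain, n)
    return x / x.std(axis=-1, keepdims=True)


def test_amp_spectrum_matches_scipy_periodogram_oracle():
    rng = np.random.default_rng(0)
    for n in (500, 501):
        x = rng.standard_normal((3, n))
        f_ref, p_ref = sps.periodogram(x, fs=RATE, window="hann", detrend=False)
        f, a = _amp_spectrum(x, RATE)
        assert np.allclose(f, f_ref)
        assert np.allclose(a, np.sqrt(p_ref), atol=1e-12)


def test_spectral_domain_resampling_matches_time_domain_oracle():
    rng = np.random.default_rng(1)
    for n in (500, 497):
        x = rng.standard_normal((2, n))
        X = np.fft.rfft(x, axis=-1)
        A = np.abs(_hann_taps(X, n))
        for num in (454, 455, 550, 551, 277, n):
            ref_f, ref_a = _amp_spectrum(sps.resample(x, num, axis=-1), RATE)
            for f, a in (_hann_windowed_amp(_resample_rfft(X, n, num), num, RATE),
                         _resampled_amp(A, X, n, num, RATE)):
                assert np.allclose(f, ref_f)
                assert np.max(np.abs(a - ref_a)) <= 1e-10 * max(ref_a.max(), 1.0)


def test_additivity_is_exact_in_both_spectrum_modes():
    rng = np.random.default_rng(2)
    x = _pink((4,), 500, rng)
    for mode in ("amplitude", "power"):
        res = irasa_decompose(x, RATE, spectrum=mode)
        assert np.allclose(res.fractal + res.harmonic, res.raw, atol=1e-12)
    amp = irasa_decompose(x, RATE, spectrum="amplitude")
    pow_ = irasa_decompose(x, RATE, spectrum="power")
    assert np.allclose(amp.raw**2, pow_.raw, atol=1e-12)
    assert np.allclose(amp.fractal**2, pow_.fractal, atol=1e-12)


def test_fft_and_polyphase_resampling_agree_on_the_fractal():
    rng = np.random.default_rng(3)
    x = _pink((8,), 500, rng)
    a = irasa_decompose(x, RATE, resample_method="fft")
    b = irasa_decompose(x, RATE, resample_method="poly")
    band = (a.freqs >= 5.0) & (a.freqs <= 20.0)
    rel = np.abs(a.fractal[:, band] - b.fractal[:, band]) / b.fractal[:, band]
    assert np.median(rel) < 0.05


def test_oscillation_lands_in_harmonic_not_fractal():
    rng = np.random.default_rng(4)
    n = 500
    t = np.arange(n) / RATE
    x = _pink((16,), n, rng) * 3.0
    x += 4.0 * np.sin(2 * np.pi * 10.0 * t + rng.uniform(0, 2 * np.pi, (16, 1)))
    res = irasa_decompose(x, RATE)
    band = (res.freqs >= 5.0) & (res.freqs <= 20.0)
    harm = res.harmonic.mean(axis=0)[band]
    assert res.freqs[band][np.argmax(harm)] == pytest.approx(10.0, abs=0.5)
    # most of the 10 Hz raw peak is attributed to the harmonic part
    at10 = np.argmin(np.abs(res.freqs - 10.0))
    assert res.harmonic.mean(axis=0)[at10] > res.fractal.mean(axis=0)[at10]


def test_irasa_input_validation():
    x = np.zeros((2, 100))
    with pytest.raises(ValueError):
        irasa_decompose(x, RATE)  # < 1 s
    with pytest.raises(ValueError):
        irasa_decompose(np.zeros((2, 500)), RATE, h_set=[0.9, 1.5])
    with pytest.raises(ValueError):
        irasa_decompose(np.zeros((2, 500)), RATE, spectrum="log")
    with pytest.raises(ValueError):
        irasa_decompose(np.zeros((2, 500)), RATE, resample_method="spline")


def test_default_h_set_is_the_irasa_convention():
    assert DEFAULT_H_SET[0] == 1.1 and DEFAULT_H_SET[-1] == 1.9
    assert np.allclose(np.diff(DEFAULT_H_SET), 0.05)


def test_feature_tensor_shape_band_and_chunking(small_epochs):
    t1 = build_feature_tensor(small_epochs, chunk=16)
    t2 = build_feature_tensor(small_epochs, chunk=10_000)
    assert np.allclose(t1.values, t2.values)
    assert t1.values.shape == (small_epochs.n_epochs, t1.freqs.size,
                               len(small_epochs.channel_labels))
    assert t1.freqs[0] >= 5.0 and t1.freqs[-1] <= 20.0
    assert t1.component == "harmonic"
    raw = build_feature_tensor(small_epochs, component="raw", chunk=10_000)
    frac = build_feature_tensor(small_epochs, component="fractal", chunk=10_000)
    assert np.allclose(frac.values + t2.values, raw.values, atol=1e-12)
    with pytest.raises(ValueError):
        build_feature_tensor(small_epochs, component="phase")


def test_feature_tensor_selection_keeps_axes(small_tensor):
    sub = small_tensor.select_epochs(np.arange(5))
    assert sub.values.shape[0] == 5
    chans = small_tensor.channel_labels[:3]
    subc = small_tensor.select_channels(chans)
    assert subc.channel_labels == tuple(chans)
    assert np.array_equal(subc.values, small_tensor.values[:, :, :3])


def _bump_tensor(center, freqs):
    vals = np.exp(-((freqs - center) / 0.8) ** 2)[None, :, None] * np.ones((4, 1, 2))
    return FeatureTensor(vals, freqs, ("O1", "O2"), np.array(["pre-EC"] * 4))


def test_iaf_detection_finds_the_planted_peak():
    freqs = np.arange(5.0, 20.5, 0.5)
    assert detect_iaf(_bump_tensor(9.5, freqs)) == pytest.approx(9.5)
    # flat spectrum: midpoint with a warning
    flat = FeatureTensor(np.ones((3, freqs.size, 2)), freqs, ("O1", "O2"),
                         np.array(["pre-EC"] * 3))
    with pytest.warns(UserWarning):
        assert detect_iaf(flat, band=(7.0, 13.0)) == pytest.approx(10.0)
    with pytest.raises(ValueError):
        detect_iaf(_bump_tensor(9.5, freqs), band=(1.0, 13.0))


def test_session_iaf_is_near_the_planted_alpha(small_tensor):
    iaf = detect_iaf(small_tensor)
    assert abs(iaf - 10.0) <= 1.0


def test_alpha_band_power_matches_hand_arithmetic():
    freqs = np.arange(5.0, 20.5, 0.5)
    vals = np.zeros((1, freqs.size, 1))
    vals[0, :, 0] = np.arange(freqs.size, dtype=float)
    tensor = FeatureTensor(vals, freqs, ("O1",), np.array(["pre-EC"]), "harmonic")
    # window 9.5..10.5 covers bins 9.5, 10.0, 10.5 -> indices 9, 10, 11
    expected = (9.0**2 + 10.0**2 + 11.0**2) / 3.0
    assert alpha_band_power(tensor, 10.0, halfwidth=0.5)[0, 0] == pytest.approx(expected)
    with pytest.raises(ValueError):
        alpha_band_power(tensor, 20.0, halfwidth=1.0)
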