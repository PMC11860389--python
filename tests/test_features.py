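"""Feature extractors: closed forms, independent oracles, invariants."""

import numpy as np
import pytest
from scipy.fft import rfft

from speechdx.features import (
    CRITICAL_BANDS,
    FeatureConfig,
    FeatureError,
    FeatureMatrix,
    assemble_features,
    compute_delta,
    compute_f0_hr,
    compute_mfcc,
    compute_teo_cb_env,
    teager_energy,
)
from speechdx.signal_io import AudioSignal, n_frames_for
from speechdx.synthetic import make_audio_fixtures


# ---------------------------------------------------------------------------
# independent MFCC oracle (explicit loops, own filterbank and DCT matrix)

def _oracle_mfcc(x, rate, n_mfcc=13, n_mel=26, frame=480, hop=160):
    out = []
    count = (len(x) - frame) // hop + 1
    # mel filterbank built independently
    def mel(f):
        return 2595.0 * np.log10(1.0 + f / 700.0)

    def imel(m):
        return 700.0 * (10.0 ** (m / 2595.0) - 1.0)

    edges = imel(np.linspace(mel(0.0), mel(8000.0), n_mel + 2))
    freqs = np.arange(frame // 2 + 1) * rate / frame
    fbank = np.zeros((n_mel, freqs.size))
    for m in range(n_mel):
        lo, c, hi = edges[m], edges[m + 1], edges[m + 2]
        for b, f in enumerate(freqs):
            if lo <= f <= c:
                fbank[m, b] = (f - lo) / (c - lo)
            elif c < f <= hi:
                fbank[m, b] = (hi - f) / (hi - c)
    # explicit orthonormal DCT-II matrix
    Dm = np.zeros((n_mel, n_mel))
    for k in range(n_mel):
        for n in range(n_mel):
            Dm[k, n] = np.cos(np.pi * k * (2 * n + 1) / (2 * n_mel))
    Dm *= np.sqrt(2.0 / n_mel)
    Dm[0] *= np.sqrt(0.5)
    win = np.hamming(frame)
    for i in range(count):
        seg = x[i * hop : i * hop + frame] * win
        power = np.abs(np.fft.rfft(seg)) ** 2
        logE = np.log(np.maximum(fbank @ power, 1e-10))
        out.append((Dm @ logE)[1 : n_mfcc + 1])
    return np.array(out)


class TestMfcc:
    def test_matches_independent_oracle_on_tones(self):
        for freq in (440.0, 3500.0):
            sig = make_audio_fixtures("tone", {"freq_hz": freq,
                                               "duration_s": 0.5})
            ours = compute_mfcc(sig, FeatureConfig()).values
            ref = _oracle_mfcc(sig.samples, sig.rate)
            assert np.max(np.abs(ours - ref)) < 1e-3

    def test_distinct_tones_have_distinct_cepstra(self):
        a = compute_mfcc(make_audio_fixtures("tone", {"freq_hz": 440.0}),
                         FeatureConfig()).values.mean(axis=0)
        b = compute_mfcc(make_audio_fixtures("tone", {"freq_hz": 3500.0}),
                         FeatureConfig()).values.mean(axis=0)
        assert np.linalg.norm(a - b) > 0

    def test_shape_follows_framing_closed_form(self):
        sig = make_audio_fixtures("noise", {"duration_s": 0.73}, seed=4)
        fm = compute_mfcc(sig, FeatureConfig())
        assert fm.values.shape == (
            n_frames_for(sig.samples.size, 480, 160), 13)

    def test_all_zero_signal_constant_rows(self):
        sig = AudioSignal(np.zeros(4800), 16000)
        fm = compute_mfcc(sig, FeatureConfig())
        assert np.allclose(fm.values, fm.values[0])

    def test_determinism(self):
        sig = make_audio_fixtures("noise", {}, seed=9)
        a = compute_mfcc(sig, FeatureConfig()).values
        b = compute_mfcc(sig, FeatureConfig()).values
        assert np.array_equal(a, b)


class TestDelta:
    def test_constant_matrix_zero_velocity(self):
        fm = FeatureMatrix(np.full((20, 3), 2.5), ["a", "b", "c"],
                           np.arange(20.0))
        assert np.allclose(compute_delta(fm, "velocity").values, 0.0)

    def test_linear_ramp_velocity_and_acceleration(self):
        vals = np.outer(np.arange(30.0) * 0.5, np.ones(2))
        fm = FeatureMatrix(vals, ["a", "b"], np.arange(30.0))
        vel = compute_delta(fm, "velocity").values
        assert np.allclose(vel[3:-3], 0.5, atol=1e-12)
        acc = compute_delta(fm, "acceleration").values
        assert np.allclose(acc[5:-5], 0.0, atol=1e-12)

    def test_too_short_errors(self):
        fm = FeatureMatrix(np.ones((5, 2)), ["a", "b"], np.arange(5.0))
        with pytest.raises(FeatureError):
            compute_delta(fm, "velocity", window=2)


class TestTeo:
    def test_sinusoid_closed_form(self):
        # Ψ[A sin(Ωn)] = A² sin²(Ω), a constant
        A, omega = 0.7, 2 * np.pi * 700 / 16000
        x = A * np.sin(omega * np.arange(2000))
        psi = teager_energy(x)[1:-1]
        assert np.allclose(psi, A**2 * np.sin(omega) ** 2, rtol=1e-9)

    def test_band_selectivity_700hz(self):
        sig = make_audio_fixtures("tone", {"freq_hz": 700.0})
        m = compute_teo_cb_env(sig).values.mean(axis=0)
        lo, _c, hi = CRITICAL_BANDS[2]
        assert lo <= 700.0 <= hi  # band 3 covers the tone
        assert m[2] > m[0] and m[2] > m[7] and m[2] > m[15]

    def test_zero_signal_all_zeros(self):
        sig = AudioSignal(np.zeros(4800), 16000)
        assert np.allclose(compute_teo_cb_env(sig).values, 0.0)

    def test_shape_and_band_count(self):
        sig = make_audio_fixtures("noise", {"duration_s": 0.5}, seed=1)
        fm = compute_teo_cb_env(sig)
        assert fm.dim == 16
        assert fm.n_frames == n_frames_for(sig.samples.size, 480, 160)

    def test_amplitude_invariance_of_normalized_areas(self):
        sig = make_audio_fixtures("harmonic", {"f0_hz": 180.0}, seed=2)
        one = compute_teo_cb_env(sig).values
        double = compute_teo_cb_env(
            AudioSignal(2.0 * sig.samples, sig.rate)).values
        assert np.allclose(one, double, atol=1e-8)

    def test_critical_band_table_structure(self):
        assert len(CRITICAL_BANDS) == 16
        assert CRITICAL_BANDS[0][0] == 100 and CRITICAL_BANDS[-1][2] == 7400
        for (lo, c, hi), (lo2, c2, hi2) in zip(CRITICAL_BANDS,
                                               CRITICAL_BANDS[1:]):
            assert lo < c < hi and hi <= lo2


class TestF0Hr:
    def test_200hz_tone(self):
        sig = make_audio_fixtures("tone", {"freq_hz": 200.0})
        fm = compute_f0_hr(sig)
        interior = fm.values[2:-2]
        assert np.all(np.abs(interior[:, 0] - 200.0) <= 2.0)
        assert np.all(interior[:, 1] > 0.95)

    def test_zero_frames(self):
        sig = AudioSignal(np.zeros(4800), 16000)
        assert np.allclose(compute_f0_hr(sig).values, 0.0)

    def test_white_noise_low_hr_matches_bruteforce_oracle(self):
        sig = make_audio_fixtures("noise", {"duration_s": 0.5}, seed=12)
        fm = compute_f0_hr(sig)
        assert np.median(fm.values[:, 1]) < 0.5
        # brute-force normalized autocorrelation on one frame
        x = sig.samples[:480] - sig.samples[:480].mean()
        best = -1.0
        for lag in range(32, 321):
            a, b = x[:-lag], x[lag:]
            r = (a @ b) / np.sqrt((a @ a) * (b @ b))
            best = max(best, r)
        assert fm.values[0, 1] == pytest.approx(max(best, 0.0), abs=1e-12)

    def test_amplitude_invariance(self):
        sig = make_audio_fixtures("harmonic", {"f0_hz": 150.0})
        one = compute_f0_hr(sig).values
        double = compute_f0_hr(
            AudioSignal(2.0 * sig.samples, sig.rate)).values
        assert np.allclose(one, double, atol=1e-9)

    def test_bad_range_errors(self):
        sig = make_audio_fixtures("tone", {"freq_hz": 200.0})
        with pytest.raises(FeatureError):
            compute_f0_hr(sig, FeatureConfig(f0_range=(50.0, 9000.0)))


class TestAssemble:
    def test_reading_preset_dim_39(self):
        sig = make_audio_fixtures("harmonic", {"f0_hz": 160.0})
        fm = assemble_features(sig, FeatureConfig.reading())
        assert fm.dim == 39
        assert len(fm.dim_names) == 39

    def test_interview_preset_dim_44(self):
        sig = make_audio_fixtures("harmonic", {"f0_hz": 160.0})
        fm = assemble_features(sig, FeatureConfig.interview())
        assert fm.dim == 44

    def test_families_frame_aligned(self):
        sig = make_audio_fixtures("noise", {"duration_s": 0.61}, seed=3)
        fm = assemble_features(sig, FeatureConfig.interview())
        assert fm.n_frames == n_frames_for(sig.samples.size, 480, 160)

    def test_all_off_errors(self):
        sig = make_audio_fixtures("tone", {})
        cfg = FeatureConfig(use_mfcc=False, use_teo=False, use_f0_hr=False)
        with pytest.raises(FeatureError):
            assemble_features(sig, cfg)


def test_feature_matrix_csv_and_npz_roundtrip(tmp_path):
    fm = FeatureMatrix(np.random.default_rng(0).normal(size=(7, 3)),
                       ["x", "y", "z"], np.arange(7) * 0.01,
                       source_id="r1", subject_id="s1", label="Healthy")
    fm.to_csv(tmp_path / "f.csv")
    back = FeatureMatrix.from_csv(tmp_path / "f.csv", source_id="r1",
                                  subject_id="s1", label="Healthy")
    assert np.allclose(back.values, fm.values)
    fm.to_npz(tmp_path / "f.npz")
    back2 = FeatureMatrix.from_npz(tmp_path / "f.npz")
    assert np.array_equal(back2.values, fm.values)
    assert back2.label == "Healthy"
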