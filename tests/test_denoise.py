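"""IMF screening, wavelet thresholding, the joint pipeline, and the four
denoising quality metrics."""
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eegclust import (
    IMFSet,
    SignalSegment,
    WaveletSpec,
    denoise_report,
    imf_correlations,
    joint_denoise,
    partial_reconstruct,
    select_imfs,
    wavelet_threshold_denoise,
)
from eegclust.synth import add_noise
from .conftest import IMF_CORRELATIONS


def _imfset(*rows, residue=None):
    rows = [np.asarray(r, dtype=float) for r in rows]
    n = rows[0].size
    return IMFSet(imfs=np.vstack(rows),
                  residue=residue if residue is not None else np.zeros(n),
                  source_length=n)


@pytest.fixture(scope="module")
def sine_segment():
    x = np.sin(2 * np.pi * 10 * np.arange(1024) / 200)
    return SignalSegment(x, fs=200, id="sine10")


class TestIMFCorrelations:
    def test_signal_itself_and_sign_flip(self, sine_segment):
        x = sine_segment.samples
        s = _imfset(x, -x)
        rho = imf_correlations(s, sine_segment)
        assert rho[0] == pytest.approx(1.0)
        assert rho[1] == pytest.approx(-1.0)

    def test_orthogonal_pair_is_uncorrelated(self):
        t = np.arange(1000) / 100  # 10 full periods of a 1 Hz pair
        seg = SignalSegment(np.sin(2 * np.pi * t), fs=100, id="sin")
        s = _imfset(np.cos(2 * np.pi * t))
        assert abs(imf_correlations(s, seg)[0]) <= 1e-10

    def test_affine_scaling_invariance(self, sine_segment):
        x = sine_segment.samples
        rho1 = imf_correlations(_imfset(0.1 * x + 3), sine_segment)
        rho2 = imf_correlations(_imfset(5.0 * x - 7), sine_segment)
        assert rho1[0] == pytest.approx(rho2[0], abs=1e-12)

    def test_zero_variance_imf_warns_and_scores_zero(self, sine_segment):
        s = _imfset(np.ones(1024))
        with pytest.warns(UserWarning):
            rho = imf_correlations(s, sine_segment)
        assert rho[0] == 0.0


class TestScreening:
    def test_published_correlation_row_selects_middle_band(self):
        assert select_imfs(np.array(IMF_CORRELATIONS), 0.3) == [3, 4, 5, 6, 7]

    def test_zero_threshold_keeps_everything(self):
        assert select_imfs(np.array(IMF_CORRELATIONS), 0.0) == list(range(1, 11))

    def test_empty_selection_warns(self):
        with pytest.warns(UserWarning):
            out = select_imfs(np.zeros(4), 0.3)
        assert out == []

    def test_threshold_out_of_range(self):
        with pytest.raises(ValueError):
            select_imfs(np.zeros(3), 1.5)


class TestPartialReconstruct:
    def test_full_selection_recovers_signal(self, sine_segment):
        from eegclust import ceemdan

        s = ceemdan(sine_segment, ensemble_size=5, noise_ratio=0.2, seed=0)
        rec = partial_reconstruct(s, list(range(1, s.n_imfs + 1)), True)
        rel = np.linalg.norm(rec - sine_segment.samples) / np.linalg.norm(
            sine_segment.samples
        )
        assert rel <= 1e-8
        assert rec.size == len(sine_segment)

    def test_empty_selection_returns_residue(self):
        s = _imfset(np.ones(128), residue=np.full(128, 2.0))
        assert np.array_equal(partial_reconstruct(s, [], True), np.full(128, 2.0))
        assert np.array_equal(partial_reconstruct(s, [], False), np.zeros(128))

    def test_out_of_range_index_rejected(self):
        s = _imfset(np.ones(128))
        with pytest.raises(IndexError):
            partial_reconstruct(s, [2], True)


class TestWaveletDenoise:
    def test_zero_threshold_scale_is_identity(self, sine_segment):
        spec = WaveletSpec(threshold_scale=0.0)
        out = wavelet_threshold_denoise(sine_segment.samples, spec)
        rel = np.linalg.norm(out - sine_segment.samples) / np.linalg.norm(
            sine_segment.samples
        )
        assert rel <= 1e-6

    def test_constant_signal_unchanged(self):
        x = np.full(256, 4.2)
        assert np.allclose(wavelet_threshold_denoise(x), x, atol=1e-9)

    def test_noisy_tone_gains_at_least_three_db(self, sine_segment):
        noisy = add_noise(sine_segment.samples, 5.0, seed=7)
        out = wavelet_threshold_denoise(noisy)
        assert denoise_report(sine_segment.samples, out).snr_db >= 8.0

    def test_unknown_wavelet_rejected(self):
        with pytest.raises(ValueError):
            WaveletSpec(name="nosuchwavelet")


class TestJointDenoise:
    def test_clean_input_nearly_preserved(self, sine_segment):
        out = joint_denoise(sine_segment, ensemble_size=50, seed=0)
        assert denoise_report(sine_segment.samples, out).ncc >= 0.99

    def test_output_length_and_determinism(self, sine_segment):
        a = joint_denoise(sine_segment, ensemble_size=5, seed=1)
        b = joint_denoise(sine_segment, ensemble_size=5, seed=1)
        assert a.size == len(sine_segment)
        assert np.array_equal(a, b)


class TestDenoiseReport:
    def test_hand_computed_four_point_example(self):
        rep = denoise_report(np.ones(4), np.array([1.0, 1, 1, 0]))
        assert rep.snr_db == pytest.approx(6.0206, abs=1e-3)
        assert rep.rmse == pytest.approx(0.5, abs=1e-12)
        assert rep.ncc == pytest.approx(0.8660, abs=1e-3)
        assert rep.psnr_db == pytest.approx(6.0206, abs=1e-3)

    def test_identical_signals_hit_sentinels(self):
        x = np.sin(np.arange(64.0))
        rep = denoise_report(x, x.copy())
        assert rep.rmse == 0.0
        assert rep.ncc == pytest.approx(1.0)
        assert np.isinf(rep.snr_db) and np.isinf(rep.psnr_db)

    def test_sign_flip_gives_ncc_minus_one(self):
        x = np.sin(np.arange(64.0)) + 0.1
        assert denoise_report(x, -x).ncc == pytest.approx(-1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            denoise_report(np.ones(4), np.ones(5))

    def test_snr_decreases_along_noise_ladder(self):
        x = np.sin(2 * np.pi * 5 * np.arange(512) / 200)
        snrs = [
            denoise_report(x, add_noise(x, level, seed=11)).snr_db
            for level in (20.0, 10.0, 0.0)
        ]
        assert snrs[0] > snrs[1] > snrs[2]

    @settings(derandomize=True, max_examples=25)
    @given(st.lists(st.floats(-50, 50), min_size=4, max_size=32),
           st.lists(st.floats(-50, 50), min_size=4, max_size=32))
    def test_metric_bounds_and_zero_rmse_iff_identical(self, xs, ys):
        n = min(len(xs), len(ys))
        x = np.asarray(xs[:n])
        y = np.asarray(ys[:n])
        if np.sum(x**2) == 0:
            return
        rep = denoise_report(x, y)
        assert -1.0 - 1e-12 <= rep.ncc <= 1.0 + 1e-12
        assert rep.rmse >= 0.0
        assert (rep.rmse == 0.0) == bool(np.array_equal(x, y))
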