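"""Denoising, normalization and beat segmentation."""

import numpy as np
import pytest

from ldcnn import (
    MITBIH5,
    EcgRecord,
    PreprocessConfig,
    denoise_wavelet,
    segment_beats,
    zscore_normalize,
)
from ldcnn.containers import BeatAnnotation
from ldcnn.errors import (
    DegenerateSignalError,
    EmptyOutputError,
    ParameterError,
)

NO_THRESHOLD = PreprocessConfig(threshold_rule="none")


class TestDenoise:
    def test_zero_signal_stays_zero(self):
        out = denoise_wavelet(np.zeros(512))
        assert out.shape == (512,)
        np.testing.assert_allclose(out, 0.0)

    def test_zero_threshold_round_trips(self, rng):
        x = rng.normal(size=777)  # odd length on purpose
        out = denoise_wavelet(x, NO_THRESHOLD)
        np.testing.assert_allclose(out, x, atol=1e-6)

    def test_reduces_rmse_against_clean_component(self, rng):
        t = np.arange(4096) / 360.0
        clean = np.sin(2 * np.pi * 1.2 * t)
        noisy = clean + rng.normal(0.0, 0.5, size=clean.size)
        den = denoise_wavelet(noisy)
        rmse_in = np.sqrt(np.mean((noisy - clean) ** 2))
        rmse_out = np.sqrt(np.mean((den - clean) ** 2))
        assert rmse_out < rmse_in

    def test_energy_never_increases(self, rng):
        x = rng.normal(size=1024)
        out = denoise_wavelet(x)
        assert np.sum(out**2) <= np.sum(x**2) + 1e-9

    def test_output_length_matches_input(self, rng):
        for n in (100, 255, 256, 1001):
            assert denoise_wavelet(rng.normal(size=n)).size == n

    def test_too_short_signal_rejected(self):
        with pytest.raises(ParameterError, match="too short"):
            denoise_wavelet(np.ones(8), PreprocessConfig(decomposition_level=5))


class TestZscore:
    def test_hand_computed_example(self):
        out = zscore_normalize(np.array([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(out, [-1.224744871, 0.0, 1.224744871], atol=1e-9)

    def test_mean_zero_sd_one(self, rng):
        out = zscore_normalize(rng.normal(3.0, 7.0, size=500))
        assert abs(out.mean()) < 1e-9
        assert abs(out.std() - 1.0) < 1e-9

    def test_constant_signal_rejected(self):
        with pytest.raises(DegenerateSignalError):
            zscore_normalize(np.array([5.0, 5.0, 5.0]))


class TestSegmentation:
    @staticmethod
    def _record(n, ann, fs=360.0):
        rng = np.random.default_rng(0)
        return EcgRecord(signal=rng.normal(size=n), sampling_rate=fs,
                         record_id="seg", annotations=ann)

    def test_window_index_arithmetic(self):
        record = self._record(1000, [BeatAnnotation(500, "N")])
        cfg = PreprocessConfig(denoise=False, normalize=False)
        data = segment_beats(record, MITBIH5, cfg)
        assert data.windows.shape == (1, 360)
        np.testing.assert_array_equal(data.windows[0], record.signal[320:680])
        assert data.provenance == [("seg", 500)]

    def test_boundary_beats_dropped_and_counted(self):
        record = self._record(
            1000, [BeatAnnotation(10, "N"), BeatAnnotation(500, "N"), BeatAnnotation(900, "V")]
        )
        cfg = PreprocessConfig(denoise=False, normalize=False)
        data = segment_beats(record, MITBIH5, cfg)
        assert len(data) == 1
        assert data.meta["boundary_dropped"] == 2

    def test_excluded_and_boundary_accounting(self, rng):
        """100 annotations: 4 near boundaries, 6 excluded codes → 90 windows."""
        anns = []
        pos = iter(range(400, 40_000, 395))
        for k in range(100):
            if k < 2:
                sym, where = "N", 50 + k  # pre-window boundary
            elif k < 4:
                sym, where = "N", 39_950 + k  # post-window boundary
            elif k < 10:
                sym, where = "/", next(pos)  # paced: excluded by the scheme
            else:
                sym, where = "NLRAV"[k % 5], next(pos)
            anns.append((where, sym))
        anns.sort()
        record = self._record(40_000, [BeatAnnotation(i, s) for i, s in anns])
        data = segment_beats(record, MITBIH5, PreprocessConfig(denoise=False, normalize=False))
        assert len(data) == 90
        assert data.meta == {"excluded": 6, "boundary_dropped": 4, "segmented": 90}

    def test_windows_are_verbatim_slices_and_labels_consistent(self, clean_record):
        cfg = PreprocessConfig(denoise=False, normalize=True)
        data = segment_beats(clean_record, MITBIH5, cfg)
        sig = zscore_normalize(clean_record.signal)
        from ldcnn import map_symbol
        from ldcnn.containers import EXCLUDE

        surviving = []
        for ann, (rid, idx) in zip(
            [a for a in clean_record.annotations
             if map_symbol(a.symbol, MITBIH5) is not EXCLUDE
             and 180 <= a.sample_index <= sig.size - 180],
            data.provenance,
        ):
            assert ann.sample_index == idx
            surviving.append(ann.symbol)
        np.testing.assert_array_equal(
            data.windows,
            np.stack([sig[i - 180 : i + 180] for _, i in data.provenance]),
        )
        assert sorted(surviving) == sorted(MITBIH5.classes[l] for l in data.labels)

    def test_zero_surviving_beats_is_error(self):
        record = self._record(1000, [BeatAnnotation(5, "N")])
        with pytest.raises(EmptyOutputError):
            segment_beats(record, MITBIH5, PreprocessConfig(denoise=False, normalize=False))

    def test_stage_idempotence_with_zero_threshold(self, rng):
        """On an already-normalized signal the (threshold-0) pipeline stages
        are idempotent within tolerance."""
        x = zscore_normalize(rng.normal(size=2048))
        again = zscore_normalize(denoise_wavelet(x, NO_THRESHOLD))
        np.testing.assert_allclose(again, x, atol=1e-6)


def test_config_invariants():
    with pytest.raises(ParameterError):
        PreprocessConfig(pre_peak=100, post_peak=100, window_length=360)
    with pytest.raises(ParameterError):
        PreprocessConfig(window_length=1, pre_peak=1, post_peak=0)
    with pytest.raises(ParameterError):
        PreprocessConfig(threshold_rule="bogus")
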