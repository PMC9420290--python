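import numpy as np
import pytest

from afdetect import AmmParams, IegmRecord, SynthConfig, amm_detect, generate
from afdetect.evaluation import match_detections
from afdetect.morphology import (
    ExtractedActivation,
    StructuringElement,
    extract_activations,
    grey_dilate,
    grey_erode,
    init_structuring_element,
    mm_filter,
    update_se,
)


def brute_erode(x, s):
    """Textbook grayscale erosion, truncated support at the edges.

    Origin at the centre sample; for even-length structures the centre is
    the right-of-middle sample (index K//2), matching the implementation.
    """
    K, c = len(s), len(s) // 2
    n = len(x)
    return np.array(
        [
            min(x[i + j - c] - s[j] for j in range(K) if 0 <= i + j - c < n)
            for i in range(n)
        ]
    )


def brute_dilate(x, s):
    K, c = len(s), len(s) // 2
    n = len(x)
    return np.array(
        [
            max(x[i - j + c] + s[j] for j in range(K) if 0 <= i - j + c < n)
            for i in range(n)
        ]
    )


def make_se(duration=20.0, span=2.0, fs=1000.0):
    d = duration
    return StructuringElement(
        np.array([0.0, 0.25 * d, 0.5 * d, 0.75 * d, d]),
        np.array([0.0, -0.25 * span, span, -0.25 * span, 0.0]),
        fs=fs,
    )


class TestStructuringElement:
    def test_profile_interpolates_fiducials(self):
        se = make_se(duration=20.0, span=2.0, fs=1000.0)
        prof = se.profile
        assert prof.size == 21
        assert prof[0] == 0.0 and prof[-1] == 0.0
        assert prof[10] == pytest.approx(2.0)
        assert prof[5] == pytest.approx(-0.5)

    def test_init_span_from_first_500ms(self, rng):
        x = np.concatenate([rng.uniform(-1.0, 1.0, 501), np.zeros(500)])
        x[10], x[20] = 1.0, -1.0  # pin the extremes
        rec = IegmRecord("r", x, fs=1000.0)
        se = init_structuring_element(rec)
        assert se.fiducial_amplitudes[2] == pytest.approx(2.0)  # peak = span
        assert se.duration_ms == 20.0

    def test_flat_head_rejected(self):
        rec = IegmRecord("r", np.ones(1000), fs=1000.0)
        with pytest.raises(ValueError, match="flat initialization"):
            init_structuring_element(rec)

    def test_short_record_rejected(self):
        rec = IegmRecord("r", np.random.default_rng(0).normal(size=300), fs=1000.0)
        with pytest.raises(ValueError, match="initialisation span"):
            init_structuring_element(rec)


class TestMmFilter:
    def test_matches_brute_force(self, rng):
        se = make_se()
        prof = se.profile
        for _ in range(20):
            x = rng.standard_normal(200)
            np.testing.assert_allclose(grey_erode(x, prof), brute_erode(x, prof))
            np.testing.assert_allclose(grey_dilate(x, prof), brute_dilate(x, prof))

    def test_opening_below_closing_above(self, rng):
        """opening(x) <= x <= closing(x) pointwise, any window and SE."""
        for _ in range(50):
            x = rng.standard_normal(rng.integers(40, 200))
            span = rng.uniform(0.1, 3.0)
            se = make_se(duration=rng.uniform(10, 30), span=span)
            prof = se.profile
            opening = grey_dilate(grey_erode(x, prof), prof)
            closing = grey_erode(grey_dilate(x, prof), prof)
            assert np.all(opening <= x + 1e-9)
            assert np.all(closing >= x - 1e-9)

    def test_flat_signal_null(self):
        se = make_se(span=2.0)
        x = np.full(200, 3.3)
        x_mm = mm_filter(x, se)
        assert np.max(np.abs(x_mm)) <= 1e-3 * 2.0

    def test_spike_produces_dominant_lobe(self):
        se = make_se(span=1.0)
        x = np.zeros(200)
        x[100] = 5.0
        x_mm = mm_filter(x, se)
        assert np.argmax(np.abs(x_mm)) == 100
        assert np.abs(x_mm[100]) > 1.0

    def test_se_longer_than_window_rejected(self):
        se = make_se(duration=50.0)
        with pytest.raises(ValueError, match="longer"):
            mm_filter(np.zeros(20), se)


class TestExtractActivations:
    def test_all_zero_feature_signal(self):
        acts = extract_activations(np.zeros(200), np.zeros(200), 0.0, 1000.0, 0.1)
        assert acts == []

    def test_single_lobe_fiducial_order(self):
        x_mm = np.zeros(200)
        x_mm[90:110] = np.hanning(20)
        x = np.sin(np.arange(200) / 5.0)
        acts = extract_activations(x_mm, x, 0.0, 1000.0, 0.2)
        assert len(acts) == 1
        a = acts[0]
        assert a.seg_start <= 99 <= a.seg_end
        assert np.all(np.diff(a.offsets_ms) >= 0)

    def test_refractory_suppression_between_lobes(self):
        x_mm = np.zeros(300)
        x_mm[100] = 1.0
        x_mm[140] = 0.8  # 40 ms later
        acts = extract_activations(x_mm, x_mm, 0.0, 1000.0, 0.5)
        assert len(acts) == 1 and acts[0].lat_ms == 100.0


class TestUpdateSe:
    def _extracted(self, offsets, amps):
        return ExtractedActivation(
            lat_ms=0.0,
            offsets_ms=np.asarray(offsets, float),
            amplitudes=np.asarray(amps, float),
            peak_mm=1.0,
        )

    def test_alpha_zero_is_identity(self):
        se = make_se()
        ex = self._extracted([0, 2, 4, 6, 8], [0, -1, 3, -1, 0])
        out = update_se(se, ex, alpha=0.0)
        np.testing.assert_array_equal(out.fiducial_offsets, se.fiducial_offsets)
        np.testing.assert_array_equal(out.fiducial_amplitudes, se.fiducial_amplitudes)

    def test_alpha_one_is_replacement(self):
        se = make_se()
        ex = self._extracted([0, 3, 6, 9, 12], [0.1, -1, 3, -1, 0.2])
        out = update_se(se, ex, alpha=1.0)
        np.testing.assert_allclose(out.fiducial_offsets, ex.offsets_ms)
        np.testing.assert_allclose(out.fiducial_amplitudes, ex.amplitudes)

    def test_half_blend_arithmetic(self):
        """current peak location 10 ms, extracted 14 ms, alpha 0.5 -> 12 ms."""
        se = make_se(duration=20.0)  # peak at 10 ms
        ex = self._extracted([0, 7, 14, 21, 28], [0, -0.5, 2, -0.5, 0])
        out = update_se(se, ex, alpha=0.5)
        assert out.fiducial_offsets[2] == pytest.approx(12.0)

    def test_degenerate_blend_keeps_current(self):
        se = make_se()
        ex = self._extracted([0, 0.1, 0.2, 0.3, 0.4], [0, 0, 0, 0, 0])
        out = update_se(se, ex, alpha=1.0)
        assert out is se

    def test_validity_preserved_over_many_updates(self, rng):
        se = make_se()
        for _ in range(200):
            offs = np.concatenate([[0.0], np.sort(rng.uniform(0.5, 40.0, 4))])
            ex = self._extracted(offs, rng.standard_normal(5))
            se = update_se(se, ex, alpha=0.5)
            assert np.all(np.diff(se.fiducial_offsets) > 0)
            assert np.all(np.isfinite(se.fiducial_amplitudes))


class TestAmmDetect:
    def test_clean_recovery(self, clean_biphasic_record):
        sr = clean_biphasic_record
        seq, _ = amm_detect(sr.record)
        m = match_detections(seq, sr.truth, tol=15.0)
        assert m.tp >= 0.94 * len(sr.truth)

    def test_flat_record_zero_detections(self):
        x = np.zeros(2000)
        x[:500] = np.sin(np.arange(500) / 10.0)  # non-flat init head only
        seq, _ = amm_detect(IegmRecord("f", x, 1000.0))
        assert all(t < 600 for t in seq.lats)

    def test_adapts_to_amplitude_step(self):
        cfg = SynthConfig(
            duration_s=10.0,
            mean_cl=200.0,
            noise_sd=0.0,
            morphology_mix={"biphasic": 1.0, "fractionated": 0.0, "double_peak": 0.0},
            seed=11,
        )
        sr = generate(cfg)
        x = sr.record.samples.copy()
        half = sr.record.index_at(5000.0)
        x[half:] *= 5.0
        seq, _ = amm_detect(IegmRecord(sr.record.record_id, x, 1000.0))
        late_truth = sr.truth.lats[sr.truth.lats > 5100]
        m = match_detections(
            seq.replace(lats=seq.lats[seq.lats > 5100]),
            sr.truth.replace(lats=late_truth),
            tol=15.0,
        )
        assert m.fn <= max(1, int(0.1 * late_truth.size))

    def test_refractory_invariant(self, clean_biphasic_record):
        seq, _ = amm_detect(clean_biphasic_record.record)
        assert np.min(np.diff(seq.lats)) >= 70.0

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            AmmParams(alpha=0.0)
        with pytest.raises(ValueError):
            AmmParams(se_duration=300.0)
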