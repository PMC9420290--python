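import numpy as np
import pytest

from afdetect import (
    ActivationSequence,
    IegmRecord,
    Source,
    WeightParams,
    correct_sequence,
    interval_stats,
    relen_detect,
)
from afdetect.correction import (
    RELEN_NONLINEAR,
    recover_missed,
    remove_false,
    weight_at,
)
from afdetect.core import REFRACTORY_MS
from afdetect.relen import EnhancedSignal
from afdetect.simulate import degraded_benchmark_config, make_corpus


def impulse_enhanced(lats, amps, th, duration=3000, fs=1000.0):
    """Synthetic enhanced signal with impulses of given amplitude at lats."""
    v = np.zeros(int(duration))
    for t, a in zip(lats, amps):
        v[int(round(t))] = a
    es = EnhancedSignal(values=v, th_p=th, fs=fs)
    rec = IegmRecord("synthetic", v, fs=fs)
    seq = ActivationSequence("synthetic", np.asarray(lats, float), Source.RAW_RELEN)
    return rec, es, seq


class TestWeightAt:
    @pytest.fixture
    def stats(self):
        seq = ActivationSequence(
            "r", np.cumsum([0, 180, 220, 200, 160, 240, 200]), Source.ANNOTATED_TRUTH
        )
        return interval_stats(seq)

    @pytest.mark.parametrize("shape", ["linear", "nonlinear"])
    def test_zero_below_refractory(self, stats, shape):
        wp = WeightParams(shape=shape, p70=0.4, p_mean=2.2)
        for k in [0.0, 50.0, 69.0, 69.999]:
            assert weight_at(k, wp, stats) == 0.0

    def test_linear_boundary_values(self, stats):
        wp = WeightParams(shape="linear", p70=0.4, p_mean=2.2)
        assert weight_at(70.0, wp, stats) == pytest.approx(0.4)
        assert weight_at(stats.mean_aa, wp, stats) == pytest.approx(2.2)

    def test_linear_is_affine_beyond_70(self, stats):
        wp = WeightParams(shape="linear", p70=0.0, p_mean=2.1)
        slope = (2.1 - 0.0) / (stats.mean_aa - 70.0)
        for k in [90.0, stats.mean_aa, stats.mean_aa + 123.0]:
            assert weight_at(k, wp, stats) == pytest.approx(slope * (k - 70.0))

    def test_nonlinear_continuous_at_mean(self, stats):
        wp = RELEN_NONLINEAR
        just_below = weight_at(stats.mean_aa - 1e-9, wp, stats)
        at = weight_at(stats.mean_aa, wp, stats)
        beyond = weight_at(stats.mean_aa + 500.0, wp, stats)
        assert at == pytest.approx(wp.p_mean)
        assert just_below == pytest.approx(wp.p_mean, rel=1e-6)
        assert beyond == wp.p_mean

    def test_nonlinear_one_widened_std_below_mean(self, stats):
        wp = RELEN_NONLINEAR
        k = stats.mean_aa - wp.enlarge * stats.sigma_aa
        assert weight_at(k, wp, stats) == pytest.approx(
            wp.p_mean * np.exp(-0.5), rel=1e-9
        )

    def test_literal_mode_amplitude(self, stats):
        wp = WeightParams(shape="nonlinear", p_mean=3.0, enlarge=1.25,
                          gaussian_mode="literal")
        expected = 1.25 * 3.0 / stats.sigma_aa
        assert weight_at(stats.mean_aa, wp, stats) == pytest.approx(expected)

    def test_gap_weight_symmetry(self, stats):
        """W(k) = w(k) * w(K-k) equals its own time reversal on any gap."""
        for wp in [RELEN_NONLINEAR, WeightParams(shape="linear", p70=0.0, p_mean=2.1)]:
            for K in [150.0, 240.0, 433.0]:
                k = np.linspace(0, K, 97)
                W = weight_at(k, wp, stats) * weight_at(K - k, wp, stats)
                np.testing.assert_allclose(W, W[::-1], atol=1e-12)


class TestRemoveFalse:
    def test_short_interval_artifact_removed_long_interval_kept(self):
        """An artifact 103 ms after an activation is dampened below the
        threshold and removed, while a neighbour 271 ms before it (interval
        above the mean) is kept."""
        lats = [100, 320, 540, 760, 980, 1083, 1354, 1574, 1794, 2014]
        # interval pattern: 220 x4, 103 (artifact), 271, then 220s
        th = 1.0
        amps = [5.0] * len(lats)
        amps[5] = 1.05  # the artifact barely crossed the threshold
        rec, es, seq = impulse_enhanced(lats, amps, th)
        st = interval_stats(seq)
        assert 200 < st.mean_aa < 240  # Fig-4-like regime
        out = remove_false(rec, seq, RELEN_NONLINEAR, detector="relen", es=es, stats=st)
        assert 1083.0 not in out.lats
        assert 980.0 in out.lats and 1354.0 in out.lats
        assert len(out) == len(seq) - 1

    def test_regular_strong_sequence_untouched(self):
        lats = list(np.arange(10) * 200.0 + 100.0)
        rec, es, seq = impulse_enhanced(lats, [5.0] * 10, th=1.0)
        out = remove_false(rec, seq, RELEN_NONLINEAR, detector="relen", es=es)
        np.testing.assert_array_equal(out.lats, seq.lats)

    def test_injected_artifacts_removed_without_collateral(
        self, clean_biphasic_record
    ):
        sr = clean_biphasic_record
        seq, es = relen_detect(sr.record)
        truth_set = set(np.round(seq.lats, 6))
        # inject artifact detections 85 ms after every 8th activation
        fakes = [t + 85.0 for t in seq.lats[2:-2:8]][:5]
        lats = np.sort(np.concatenate([seq.lats, fakes]))
        injected = ActivationSequence(seq.record_id, lats, Source.RAW_RELEN)
        out = remove_false(
            sr.record, injected, RELEN_NONLINEAR, detector="relen", es=es,
            stats=interval_stats(seq),
        )
        removed = set(np.round(lats, 6)) - set(np.round(out.lats, 6))
        assert len(removed & set(np.round(fakes, 6))) >= 4
        assert not (removed & truth_set)


class TestRecoverMissed:
    def test_long_gap_deflection_recovered(self):
        """A suprathreshold-after-weighting deflection in a 432 ms gap
        (mean interval ~231 ms) is inserted; a 185 ms gap is left alone."""
        lats = [100, 331, 562, 793, 1225, 1410, 1641, 1872, 2103, 2334]
        # gaps: 231 x4, 432, 185, then 231s
        th = 1.0
        amps = [5.0] * len(lats)
        rec, es, seq = impulse_enhanced(lats, amps, th)
        st = interval_stats(seq)
        # hidden deflection mid-gap, below threshold on its own
        v = es.values.copy()
        v[1009] = 0.5
        es = EnhancedSignal(values=v, th_p=th, fs=1000.0)
        out = recover_missed(rec, seq, RELEN_NONLINEAR, detector="relen", es=es, stats=st)
        assert len(out) == len(seq) + 1
        new = sorted(set(out.lats) - set(seq.lats))[0]
        assert new == pytest.approx(1009.0, abs=2.0)
        # nothing inserted into the 185 ms gap
        assert not np.any((out.lats > 1225) & (out.lats < 1410))

    def test_empty_quiet_gaps_unchanged(self):
        lats = list(np.arange(10) * 231.0 + 100.0)
        rec, es, seq = impulse_enhanced(lats, [5.0] * 10, th=1.0)
        out = recover_missed(rec, seq, RELEN_NONLINEAR, detector="relen", es=es)
        np.testing.assert_array_equal(out.lats, seq.lats)


class TestCorrectSequence:
    def test_perfect_sequence_is_fixed_point(self, clean_biphasic_record):
        sr = clean_biphasic_record
        seq, es = relen_detect(sr.record)
        out = correct_sequence(sr.record, seq, detector="relen", es=es)
        np.testing.assert_array_equal(out.lats, seq.lats)
        assert out.source == Source.CORRECTED

    def test_fewer_than_three_detections_returned_unchanged(self, noise_record):
        seq = ActivationSequence("noise", [100.0, 300.0], Source.RAW_RELEN)
        es = EnhancedSignal(np.zeros(2000), th_p=1.0, fs=1000.0)
        out = correct_sequence(noise_record, seq, detector="relen", es=es)
        np.testing.assert_array_equal(out.lats, seq.lats)

    def test_output_respects_refractory_and_no_reinsertion(self):
        cfg = degraded_benchmark_config()
        for seed in range(10):
            corpus = make_corpus(cfg, 2, seed=seed)
            for sr in corpus:
                seq, es = relen_detect(sr.record)
                out = correct_sequence(sr.record, seq, detector="relen", es=es)
                if len(out) > 1:
                    assert np.min(np.diff(out.lats)) >= REFRACTORY_MS
                removed = np.setdiff1d(seq.lats, out.lats)
                inserted = np.setdiff1d(out.lats, seq.lats)
                for t in inserted:
                    if removed.size:
                        assert np.min(np.abs(removed - t)) >= 0.5 * REFRACTORY_MS

    def test_missing_enhanced_signal_rejected(self, noise_record):
        seq = ActivationSequence("noise", [100.0, 300.0, 500.0], Source.RAW_RELEN)
        with pytest.raises(ValueError, match="enhanced"):
            remove_false(noise_record, seq, RELEN_NONLINEAR, detector="relen")
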