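"""Network architecture contracts: preprocessing, rates, receptive field,
gradient correctness, freeze contract, augmentation arithmetic."""

import numpy as np
import pytest

from somnoscore.net.model import (
    ArousalNet,
    ModelConfig,
    preprocess_flow,
    preprocess_ppg,
    small_config,
)
from somnoscore.net.ops import Adam, Conv1d, MaxPool, ResBlock, params_hash
from somnoscore.net.train import TrainConfig, stretch_targets, train_end2end
from somnoscore.waveio import Waveform


def rms(x):
    return float(np.sqrt(np.mean(np.square(x))))


class TestPreprocessing:
    def test_ppg_drift_attenuated(self):
        t = np.arange(0, 300, 0.01)
        w = Waveform("PPG", 100.0, np.sin(2 * np.pi * 0.05 * t))
        out = preprocess_ppg(w)
        assert rms(out.samples) < 0.1 * rms(w.samples)

    def test_ppg_passband_preserved(self):
        t = np.arange(0, 300, 0.01)
        w = Waveform("PPG", 100.0, np.sin(2 * np.pi * 1.0 * t))
        out = preprocess_ppg(w)
        assert abs(rms(out.samples) - rms(w.samples)) < 0.05 * rms(w.samples)

    def test_ppg_constant_becomes_zero(self):
        w = Waveform("PPG", 100.0, np.full(3000, 5.0))
        assert np.max(np.abs(preprocess_ppg(w).samples)) < 1e-6

    def test_ppg_resampled_to_100(self):
        w = Waveform("PPG", 64.0, np.random.default_rng(0).standard_normal(6400))
        out = preprocess_ppg(w)
        assert out.rate == 100.0 and out.samples.size == 10000

    def test_flow_breathing_band_preserved(self):
        t = np.arange(0, 600, 0.1)
        w = Waveform("Flow", 10.0, np.sin(2 * np.pi * 0.25 * t))
        out = preprocess_flow(w)
        assert abs(rms(out.samples) - rms(w.samples)) < 0.05 * rms(w.samples)

    def test_flow_drift_attenuated_20db(self):
        t = np.arange(0, 2000, 0.1)
        w = Waveform("Flow", 10.0, np.sin(2 * np.pi * 0.005 * t))
        out = preprocess_flow(w)
        assert rms(out.samples) < 0.1 * rms(w.samples)  # >= 20 dB

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            preprocess_ppg(Waveform("PPG", 100.0, np.array([])))


class TestModelConfig:
    def test_default_receptive_field_in_spec_band(self):
        rf = ModelConfig().receptive_field_s()
        assert 80.0 <= rf <= 100.0

    def test_bad_pooling_rejected(self):
        with pytest.raises(ValueError, match="pooling"):
            ArousalNet(ModelConfig(cardiac_pools=(5, 5, 2, 2)))

    def test_bad_receptive_field_rejected(self):
        with pytest.raises(ValueError, match="receptive field"):
            ArousalNet(ModelConfig(arousal_dilations=((1,), (1,), (1,))))


class TestForward:
    def test_rate_arithmetic_90s(self):
        net = ArousalNet(small_config(seed=1))
        ihr, prob = net.forward(np.random.randn(1, 1, 9000).astype(np.float32),
                                np.random.randn(1, 1, 900).astype(np.float32))
        assert prob.shape == (1, 1, 180)
        assert ihr.shape == (1, 1, 180)

    def test_probabilities_bounded(self):
        net = ArousalNet(small_config(seed=2))
        rng = np.random.default_rng(0)
        _, prob = net.forward(5 * rng.standard_normal((2, 1, 6000)).astype(np.float32),
                              5 * rng.standard_normal((2, 1, 600)).astype(np.float32))
        assert prob.min() >= 0.0 and prob.max() <= 1.0

    def test_deterministic(self):
        net = ArousalNet(small_config(seed=3))
        x = np.random.default_rng(1).standard_normal((1, 1, 6000)).astype(np.float32)
        f = np.random.default_rng(2).standard_normal((1, 1, 600)).astype(np.float32)
        a = net.forward(x, f)[1]
        b = net.forward(x, f)[1]
        np.testing.assert_array_equal(a, b)

    def test_receptive_field_locality(self):
        net = ArousalNet(ModelConfig(seed=4))
        rng = np.random.default_rng(5)
        x = rng.standard_normal((1, 1, 15000)).astype(np.float32)  # 150 s
        f = rng.standard_normal((1, 1, 1500)).astype(np.float32)
        _, p0 = net.forward(x, f)
        x2 = x.copy()
        x2[0, 0, : 2500] += 10.0  # perturbation ends at t = 25 s
        f2 = f.copy()
        f2[0, 0, : 250] += 10.0
        _, p1 = net.forward(x2, f2)
        i = int(80 * 2)  # probe t = 80 s, 55 s from the perturbation
        assert abs(float(p1[0, 0, i] - p0[0, 0, i])) < 1e-6

    def test_zero_overlap_rejected(self):
        net = ArousalNet(small_config(seed=5))
        ppg = Waveform("PPG", 100.0, np.zeros(6000), start=0.0)
        flow = Waveform("Flow", 10.0, np.zeros(600), start=100.0)
        with pytest.raises(ValueError):
            net.predict(ppg, flow)

    def test_rate_mismatch_rejected(self):
        net = ArousalNet(small_config(seed=6))
        with pytest.raises(ValueError):
            net.predict(Waveform("PPG", 50.0, np.zeros(3000)),
                        Waveform("Flow", 10.0, np.zeros(600)))


class TestGradients:
    def test_conv_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(7)
        conv = Conv1d(2, 3, 3, dilation=2, rng=rng)
        x = rng.standard_normal((2, 2, 16)).astype(np.float32)
        y = conv.forward(x)
        g = rng.standard_normal(y.shape).astype(np.float32)
        conv.W.grad[...] = 0
        gx = conv.backward(g)
        eps = 1e-3
        for idx in [(0, 0, 0), (1, 1, 2), (2, 0, 1)]:
            w0 = conv.W.value[idx]
            conv.W.value[idx] = w0 + eps
            lp = float((conv.forward(x) * g).sum())
            conv.W.value[idx] = w0 - eps
            lm = float((conv.forward(x) * g).sum())
            conv.W.value[idx] = w0
            assert conv.W.grad[idx] == pytest.approx((lp - lm) / (2 * eps), rel=2e-2)
        i = (1, 0, 7)
        x2 = x.copy()
        x2[i] += eps
        lp = float((conv.forward(x2) * g).sum())
        x2[i] -= 2 * eps
        lm = float((conv.forward(x2) * g).sum())
        assert gx[i] == pytest.approx((lp - lm) / (2 * eps), rel=2e-2)

    def test_resblock_gradient_direction(self):
        # one Adam step on a scalar objective must reduce it
        rng = np.random.default_rng(8)
        block = ResBlock(1, 4, (1, 2), 3, 2, rng)
        x = rng.standard_normal((2, 1, 32)).astype(np.float32)
        opt = Adam(block.params(), lr=1e-2)
        losses = []
        for _ in range(30):
            y = block.forward(x)
            losses.append(float((y ** 2).mean()))
            opt.zero_grad()
            block.backward(2 * y / y.size)
            opt.step()
        assert losses[-1] < losses[0]

    def test_maxpool_backward_routes_to_argmax(self):
        pool = MaxPool(2)
        x = np.array([[[1.0, 3.0, 2.0, 0.0]]], dtype=np.float32)
        y = pool.forward(x)
        gx = pool.backward(np.ones_like(y))
        np.testing.assert_array_equal(gx[0, 0], [0.0, 1.0, 1.0, 0.0])


class TestTraining:
    def test_stretch_identity(self):
        ihr = np.full(10, 60.0)
        np.testing.assert_array_equal(stretch_targets(ihr, 1.0), ihr)

    def test_stretch_reciprocal_scaling(self):
        np.testing.assert_allclose(stretch_targets(np.full(4, 60.0), 0.8), 75.0)

    def test_invalid_phase_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(phase="both")

    def test_end2end_requires_arousal_labels(self, small_wave_cohort):
        from somnoscore.annotations import AnnotationSet, Hypnogram, SubjectRecord
        from dataclasses import replace
        rec = small_wave_cohort[0]
        bare = AnnotationSet(Hypnogram(rec.psg_ref.hypnogram.stages),
                             [e for e in rec.psg_ref.events
                              if not e.etype.startswith("arousal")],
                             rec.psg_ref.rec_duration)
        stripped = replace(rec, psg_ref=bare)
        net = ArousalNet(small_config(seed=9))
        with pytest.raises(ValueError, match="arousal"):
            train_end2end(net, [stripped],
                          TrainConfig(phase="end2end", epochs=1, steps_per_epoch=1))

    def test_mean_probability_decreases_on_negative_labels(self, small_wave_cohort):
        from dataclasses import replace
        from somnoscore.annotations import AnnotationSet, Hypnogram, ScoredEvent
        # keep one token arousal so training is legal; nearly all targets are 0
        rec = small_wave_cohort[0]
        events = [e for e in rec.psg_ref.events if not e.etype.startswith("arousal")]
        events.append(ScoredEvent("arousal_cortical", 1.0, 2.0))
        ref = AnnotationSet(Hypnogram(rec.psg_ref.hypnogram.stages), events,
                            rec.psg_ref.rec_duration)
        rec = replace(rec, psg_ref=ref)
        net = ArousalNet(small_config(seed=10))
        x = rec.waveforms["ppg"].samples[None, None, :30000].astype(np.float32)
        f = rec.waveforms["flow"].samples[None, None, :3000].astype(np.float32)
        before = float(net.forward(x, f)[1].mean())
        train_end2end(net, [rec], TrainConfig(phase="end2end", epochs=2,
                                              steps_per_epoch=10, window_s=96,
                                              batch_size=4, pos_weight=1.0))
        after = float(net.forward(x, f)[1].mean())
        assert after < before

    def test_cardiac_freeze_contract(self, small_wave_cohort):
        net = ArousalNet(small_config(seed=11))
        h0 = net.cardiac_hash()
        log = train_end2end(net, list(small_wave_cohort[:2]),
                            TrainConfig(phase="end2end", epochs=1,
                                        steps_per_epoch=5, window_s=96,
                                        batch_size=2))
        assert net.cardiac_hash() == h0
        assert log.cardiac_hash_before == log.cardiac_hash_after == h0
        # and the detector parameters did change
        assert params_hash(net.detector_params()) != h0


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path):
        net = ArousalNet(small_config(seed=12))
        rng = np.random.default_rng(3)
        x = rng.standard_normal((1, 1, 6000)).astype(np.float32)
        f = rng.standard_normal((1, 1, 600)).astype(np.float32)
        _, p0 = net.forward(x, f)
        path = tmp_path / "model.ckpt"
        net.save(path)
        net2 = ArousalNet.load(path)
        _, p1 = net2.forward(x, f)
        np.testing.assert_array_equal(p0, p1)
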