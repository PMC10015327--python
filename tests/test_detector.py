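import numpy as np
import pytest

from pampipe.audio.frontend import window_stream
from pampipe.audio.synth import CallEvent, Waveform, render_recording, make_clipset
from pampipe.detector.autodiff import Tensor
from pampipe.detector.metrics import evaluate, harmonic_f1
from pampipe.detector.model import AttentionPool, DetectorConfig, build_model
from pampipe.detector.training import predict, predict_clips, split_site_independent, train
from pampipe.detector.export import export_positives

from conftest import MEL, RATE, CLIP_LEN


class TestArchitecture:
    def test_se_identity_gate_equals_no_se(self):
        cfg = DetectorConfig(conv_channels=(4, 8), attention_heads=2, dropout=0.0, seed=3)
        m = build_model(cfg)
        x = np.random.default_rng(0).standard_normal((2, 16, 16))
        for se in m.se:
            se.gate_override = np.ones(se.w2.shape[1])
        with_identity = m.forward(x).data
        m.cfg.use_se = False
        without_se = m.forward(x).data
        assert np.allclose(with_identity, without_se, atol=1e-12)

    def test_uniform_attention_equals_mean_pooling(self):
        rng = np.random.default_rng(1)
        pool = AttentionPool(dim=8, heads=2, rng=rng)
        frames = Tensor(rng.standard_normal((3, 7, 8)))
        pool.force_uniform = True
        pooled = pool(frames).data
        expected = np.concatenate(
            [frames.data.mean(axis=1) @ wv.data for wv in pool.value_w], axis=-1
        )
        assert np.allclose(pooled, expected, atol=1e-12)

    def test_single_frame_attention_returns_that_frame(self):
        rng = np.random.default_rng(2)
        pool = AttentionPool(dim=8, heads=4, rng=rng)
        frames = Tensor(rng.standard_normal((2, 1, 8)))
        attended = pool(frames).data
        pool.force_uniform = True
        uniform = pool(frames).data
        assert np.allclose(attended, uniform, atol=1e-12)

    def test_confidence_in_unit_interval(self):
        m = build_model(DetectorConfig(conv_channels=(4, 8), attention_heads=2))
        x = np.random.default_rng(3).standard_normal((4, 16, 16)) * 10
        c = m.confidence(x)
        assert np.all((c >= 0) & (c <= 1))

    def test_heads_must_divide_dim(self):
        with pytest.raises(ValueError):
            AttentionPool(dim=6, heads=4, rng=np.random.default_rng(0))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            DetectorConfig(threshold=1.5)
        with pytest.raises(ValueError):
            DetectorConfig(attention_heads=0)

    def test_save_load_roundtrip(self, tmp_path):
        cfg = DetectorConfig(conv_channels=(4, 8), attention_heads=2, seed=5)
        m = build_model(cfg)
        x = np.random.default_rng(4).standard_normal((2, 16, 16))
        path = str(tmp_path / "model.npz")
        m.save(path)
        m2 = type(m).load(path)
        assert np.allclose(m.confidence(x), m2.confidence(x))


class TestSplit:
    def test_13_sites_test_partition_has_3(self):
        clips = make_clipset(26, 26, 0.0, 13, clip_length=CLIP_LEN, rate=RATE, seed=0)
        tr, va, te = split_site_independent(clips, fractions=(0.54, 0.23, 0.23), seed=1)
        assert len({c.site_id for c in te}) == 3

    def test_site_disjointness(self, easy_clipset):
        tr, va, te = split_site_independent(easy_clipset, seed=0)
        s = [{c.site_id for c in p} for p in (tr, va, te)]
        assert not (s[0] & s[1]) and not (s[0] & s[2]) and not (s[1] & s[2])
        assert len(tr) + len(va) + len(te) == len(easy_clipset)

    def test_three_sites_one_each(self):
        clips = make_clipset(6, 6, 0.0, 3, clip_length=CLIP_LEN, rate=RATE, seed=0)
        parts = split_site_independent(clips, fractions=(1 / 3, 1 / 3, 1 / 3), seed=2)
        assert all(len({c.site_id for c in p}) == 1 for p in parts)

    def test_deterministic(self, easy_clipset):
        a = split_site_independent(easy_clipset, seed=4)
        b = split_site_independent(easy_clipset, seed=4)
        assert [[c.clip_id for c in p] for p in a] == [[c.clip_id for c in p] for p in b]

    def test_too_few_sites_rejected(self):
        clips = make_clipset(4, 4, 0.0, 2, clip_length=CLIP_LEN, rate=RATE, seed=0)
        with pytest.raises(ValueError):
            split_site_independent(clips)


class TestTraining:
    def test_separable_clipset_high_uar(self, trained_detector):
        assert trained_detector["log"].attrs["best_val_uar"] >= 0.95

    def test_loss_decreases(self, trained_detector):
        log = trained_detector["log"]
        assert log["train_loss"].iloc[-1] < log["train_loss"].iloc[0]

    def test_permuted_labels_chance_level(self, easy_clipset):
        rng = np.random.default_rng(0)
        import copy

        clips = [copy.copy(c) for c in easy_clipset]
        labels = [c.label for c in clips]
        for c, lab in zip(clips, rng.permutation(labels)):
            c.label = lab
        cfg = DetectorConfig(epochs=3, seed=1, lr=2e-3)
        tr, va, te = split_site_independent(clips, seed=1)
        m = build_model(cfg)
        m, log = train(m, tr, va, cfg, MEL)
        conf = predict_clips(m, te, MEL)
        rep = evaluate(conf, [1 if c.label == "positive" else 0 for c in te], threshold=0.5)
        assert 0.25 <= rep.uar <= 0.8  # chance level, wide band at desk scale

    def test_zero_epochs_flagged_untrained(self, easy_clipset):
        cfg = DetectorConfig(epochs=0, seed=0)
        tr, va, _ = split_site_independent(easy_clipset, seed=0)
        m, log = train(build_model(cfg), tr, va, cfg, MEL)
        assert not m.trained and log.empty

    def test_single_class_train_rejected(self, easy_clipset):
        tr, va, _ = split_site_independent(easy_clipset, seed=0)
        pos_only = [c for c in tr if c.label == "positive"]
        with pytest.raises(ValueError):
            train(build_model(DetectorConfig(epochs=1)), pos_only, va, mel=MEL)


@pytest.fixture(scope="module")
def rendered(tmp_path_factory):
    out = tmp_path_factory.mktemp("audio")
    schedule = [(0.0, 0.02)]  # 72 s window
    events = [
        CallEvent(onset=o, duration=0.8, kind="whinny", snr_db=22.0)
        for o in (10.0, 30.0, 55.0)
    ]
    manifest = render_recording(schedule, events, rate=RATE, out_dir=str(out), seed=9)
    fname = manifest.iloc[0]["file"]
    w = Waveform.read(str(out / fname))
    windows = list(window_stream(w, CLIP_LEN, CLIP_LEN / 2, MEL, source=fname))
    return {"dir": out, "windows": windows, "events": events, "file": fname}


class TestPredict:
    def test_threshold_zero_emits_all(self, trained_detector, rendered):
        dets = predict(trained_detector["model"], rendered["windows"], 0.0, site_id="s")
        assert len(dets) == len(rendered["windows"])

    def test_invalid_threshold_rejected(self, trained_detector, rendered):
        with pytest.raises(ValueError):
            predict(trained_detector["model"], rendered["windows"], 1.0 + 1e-9)

    def test_threshold_monotonicity(self, trained_detector, rendered):
        m = trained_detector["model"]
        ids5 = {d.detection_id for d in predict(m, rendered["windows"], 0.5, site_id="s")}
        ids3 = {d.detection_id for d in predict(m, rendered["windows"], 0.3, site_id="s")}
        assert ids5 <= ids3

    def test_windows_over_calls_score_higher(self, trained_detector, rendered):
        m = trained_detector["model"]
        dets = predict(m, rendered["windows"], 0.0, site_id="s")
        conf = np.array([d.confidence for d in dets])
        overlap = np.array(
            [
                any(w.start < ev.onset + ev.duration and ev.onset < w.end
                    for ev in rendered["events"])
                for w in rendered["windows"]
            ]
        )
        pos, neg = conf[overlap], conf[~overlap]
        auroc = np.mean([p > n for p in pos for n in neg])
        assert auroc >= 0.9

    def test_export_positives(self, trained_detector, rendered, tmp_path):
        m = trained_detector["model"]
        dets = predict(m, rendered["windows"], 0.0, site_id="s")[:5]
        df = export_positives(dets, str(rendered["dir"]), str(tmp_path / "out"))
        assert len(df) == 5
        clips = sorted((tmp_path / "out" / "clips").iterdir())
        assert len(clips) == 5
        assert set(df["clip"]) == {c.name for c in clips}
        # clip re-read is sample-identical to the source window
        src = Waveform.read(str(rendered["dir"] / rendered["file"]))
        d0 = dets[0]
        clip = Waveform.read(str(tmp_path / "out" / "clips" / df.iloc[0]["clip"]))
        s = slice(int(d0.start * RATE), int(d0.end * RATE))
        assert np.array_equal(clip.samples, src.samples[s])
        assert clip.duration == pytest.approx(CLIP_LEN)

    def test_export_empty(self, tmp_path):
        df = export_positives([], str(tmp_path), str(tmp_path / "out"))
        assert df.empty and (tmp_path / "out" / "positives.csv").exists()
        assert list((tmp_path / "out" / "clips").iterdir()) == []

    def test_export_missing_audio(self, trained_detector, rendered, tmp_path):
        dets = predict(trained_detector["model"], rendered["windows"], 0.0, site_id="s")[:1]
        dets[0].file = "nonexistent.wav"
        with pytest.raises(IOError):
            export_positives(dets, str(rendered["dir"]), str(tmp_path / "out"))


class TestEvaluate:
    def test_hand_confusion_uar(self):
        # TP=3, FN=1, FP=2, TN=4 -> UAR = (0.75 + 4/6) / 2
        preds = [1, 1, 1, 0, 1, 1, 0, 0, 0, 0]
        labels = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        rep = evaluate(preds, labels)
        assert (rep.tp, rep.fn, rep.fp, rep.tn) == (3, 1, 2, 4)
        assert rep.uar == pytest.approx((0.75 + 4 / 6) / 2)
        assert rep.n == 10

    def test_f1_from_printed_precision_recall(self):
        # harmonic mean of 0.53 and 0.75 is 62% (to the nearest percent)
        assert round(100 * harmonic_f1(0.53, 0.75)) == 62

    def test_perfect_predictions(self):
        rep = evaluate([1, 0, 1, 0], [1, 0, 1, 0])
        assert rep.uar == 1.0 and rep.precision == 1.0 and rep.f1 == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            evaluate([], [])

    def test_misaligned_rejected(self):
        with pytest.raises(ValueError):
            evaluate([1, 0], [1])

    def test_threshold_application(self):
        rep = evaluate([0.9, 0.4, 0.6], [1, 0, 1], threshold=0.5)
        assert rep.tp == 2 and rep.tn == 1
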