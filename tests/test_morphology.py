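"""Morphology features, classifier, training harness and orchestration."""

import numpy as np
import pytest

from ectopy.beat_detection import BeatEvent, beats_from_annotations, mark_noise
from ectopy.errors import InvalidInputError
from ectopy.evaluation import match
from ectopy.io_signals import EcgSignal, preprocess
from ectopy.morphology import (BeatFeatureVector, ClassifierModel, FEATURE_NAMES,
                               classify, detect_pvcs, extract_features,
                               train_model)
from ectopy.synth_ecg import SyntheticConfig, prototype_wave, simulate
from ectopy.templates import NsrTemplate, window_length
from ectopy.trigger import CandidateEvent


def _fv(seq="single", **over):
    base = dict(one_minus_cwa=0.0, one_minus_dcwa=0.0, prematurity=1.0,
                compensatory_ratio=1.0, amp_ratio=1.0, slew_ratio=1.0,
                width_ratio=1.0)
    base.update(over)
    return BeatFeatureVector(seq_type=seq, **base)


def _model(weights, intercept=0.0, thr=0.5, seq="single"):
    return ClassifierModel(seq_type=seq, feature_names=FEATURE_NAMES,
                           means=np.zeros(7), scales=np.ones(7),
                           weights=np.asarray(weights, float),
                           intercept=intercept, decision_threshold=thr)


def _signal_with_proto(proto, fs=256.0, at=2.0, dur=4.0, amp=600.0):
    t = np.arange(int(dur * fs)) / fs
    w = prototype_wave(proto, fs, amp_uv=amp)
    x = np.zeros_like(t)
    i0 = int(at * fs) - len(w) // 2
    x[i0:i0 + len(w)] += w
    return EcgSignal(samples=x, fs=fs)


def _template(fs=256.0):
    L = window_length(fs)
    proto = prototype_wave("nsr", fs)
    c = len(proto) // 2
    return NsrTemplate(window=proto[c - L // 2: c + L // 2 + 1].copy(),
                       n_beats_used=16, valid=True)


def _candidate(t, seq="single", prematurity=1.0, amp_ratio=1.0):
    return CandidateEvent(beat=BeatEvent(time=t, peak_amp=600.0), index=1,
                          seq_type=seq, member_index=0, rr_prev=prematurity,
                          rr_next=1.0, rr_local_mean=1.0,
                          prematurity=prematurity, amp_ratio=amp_ratio)


class TestExtractFeatures:
    def test_template_identical_beat_on_time(self):
        sig = _signal_with_proto("nsr")
        fv = extract_features(sig, _candidate(2.0), _template(), [])
        assert fv.one_minus_cwa == pytest.approx(0.0, abs=1e-6)
        assert fv.prematurity == pytest.approx(1.0)
        assert fv.width_ratio == pytest.approx(1.0)

    def test_wide_inverted_ectopic_beat_is_dissimilar(self):
        sig = _signal_with_proto("pvc_wide")
        fv = extract_features(sig, _candidate(2.0, prematurity=0.72),
                              _template(), [])
        assert fv.one_minus_cwa >= 0.5

    def test_scale_invariance_of_cwa_with_amp_ratio_preserved(self):
        sig = _signal_with_proto("nsr", amp=1200.0)
        fv = extract_features(sig, _candidate(2.0, amp_ratio=2.0),
                              _template(), [])
        assert fv.one_minus_cwa == pytest.approx(0.0, abs=1e-6)
        assert fv.amp_ratio == pytest.approx(2.0)

    def test_window_beyond_record_bounds_rejected(self):
        sig = _signal_with_proto("nsr")
        with pytest.raises(InvalidInputError):
            extract_features(sig, _candidate(0.01), _template(), [])

    def test_invalid_template_rejected(self):
        sig = _signal_with_proto("nsr")
        bad = NsrTemplate(window=np.zeros(51), valid=False)
        with pytest.raises(InvalidInputError):
            extract_features(sig, _candidate(2.0), bad, [])


class TestClassify:
    def test_zero_logit_gives_half_probability(self):
        lab = classify(_fv(), _model(np.zeros(7), intercept=0.0))
        assert lab.probability == pytest.approx(0.5)
        assert lab.is_pvc  # p >= threshold

    def test_saturation_toward_one(self):
        lab = classify(_fv(one_minus_cwa=50.0), _model([10, 0, 0, 0, 0, 0, 0]))
        assert lab.probability == pytest.approx(1.0, abs=1e-12)

    def test_probability_matches_hand_computed_logistic(self):
        rng = np.random.default_rng(11)
        w = rng.normal(size=7)
        fv = _fv(one_minus_cwa=1.3, prematurity=0.7, amp_ratio=2.1)
        z = float(np.dot(w, fv.values()) + 0.37)
        lab = classify(fv, _model(w, intercept=0.37))
        assert lab.probability == pytest.approx(1 / (1 + np.exp(-z)), abs=1e-12)

    def test_sequence_type_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            classify(_fv(seq="couplet"), _model(np.zeros(7), seq="single"))


class TestTrainModel:
    def _separable(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        feats, labs = [], []
        for _ in range(n):
            y = int(rng.random() < 0.5)
            feats.append(_fv(one_minus_cwa=(1.5 if y else 0.05)
                             + 0.05 * rng.standard_normal(),
                             prematurity=(0.7 if y else 1.0)))
            labs.append(y)
        return feats, labs

    def test_separable_data_trains_to_high_accuracy(self):
        feats, labs = self._separable()
        model = train_model(feats, labs, "single", seed=1)
        pred = [classify(f, model).is_pvc for f in feats]
        acc = np.mean([p == bool(y) for p, y in zip(pred, labs)])
        assert acc >= 0.99

    def test_same_seed_reproduces_identical_weights(self):
        feats, labs = self._separable()
        m1 = train_model(feats, labs, "single", seed=7)
        m2 = train_model(feats, labs, "single", seed=7)
        np.testing.assert_array_equal(m1.weights, m2.weights)
        assert m1.decision_threshold == m2.decision_threshold
        assert m1.data_hash == m2.data_hash

    def test_shuffled_labels_give_prevalence_level_f1(self):
        rng = np.random.default_rng(3)
        feats, labs = self._separable(n=400, seed=3)
        shuffled = list(labs)
        rng.shuffle(shuffled)
        model = train_model(feats, shuffled, "single", seed=3)
        held = [classify(f, model).is_pvc for f in feats]
        tp = sum(h and y for h, y in zip(held, shuffled))
        fp = sum(h and not y for h, y in zip(held, shuffled))
        fn = sum((not h) and y for h, y in zip(held, shuffled))
        f1 = 2 * tp / max(1, 2 * tp + fp + fn)
        prev = np.mean(shuffled)
        assert f1 <= prev + 0.25  # no better than chance-level

    def test_single_class_input_rejected(self):
        feats, _ = self._separable(n=60)
        with pytest.raises(InvalidInputError):
            train_model(feats, [1] * 60, "single", seed=0)

    def test_model_json_roundtrip(self, tmp_path):
        feats, labs = self._separable()
        model = train_model(feats, labs, "single", seed=2)
        p = str(tmp_path / "m.json")
        model.to_json(p)
        back = ClassifierModel.from_json(p)
        np.testing.assert_array_equal(back.weights, model.weights)
        assert back.decision_threshold == model.decision_threshold
        assert back.data_hash == model.data_hash


class TestDetectPvcs:
    def test_pure_nsr_yields_no_pvc_labels(self, cfg, models):
        res = simulate(SyntheticConfig(duration=300, seed=14))
        work = preprocess(res.signal)
        beats = beats_from_annotations(res.annotations, work)
        labels = detect_pvcs(work, beats, [], cfg, models)
        assert sum(l.is_pvc for l in labels) == 0

    def test_single_pvc_count_within_ten_percent(self, cfg, models,
                                                 ectopy_pipeline_inputs):
        res, work, beats, noise = ectopy_pipeline_inputs
        labels = detect_pvcs(work, beats, noise, cfg, models)
        n_est = sum(l.is_pvc for l in labels)
        n_true = len(res.truth.v_times)
        assert abs(n_est - n_true) <= 0.10 * n_true

    def test_sequence_sensitivity_close_to_single_sensitivity(self, cfg, models):
        res = simulate(SyntheticConfig(duration=900, target_burden_pct=15,
                                       seed=77, seq_mix=(0.4, 0.1, 0.3, 0.2)))
        work = preprocess(res.signal)
        beats = beats_from_annotations(res.annotations, work)
        labels = detect_pvcs(work, beats, [], cfg, models)
        det = [l.beat.time for l in labels if l.is_pvc]
        seq_v = [t for t, s in res.truth.seq_type_of.items()
                 if s in ("couplet", "triplet")]
        sgl_v = [t for t, s in res.truth.seq_type_of.items() if s == "single"]
        ms = match(det, seq_v, 0.150)
        mg = match(det, sgl_v, 0.150)
        seq_sens = ms.n_tp / (ms.n_tp + ms.n_fn)
        sgl_sens = mg.n_tp / (mg.n_tp + mg.n_fn)
        assert seq_sens >= 0.8 * sgl_sens

    def test_missing_model_rejected(self, cfg, models):
        res = simulate(SyntheticConfig(duration=60, seed=15))
        work = preprocess(res.signal)
        beats = beats_from_annotations(res.annotations, work)
        partial = {k: v for k, v in models.items() if k != "triplet"}
        with pytest.raises(InvalidInputError):
            detect_pvcs(work, beats, [], cfg, partial)
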