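"""Two-head training, OpenMax calibration, and open-set clip decisions."""

import dataclasses

import numpy as np
import pytest

from ivcflow import phantom, retrieval
from ivcflow.retrieval import (
    OpenMaxCalibration,
    classify_clip,
    compute_mavs,
    fit_weibull_tail,
    openmax_scores,
    train_two_head,
)


def toy_calibration(K=2, shape=2.0, scale=1.0, alpha=2):
    mavs = np.eye(K) * 5.0
    return OpenMaxCalibration(
        classes=[f"c{i}" for i in range(K)], mavs=mavs,
        weibulls=[(shape, scale, 0.0)] * K, tail_size=5, alpha=alpha,
    )


class TestTraining:
    def test_separable_classes_high_heldout_accuracy(self, small_corpus,
                                                     trained_two_head):
        model, _ = trained_two_head
        test = small_corpus.subset("test")
        frames, views, _ = test.frames_and_labels()
        X = model.features(frames)
        pred = np.argmax(model.activations(X), axis=1)
        known = [(p, v) for p, v in zip(pred, views) if v in model.view_classes]
        acc = np.mean([model.view_classes[p] == v for p, v in known])
        assert acc >= 0.95

    def test_same_seed_identical_loss(self, small_corpus):
        m1 = train_two_head(small_corpus, {"epochs": 40}, seed=5)
        m2 = train_two_head(small_corpus, {"epochs": 40}, seed=5)
        assert m1.final_loss == m2.final_loss

    def test_single_view_class_rejected(self):
        frames = [np.zeros((32, 32))] * 4
        with pytest.raises(ValueError, match="view classes"):
            train_two_head((frames, ["ivc"] * 4, ["good", "bad"] * 2))

    def test_missing_quality_label_rejected(self):
        frames = [np.zeros((32, 32))] * 4
        with pytest.raises(ValueError, match="quality"):
            train_two_head((frames, ["ivc", "ivc", "plax_like", "plax_like"],
                            ["good"] * 4))

    def test_checkpoint_round_trip(self, trained_two_head, tmp_path):
        model, _ = trained_two_head
        model.save(tmp_path / "m.npz")
        back = retrieval.TwoHeadModel.load(tmp_path / "m.npz")
        x = np.random.default_rng(0).random((2, 32 * 32))
        assert np.allclose(back.activations(x), model.activations(x))
        assert back.view_classes == model.view_classes


class TestMavs:
    def test_mav_is_mean_of_activations(self, trained_two_head, small_corpus):
        model, _ = trained_two_head
        frames, views, _ = small_corpus.subset("train").frames_and_labels()
        mavs = compute_mavs(model, frames, views)
        X = model.features(frames)
        A = model.activations(X)
        pred = np.argmax(A, axis=1)
        k = model.view_classes.index("ivc")
        idx = [i for i, v in enumerate(views) if v == "ivc" and pred[i] == k]
        assert np.allclose(mavs["ivc"], A[idx].mean(axis=0))

    def test_absent_class_raises_with_name(self, trained_two_head):
        model, _ = trained_two_head
        frames = [np.zeros((40, 40))] * 2
        missing = model.view_classes[0]
        with pytest.raises(ValueError, match=missing):
            compute_mavs(model, frames, ["plax_like"] * 2)


class TestWeibullTail:
    def test_cdf_zero_at_shift_and_monotone(self):
        rng = np.random.default_rng(0)
        d = rng.weibull(1.5, 200) + 0.2
        shape, scale, shift = fit_weibull_tail(d, 50, shift=0.1)
        calib = OpenMaxCalibration(["a"], np.zeros((1, 1)),
                                   [(shape, scale, shift)], tail_size=5, alpha=1)
        assert calib.wscore(0, 0.0) == 0.0
        grid = [calib.wscore(0, x) for x in np.linspace(0, 10, 50)]
        assert all(b >= a for a, b in zip(grid, grid[1:]))
        assert all(0 <= g <= 1 for g in grid)

    def test_recovers_known_parameters(self):
        rng = np.random.default_rng(1)
        sample = rng.weibull(2.0, 10_000) * 1.0  # shape 2, scale 1
        shape, scale, _ = fit_weibull_tail(sample, 10_000)
        assert shape == pytest.approx(2.0, rel=0.1)
        assert scale == pytest.approx(1.0, rel=0.1)

    def test_too_few_distances(self):
        with pytest.raises(ValueError):
            fit_weibull_tail([1.0, 2.0], 5)

    def test_degenerate_all_equal(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_weibull_tail([1.0] * 30, 10)


class TestOpenMaxScores:
    def test_probability_vector(self):
        calib = toy_calibration()
        probs = openmax_scores(np.array([3.0, 1.0]), calib)
        assert probs.shape == (3,)
        assert probs.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(probs >= 0)

    def test_alpha_zero_is_closed_set_softmax(self):
        calib = toy_calibration()
        v = np.array([2.0, -1.0])
        probs = openmax_scores(v, calib, alpha=0)
        closed = np.exp(v) / np.exp(v).sum()
        assert probs[-1] == 0.0
        assert np.allclose(probs[:2], closed)

    def test_at_mav_with_positive_shift_no_unknown_mass(self):
        calib = toy_calibration()
        calib.weibulls = [(2.0, 1.0, 0.5), (2.0, 1.0, 0.5)]
        v = calib.mavs[0].copy()  # distance 0 < shift -> w = 0
        probs = openmax_scores(v, calib)
        closed = np.exp(v) / np.exp(v).sum()
        # no mass removed from the top class; unknown gets only exp(0) share
        assert probs[-1] == pytest.approx(
            1.0 / (np.exp(v).sum() + 1.0), abs=1e-12)
        assert np.allclose(probs[:2] * (np.exp(v).sum() + 1.0), np.exp(v))

    def test_far_activation_maps_to_unknown(self):
        calib = toy_calibration()
        v = np.array([40.0, 39.0])  # far beyond both fitted tails
        probs = openmax_scores(v, calib)
        assert np.argmax(probs) == 2

    def test_monotone_in_distance(self):
        # growing distance from the top-class MAV never raises its probability
        calib = toy_calibration(K=2, alpha=1)
        last = 1.0
        for delta in np.linspace(0, 3.5, 15):
            # move v away from MAV_0 while keeping v_0 fixed and class 0 top
            probs = openmax_scores(np.array([5.0, 1.0 + delta]), calib)
            k0 = probs[0] / (probs[0] + probs[2])  # class-0 share vs unknown
            assert k0 <= last + 1e-12
            last = k0

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            openmax_scores(np.array([1.0, 2.0, 3.0]), toy_calibration())

    def test_permutation_equivariance(self):
        calib = toy_calibration()
        v = np.array([2.0, 0.5])
        p = openmax_scores(v, calib)
        # permute class order: MAV rows AND their coordinates swap together
        swapped = OpenMaxCalibration(
            classes=calib.classes[::-1], mavs=calib.mavs[::-1, ::-1],
            weibulls=calib.weibulls[::-1], tail_size=5, alpha=2)
        q = openmax_scores(v[::-1], swapped)
        assert np.allclose(q[:2], p[:2][::-1]) and q[2] == pytest.approx(p[2])

    def test_calibration_json_round_trip(self, trained_two_head, tmp_path):
        _, calib = trained_two_head
        calib.to_json(tmp_path / "c.json")
        back = OpenMaxCalibration.from_json(tmp_path / "c.json")
        v = np.asarray(calib.mavs[0]) + 0.3
        assert np.allclose(openmax_scores(v, back), openmax_scores(v, calib))


class TestClipDecisions:
    def test_identical_frames_clip_equals_frame(self, trained_two_head):
        model, calib = trained_two_head
        frame = np.random.default_rng(3).random((96, 128))
        clip = _clip_from_frames([frame] * 5)
        dec = classify_clip(model, calib, clip)
        assert np.allclose(dec.view_probs, dec.frame_view_probs[0])

    def test_good_ivc_phantom_accepted(self, trained_two_head):
        model, calib = trained_two_head
        params = phantom.PhantomParams(
            image_size=(96, 128), mm_per_px=0.5, frame_rate_hz=2.0,
            n_cycles=1, seed=77)
        clip, _, _, _ = phantom.make_clip(params)
        dec = classify_clip(model, calib, clip)
        assert dec.view_label == "ivc" and dec.quality_label == "good"
        assert dec.analyzable

    def test_dropout_artifact_raises_unknown_probability(self, trained_two_head):
        model, calib = trained_two_head
        base = phantom.PhantomParams(
            image_size=(96, 128), mm_per_px=0.5, frame_rate_hz=2.0,
            n_cycles=1, seed=33)
        clean_clip, _, _, _ = phantom.make_clip(base)
        drop = dataclasses.replace(base, dropout_frames=tuple(range(0, 8, 2)))
        drop_clip, _, _, _ = phantom.make_clip(drop)
        p_clean = classify_clip(model, calib, clean_clip).view_probs[-1]
        p_drop = classify_clip(model, calib, drop_clip).view_probs[-1]
        assert p_drop > p_clean

    def test_short_clip_single_frame_fallback(self, trained_two_head):
        model, calib = trained_two_head
        frame = np.random.default_rng(4).random((96, 128))
        clip = _clip_from_frames([frame])
        dec = classify_clip(model, calib, clip, frame_stride=10)
        assert dec.frame_view_probs.shape[0] == 1


def _clip_from_frames(frames):
    from ivcflow.media_io import VideoClip

    stack = np.stack([f / max(f.max(), 1e-9) for f in frames])
    return VideoClip(stack, 30.0, 0.5, source_id="synthetic")
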