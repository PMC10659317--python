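"""Segment decoding: classifiers, repeated splits, chance bands."""

import numpy as np
import pytest

from instaspace._lstm import BiLSTMClassifier
from instaspace.decode import (DecoderSpec, ParameterError,
                               accuracy_timecourse, chance_accuracy_band,
                               fit_segment_classifier)
from instaspace.subspace import instantaneous_subspace_series

from conftest import make_tensor

OBJECTS = ("sphere", "button", "coax", "perp")
FAST_LSTM = DecoderSpec(classifier="bilstm", epochs=60, n_repeats=5)
LOGISTIC = DecoderSpec(classifier="logistic", n_repeats=10)


def gaussian_segments(rng, n_per_class=12, t_len=30, dim=3, sep=0.0):
    """Single-trial segments; class means separated by ``sep``."""
    out = {}
    for i, o in enumerate(OBJECTS):
        mean = np.zeros(dim)
        mean[i % dim] = sep * (1 if i < dim else -1)
        out[o] = mean + rng.standard_normal((n_per_class, t_len, dim))
    return out


class TestBiLSTMInternals:
    def test_gradients_match_numerical_differentiation(self):
        rng = np.random.default_rng(0)
        clf = BiLSTMClassifier(n_hidden=3, n_classes=4, seed=1)
        xs = rng.standard_normal((5, 4, 2))     # (T, B, d)
        y = np.array([0, 1, 2, 3])
        params = clf._init_params(2)
        _, grads = clf.loss_and_grads(xs, y, params)
        eps = 1e-6
        for key in params:
            flat = params[key].reshape(-1)
            for idx in range(0, flat.size, max(1, flat.size // 5)):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp, _ = clf.loss_and_grads(xs, y, params)
                flat[idx] = orig - eps
                lm, _ = clf.loss_and_grads(xs, y, params)
                flat[idx] = orig
                num = (lp - lm) / (2 * eps)
                ana = grads[key].reshape(-1)[idx]
                assert ana == pytest.approx(num, rel=1e-4, abs=1e-7), key

    def test_learns_separable_sequences(self):
        rng = np.random.default_rng(2)
        x, y = [], []
        for c in range(4):
            mean = np.zeros(3)
            mean[c % 3] = (1 if c < 3 else -1) * 2.0
            x.append(mean + 0.1 * rng.standard_normal((8, 20, 3)))
            y.extend([c] * 8)
        x = np.concatenate(x)
        clf = BiLSTMClassifier(epochs=80, seed=0).fit(x, np.array(y))
        assert np.mean(clf.predict(x) == y) == 1.0


class TestFitSegmentClassifier:
    def test_perfect_accuracy_on_noise_free_separable_segments(self):
        rng = np.random.default_rng(3)
        segments = {}
        for i, o in enumerate(OBJECTS):
            point = np.zeros(3)
            point[i % 3] = 1.0 if i < 3 else -1.0
            segments[o] = np.tile(point, (10, 30, 1))
        for spec in (FAST_LSTM, LOGISTIC):
            accs = fit_segment_classifier(segments, spec, seed=rng)
            assert np.all(accs == 1.0), spec.classifier

    def test_shuffled_labels_give_chance_accuracy(self):
        rng = np.random.default_rng(4)
        segments = gaussian_segments(rng, n_per_class=24, sep=3.0)
        pooled = np.concatenate([segments[o] for o in OBJECTS])
        perm = rng.permutation(len(pooled))
        shuffled = {o: pooled[perm[24 * i: 24 * (i + 1)]]
                    for i, o in enumerate(OBJECTS)}
        accs = fit_segment_classifier(shuffled, LOGISTIC, seed=5)
        # permutation null for 4 balanced classes
        n_test = 24 - round(0.4 * 24)
        sd = np.sqrt(0.25 * 0.75 / (4 * n_test)) / np.sqrt(len(accs))
        assert abs(accs.mean() - 0.25) < 4 * sd + 0.02

    def test_class_relabeling_equivariance(self):
        rng = np.random.default_rng(6)
        segments = gaussian_segments(rng, n_per_class=10, sep=2.0)
        a = fit_segment_classifier(segments, LOGISTIC, seed=7)
        rolled = {OBJECTS[(i + 1) % 4]: segments[OBJECTS[i]] for i in range(4)}
        b = fit_segment_classifier(rolled, LOGISTIC, seed=7)
        assert abs(a.mean() - b.mean()) < 0.1

    def test_duplicated_trials_do_not_leak(self):
        # identity-level splitting: duplicating every trial (same trial id)
        # must not let copies of one trial appear on both sides of the
        # split, so accuracy on class-uninformative segments stays at chance
        from instaspace.trajectory import SegmentSet
        rng = np.random.default_rng(8)
        segments = gaussian_segments(rng, n_per_class=10, sep=0.0)
        doubled = SegmentSet(
            event="H",
            segments={o: np.concatenate([s, s]) for o, s in segments.items()},
            aggregation="single_trial",
            source_trials={o: [f"{o}-{k}" for k in range(10)] * 2
                           for o in OBJECTS},
            start_index=0)
        accs = fit_segment_classifier(doubled, LOGISTIC, seed=9)
        assert abs(accs.mean() - 0.25) < 0.12

    def test_too_few_trials_rejected(self):
        rng = np.random.default_rng(0)
        segments = gaussian_segments(rng, n_per_class=1)
        with pytest.raises(ParameterError):
            fit_segment_classifier(segments, LOGISTIC, seed=0)


class TestChanceBand:
    def test_band_centers_at_chance_for_uninformative_segments(self):
        rng = np.random.default_rng(10)
        segments = {o: rng.standard_normal((12, 20, 8)) for o in OBJECTS}
        mean, sd = chance_accuracy_band(segments, n_random=40,
                                        spec=LOGISTIC, seed=11)
        assert abs(mean - 0.25) < 3 * sd + 0.03

    def test_band_mean_above_chance_for_informative_segments(self):
        rng = np.random.default_rng(12)
        high_d = {}
        for i, o in enumerate(OBJECTS):
            mean = np.zeros(8)
            mean[i] = 4.0
            high_d[o] = mean + 0.3 * rng.standard_normal((12, 20, 8))
        mean, _ = chance_accuracy_band(high_d, n_random=40, spec=LOGISTIC,
                                       seed=13)
        assert mean > 0.3

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(14)
        segments = {o: rng.standard_normal((10, 20, 6)) for o in OBJECTS}
        a = chance_accuracy_band(segments, n_random=15, spec=LOGISTIC, seed=3)
        b = chance_accuracy_band(segments, n_random=15, spec=LOGISTIC, seed=3)
        assert a == b

    def test_reduced_cost_mode_matches_full_band(self):
        rng = np.random.default_rng(15)
        segments = {o: rng.standard_normal((14, 20, 10)) for o in OBJECTS}
        full_mean, full_sd = chance_accuracy_band(
            segments, n_random=400, spec=LOGISTIC, seed=16)
        red_mean, _ = chance_accuracy_band(
            segments, n_random=50,
            spec=DecoderSpec(classifier="logistic", n_repeats=5), seed=17)
        assert abs(red_mean - full_mean) <= 2 * full_sd


class TestAccuracyTimecourse:
    def test_sweep_marks_degenerate_steps_missing(self):
        rng = np.random.default_rng(18)
        t_len = 160
        rates = {}
        for i, o in enumerate(OBJECTS):
            base = 0.2 + 0.02 * rng.random((8, 6, t_len))
            signal = np.zeros((8, 6, t_len))
            signal[i, :, 80:] = 0.5      # object signal only after sample 80
            rates[o] = base + signal
        tensor = make_tensor(rates, {"I": 10, "G": 40, "M": 90, "H": 130})
        # make the first step exactly degenerate
        for o in OBJECTS:
            rates[o][:, :, 0] = 0.3
        series = instantaneous_subspace_series(
            tensor, times=np.arange(0, t_len - 30, 10))
        from instaspace.trajectory import clip_segments
        segs = clip_segments(tensor, "I", "single_trial", start_offset=-10)
        acc = accuracy_timecourse(
            segs, series, step_ms=40,
            spec=DecoderSpec(classifier="logistic", n_repeats=4), seed=19)
        assert np.isnan(acc.repeat_accuracies[0]).all()
        assert np.isfinite(acc.repeat_accuracies[1:]).all()

    def test_accuracy_tracks_subspace_alignment(self):
        # the object code moves between unit groups over the trial: the
        # same late segment decodes near-perfectly in the late subspace but
        # poorly in subspaces from times when other units carried the code
        rng = np.random.default_rng(20)
        t_len, n, k = 200, 20, 14
        early_ramp = np.clip((100 - np.arange(t_len)) / 50.0, 0.0, 1.0)
        late_ramp = np.clip((np.arange(t_len) - 100) / 50.0, 0.0, 1.0)
        rates = {}
        for i, o in enumerate(OBJECTS):
            base = 2.0 + 0.3 * rng.standard_normal((n, k, t_len))
            sig = np.zeros((n, t_len))
            sig[10 + i] = early_ramp        # early code: units 10-13
            sig[i] = late_ramp              # late code: units 0-3
            rates[o] = np.clip(base + sig[:, None, :], 0.0, None)
        tensor = make_tensor(rates, {"I": 20, "G": 80, "M": 140, "H": 160})
        series = instantaneous_subspace_series(tensor)
        from instaspace.trajectory import clip_segments
        segs = clip_segments(tensor, "H", "single_trial", start_offset=-60)
        acc = accuracy_timecourse(segs, series, step_ms=50,
                                  spec=DecoderSpec(classifier="logistic",
                                                   n_repeats=6), seed=21)
        early = acc.mean[acc.times <= 50]
        late = acc.mean[acc.times >= 150]
        assert late.mean() > early.mean() + 0.3
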