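"""Decoding object identity from projected trajectory segments.

A 4-class sequence classifier (bidirectional LSTM, 3 inputs, 20 hidden
units, softmax over the four objects; or a multinomial-logistic baseline on
flattened segments for fast runs) is swept along the time series of
instantaneous subspaces at 50-ms steps.  At each step the single-trial
100-ms segments are projected into that step's 3-D subspace, classes are
balanced to the smallest per-object trial count, 40% of distinct trials
train the classifier and the held-out 60% are decoded; ten repeated splits
give mean +/- SD accuracy.  A chance band is obtained by projecting the
same segments into randomly drawn 3-D subspaces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

from ._lstm import BiLSTMClassifier
from .session import OBJECTS
from .subspace import SubspaceSeries
from .trajectory import SegmentSet

logger = logging.getLogger(__name__)


class ParameterError(ValueError):
    pass


@dataclass
class DecoderSpec:
    """Classifier architecture and evaluation protocol.

    ``classifier`` selects the reference bidirectional LSTM (``"bilstm"``)
    or the fast multinomial-logistic baseline (``"logistic"``).  The LSTM
    training schedule (epochs, learning rate, full batch) is configurable;
    the split protocol (balance to the minimum object count, 40/60
    train/test, 10 repeats) is shared by both classifiers.
    """

    classifier: str = "bilstm"
    n_hidden: int = 20
    n_classes: int = 4
    epochs: int = 150
    learning_rate: float = 0.01
    train_fraction: float = 0.4
    n_repeats: int = 10
    logistic_c: float = 1.0

    def make(self, seed: int | np.random.Generator):
        if self.classifier == "bilstm":
            return BiLSTMClassifier(n_hidden=self.n_hidden,
                                    n_classes=self.n_classes,
                                    epochs=self.epochs,
                                    learning_rate=self.learning_rate,
                                    seed=seed)
        if self.classifier == "logistic":
            return _LogisticSegmentClassifier(c=self.logistic_c)
        raise ParameterError(f"unknown classifier {self.classifier!r}")


class _LogisticSegmentClassifier:
    """Multinomial logistic regression on flattened, standardized segments."""

    def __init__(self, c: float = 1.0):
        self.scaler = StandardScaler()
        self.model = LogisticRegression(C=c, max_iter=2000)

    def fit(self, x: np.ndarray, y: np.ndarray):
        flat = np.asarray(x, float).reshape(len(x), -1)
        self.model.fit(self.scaler.fit_transform(flat), y)
        return self

    def predict(self, x: np.ndarray) -> np.ndarray:
        flat = np.asarray(x, float).reshape(len(x), -1)
        return self.model.predict(self.scaler.transform(flat))


def _segments_as_arrays(segments: SegmentSet | dict) -> dict[str, np.ndarray]:
    if isinstance(segments, SegmentSet):
        if segments.aggregation != "single_trial":
            raise ParameterError("decoding requires single-trial segments")
        return segments.segments
    return segments


def _balanced_split(identities: dict[str, np.ndarray], train_fraction: float,
                    rng: np.random.Generator):
    """Identity-level 40/60 split, then with-replacement class balancing.

    Distinct trial identities are assigned to train or test first, so no
    trial (or resampled copy of it) can appear on both sides; each side is
    then resampled with replacement to the same per-class count derived
    from the smallest object count.
    """
    n_min = min(len(np.unique(ids)) for ids in identities.values())
    n_train = max(1, int(round(train_fraction * n_min)))
    n_test = max(1, n_min - n_train)
    train_idx, test_idx = {}, {}
    for o, ids in identities.items():
        uniq = np.unique(ids)
        if len(uniq) < 2:
            raise ParameterError(f"object {o!r} has fewer than 2 distinct trials")
        perm = rng.permutation(uniq)
        cut = max(1, min(len(uniq) - 1, int(round(train_fraction * len(uniq)))))
        train_pool = np.flatnonzero(np.isin(ids, perm[:cut]))
        test_pool = np.flatnonzero(np.isin(ids, perm[cut:]))
        train_idx[o] = rng.choice(train_pool, size=n_train, replace=True)
        test_idx[o] = rng.choice(test_pool, size=n_test, replace=True)
    return train_idx, test_idx


def fit_segment_classifier(segments: SegmentSet | dict[str, np.ndarray],
                           spec: DecoderSpec,
                           seed: int | np.random.Generator = 0) -> np.ndarray:
    """Repeated-split classification accuracy on projected segments.

    ``segments`` maps object -> (K, 100, d) single-trial arrays.  When a
    :class:`SegmentSet` is given, its source trial ids define the trial
    identities for the leak-free split (duplicate source trials share an
    identity); plain arrays treat each row as its own identity.  Returns
    the per-repeat accuracies (fraction of held-out trials decoded
    correctly), length ``spec.n_repeats``.
    """
    arrays = _segments_as_arrays(segments)
    for o in OBJECTS:
        if o not in arrays:
            raise ParameterError(f"missing object {o!r}")
    if isinstance(segments, SegmentSet):
        identities = {o: np.asarray(segments.source_trials[o])
                      for o in OBJECTS}
    else:
        identities = {o: np.arange(arrays[o].shape[0]) for o in OBJECTS}
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = {o: i for i, o in enumerate(OBJECTS)}
    accs = np.empty(spec.n_repeats)
    for rep in range(spec.n_repeats):
        train_idx, test_idx = _balanced_split(identities, spec.train_fraction, rng)
        x_tr = np.concatenate([arrays[o][train_idx[o]] for o in OBJECTS])
        y_tr = np.concatenate([np.full(len(train_idx[o]), labels[o]) for o in OBJECTS])
        x_te = np.concatenate([arrays[o][test_idx[o]] for o in OBJECTS])
        y_te = np.concatenate([np.full(len(test_idx[o]), labels[o]) for o in OBJECTS])
        clf = spec.make(rng)
        clf.fit(x_tr, y_tr)
        accs[rep] = float(np.mean(clf.predict(x_te) == y_te))
    return accs


@dataclass
class AccuracySeries:
    """Decoding accuracy of one segment event across subspace times."""

    event: str
    times: np.ndarray                  # subspace sample indices (1-ms units)
    repeat_accuracies: np.ndarray      # (n_times, n_repeats), NaN where degenerate
    chance_mean: float | None = None
    chance_sd: float | None = None
    clip_window: tuple[int, int] | None = None

    @property
    def mean(self) -> np.ndarray:
        return np.nanmean(self.repeat_accuracies, axis=1)

    @property
    def sd(self) -> np.ndarray:
        return np.nanstd(self.repeat_accuracies, axis=1, ddof=1)


def accuracy_timecourse(segments: SegmentSet | dict[str, np.ndarray],
                        series: SubspaceSeries,
                        step_ms: int = 50,
                        spec: DecoderSpec | None = None,
                        seed: int | np.random.Generator = 0,
                        event: str = "",
                        clip_window: tuple[int, int] | None = None,
                        ) -> AccuracySeries:
    """Sweep the classifier over the subspace series at 50-ms steps.

    An independent classifier is trained at every selected step on the
    single-trial segments projected into that step's instantaneous
    subspace.  Degenerate steps are reported as NaN.
    """
    spec = spec or DecoderSpec()
    arrays = _segments_as_arrays(segments)
    if isinstance(segments, SegmentSet):
        event = event or segments.event
        clip_window = clip_window or (segments.start_index,
                                      segments.start_index + 100)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    targets = np.arange(series.times[0], series.times[-1] + 1, max(1, step_ms))
    sel = np.unique(np.searchsorted(series.times, targets))
    sel = sel[sel < len(series.times)]
    times = series.times[sel]
    out = np.full((len(sel), spec.n_repeats), np.nan)
    for row, pos in enumerate(sel):
        if series.degenerate[pos]:
            logger.info("degenerate subspace at sample %d; accuracy missing",
                        series.times[pos])
            continue
        w = series.bases[pos]
        projected = {o: arrays[o] @ w for o in OBJECTS}
        if isinstance(segments, SegmentSet):
            projected = SegmentSet(segments.event, projected, "single_trial",
                                   segments.source_trials,
                                   segments.start_index)
        out[row] = fit_segment_classifier(projected, spec, rng)
    return AccuracySeries(event=event, times=times, repeat_accuracies=out,
                          clip_window=clip_window)


def chance_accuracy_band(segments: SegmentSet | dict[str, np.ndarray],
                         n_random: int = 500,
                         spec: DecoderSpec | None = None,
                         seed: int | np.random.Generator = 0,
                         ) -> tuple[float, float]:
    """Accuracy distribution over random 3-D projections (mean, SD).

    Each draw projects the high-D single-trial segments into an
    independently drawn random orthonormal N x 3 basis and runs one full
    train/evaluate split.  The reference lines for accuracy plots are the
    mean and mean + 3 SD of this distribution.
    """
    spec = spec or DecoderSpec()
    arrays = _segments_as_arrays(segments)
    n = arrays[OBJECTS[0]].shape[2]
    if n < 3:
        raise ParameterError("ambient dimension must be >= 3")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    one_shot = DecoderSpec(**{**spec.__dict__, "n_repeats": 1})
    accs = np.empty(n_random)
    for d in range(n_random):
        q, _ = np.linalg.qr(rng.standard_normal((n, 3)))
        projected = {o: arrays[o] @ q for o in OBJECTS}
        if isinstance(segments, SegmentSet):
            projected = SegmentSet(segments.event, projected, "single_trial",
                                   segments.source_trials,
                                   segments.start_index)
        accs[d] = fit_segment_classifier(projected, one_shot, rng)[0]
    return float(accs.mean()), float(accs.std(ddof=1))
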