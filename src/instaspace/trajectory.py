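"""Trajectory segments and cumulative separation.

100-ms segments of population activity are clipped starting at each of the
four behavioral events (I, G, M, H) and projected into instantaneous 3-D
subspaces, L = X W.  Separation of the four object trajectories inside a
subspace is summarized by the cumulative separation

    CS = (1/T) * sum_t sum_{i<j} d_ij(t),     T = 100,

the time-normalized sum of the six pairwise Euclidean distances among the
four projected segments.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .preprocess import RateTensor
from .session import OBJECTS
from .subspace import SubspaceSeries

SEGMENT_LEN = 100
EVENTS = ("I", "G", "M", "H")


class ParameterError(ValueError):
    pass


@dataclass
class SegmentSet:
    """100-sample trajectory segments per object, high-D or 3-D.

    ``segments[obj]`` is (100, D) for trial-averaged segments or
    (K, 100, D) for single-trial ones.
    """

    event: str
    segments: dict[str, np.ndarray]
    aggregation: str                    # "trial_averaged" | "single_trial"
    source_trials: dict[str, list[str]]
    start_index: int

    @property
    def n_dims(self) -> int:
        return next(iter(self.segments.values())).shape[-1]


def clip_segments(tensor: RateTensor, event: str,
                  aggregation: str = "trial_averaged",
                  trial_subset: dict[str, np.ndarray] | str = "all",
                  start_offset: int = 0) -> SegmentSet:
    """Clip the 100 consecutive 1-ms samples starting at an event.

    ``start_offset`` shifts the clip start relative to the event sample (in
    ms); the event sample itself is included when the offset is zero.
    """
    if event not in tensor.event_index:
        raise ParameterError(f"unknown event {event!r}")
    if aggregation not in ("trial_averaged", "single_trial"):
        raise ParameterError(f"unknown aggregation {aggregation!r}")
    start = tensor.event_index[event] + start_offset
    stop = start + SEGMENT_LEN
    if start < 0 or stop > tensor.n_timepoints:
        raise ParameterError(
            f"segment [{start}, {stop}) crosses the tensor's time axis "
            f"(T = {tensor.n_timepoints})")
    segments: dict[str, np.ndarray] = {}
    sources: dict[str, list[str]] = {}
    for o in OBJECTS:
        r = tensor.rates[o]
        ids = tensor.trial_ids[o]
        if trial_subset != "all":
            idx = np.asarray(trial_subset[o], int)
            r = r[:, idx, :]
            ids = [ids[i] for i in idx]
        clip = r[:, :, start:stop]                     # (N, K, 100)
        if aggregation == "trial_averaged":
            segments[o] = clip.mean(axis=1).T          # (100, N)
        else:
            segments[o] = clip.transpose(1, 2, 0)      # (K, 100, N)
        sources[o] = list(ids)
    return SegmentSet(event=event, segments=segments, aggregation=aggregation,
                      source_trials=sources, start_index=start)


def project_segments(segments: SegmentSet, basis: np.ndarray) -> SegmentSet:
    """Project high-D segments into a 3-D basis: L = X W."""
    basis = np.asarray(basis, float)
    if basis.ndim != 2 or basis.shape[0] != segments.n_dims:
        raise ParameterError(
            f"basis shape {basis.shape} incompatible with {segments.n_dims}-D segments")
    projected = {o: x @ basis for o, x in segments.segments.items()}
    return SegmentSet(event=segments.event, segments=projected,
                      aggregation=segments.aggregation,
                      source_trials=segments.source_trials,
                      start_index=segments.start_index)


def cumulative_separation(segments: SegmentSet) -> float:
    """Time-normalized sum of the six pairwise distances (trial-averaged)."""
    if segments.aggregation != "trial_averaged":
        raise ParameterError("cumulative separation is defined on trial-averaged segments")
    missing = [o for o in OBJECTS if o not in segments.segments]
    if missing:
        raise ParameterError(f"missing objects {missing}")
    mats = [np.asarray(segments.segments[o], float) for o in OBJECTS]
    n_rows = {m.shape[0] for m in mats}
    if len(n_rows) != 1:
        raise ParameterError("segments have mismatched row counts")
    t = n_rows.pop()
    total = 0.0
    for a, b in combinations(range(4), 2):
        total += float(np.linalg.norm(mats[a] - mats[b], axis=1).sum())
    return total / t


def separation_matrix(tensor: RateTensor, series: SubspaceSeries,
                      trial_subset: dict[str, np.ndarray] | str = "all",
                      ) -> np.ndarray:
    """4 x 4 cumulative separation: rows = segment event, cols = subspace event.

    Entry [a, b] projects the trial-averaged segments clipped at event a
    into the instantaneous subspace at event b.
    """
    out = np.empty((4, 4))
    for i, seg_event in enumerate(EVENTS):
        segs = clip_segments(tensor, seg_event, "trial_averaged", trial_subset)
        for j, sub_event in enumerate(EVENTS):
            w = series.basis_at_event(sub_event)
            out[i, j] = cumulative_separation(project_segments(segs, w))
    return out
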