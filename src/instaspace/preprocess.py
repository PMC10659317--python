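"""Event-aligned rate tensors and MN/AE/AO/NS unit classification.

Spike times are binned at 1 ms, smoothed with a Gaussian kernel
(sigma = 50 ms, truncated at +/-4 sigma and edge-renormalized) and
square-root transformed to stabilize Poisson variance.  Each trial is then
time-aligned to four behavioral events and truncated using median epoch
durations, producing per-object N x K x T tensors on a shared time axis:

* I — instruction onset, 500 ms before to 500 ms after;
* G — go cue, median delay before to half the median reaction time after;
* M — movement onset, half the median reaction time before to 200 ms after;
* H — start of the final hold, 200 ms before to 200 ms after.

Smoothing is applied to the full trial *before* snippets are cut, so
snippet boundaries carry no smoothing edge artifacts.

Unit classes are assigned from a two-way fixed-effects ANOVA (object x
period, with interaction, Type II sums of squares) on spike counts in
eleven 200-ms windows, separately per behavioral context.  A unit is
task-related in a context if any of the three effects has p below alpha
(default 0.05/6 = 0.0083, correcting for the six tests each unit gets
across the two contexts); mirror neurons (MN) are related in both contexts,
AE in execution only, AO in observation only, NS in neither.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats

from .session import CONTEXTS, OBJECTS, SessionDataset, TrialRecord

logger = logging.getLogger(__name__)

BIN_S = 1e-3
SMOOTH_SIGMA_S = 0.050
KERNEL_HALF_WIDTH_SIGMAS = 4
#: Bonferroni-corrected significance level: 0.05 / 6 tests per unit
DEFAULT_ALPHA = 0.05 / 6

ANCHOR_EVENTS = {"I": "instruction_on", "G": "go", "M": "movement_on", "H": "hold_on"}


class ParameterError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Binning and smoothing
# ---------------------------------------------------------------------------

def gaussian_kernel_1ms(sigma_s: float = SMOOTH_SIGMA_S) -> np.ndarray:
    """Unit-mass Gaussian kernel on the 1-ms grid, truncated at 4 sigma."""
    half = int(round(KERNEL_HALF_WIDTH_SIGMAS * sigma_s / BIN_S))
    x = np.arange(-half, half + 1) * BIN_S
    k = np.exp(-0.5 * (x / sigma_s) ** 2)
    return k / k.sum()


def bin_spikes(spike_times: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    """Half-open 1-ms binning: a spike at a bin edge belongs to the later bin."""
    t0, t1 = window
    if t1 <= t0:
        raise ParameterError("window end must exceed window start")
    n_bins = int(round((t1 - t0) / BIN_S))
    spike_times = np.asarray(spike_times, float)
    idx = np.floor((spike_times - t0) / BIN_S).astype(int)
    ok = (idx >= 0) & (idx < n_bins)
    return np.bincount(idx[ok], minlength=n_bins).astype(float)


def smooth_counts(counts: np.ndarray, sigma_s: float = SMOOTH_SIGMA_S) -> np.ndarray:
    """Gaussian smoothing along the last axis with edge renormalization.

    The trace stays in units of expected spikes per 1-ms bin; away from the
    edges it integrates to the spike count.
    """
    kernel = gaussian_kernel_1ms(sigma_s)
    counts = np.asarray(counts, float)
    shape1 = (1,) * (counts.ndim - 1) + (-1,)
    sm = signal.fftconvolve(counts, kernel.reshape(shape1), mode="same", axes=-1)
    norm = signal.fftconvolve(np.ones(counts.shape[-1]), kernel, mode="same")
    sm /= norm.reshape(shape1)
    return np.clip(sm, 0.0, None)


def bin_smooth_sqrt(spike_times: np.ndarray, window: tuple[float, float],
                    sigma_s: float = SMOOTH_SIGMA_S, sqrt: bool = True) -> np.ndarray:
    """Bin at 1 ms, smooth, and (by default) square-root transform."""
    sm = smooth_counts(bin_spikes(spike_times, window), sigma_s)
    return np.sqrt(sm) if sqrt else sm


# ---------------------------------------------------------------------------
# Alignment and concatenation
# ---------------------------------------------------------------------------

@dataclass
class AlignmentWindows:
    """Median epoch durations (seconds).

    ``per_object`` holds the medians of each object's successful trials;
    ``pooled`` (all successful trials of the context) defines the common
    snippet windows so that all four objects share one time axis.
    """

    per_object: dict[str, dict[str, float]]
    pooled: dict[str, float]


@dataclass
class RateTensor:
    """Per-object event-aligned population tensors on a common time axis.

    ``rates[obj]`` is (N, K_obj, T) of sqrt-transformed smoothed rates;
    ``event_index`` gives the sample index of I, G, M, H on the
    concatenated axis; ``snippet_bounds`` are the [start, end) indices of
    the four snippets.
    """

    rates: dict[str, np.ndarray]
    event_index: dict[str, int]
    snippet_bounds: dict[str, tuple[int, int]]
    unit_ids: list[str]
    trial_ids: dict[str, list[str]]
    context: str
    windows: AlignmentWindows

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    @property
    def n_timepoints(self) -> int:
        return next(iter(self.rates.values())).shape[2]

    def trial_counts(self) -> dict[str, int]:
        return {o: r.shape[1] for o, r in self.rates.items()}

    def condition_means(self, trial_subset: dict[str, np.ndarray] | None = None
                        ) -> np.ndarray:
        """(4, N, T) per-object trial means (object order as in OBJECTS)."""
        means = []
        for o in OBJECTS:
            r = self.rates[o]
            if trial_subset is not None:
                r = r[:, np.asarray(trial_subset[o], int), :]
            means.append(r.mean(axis=1))
        return np.stack(means)

    def subset_units(self, indices: np.ndarray | list[int]) -> "RateTensor":
        idx = np.asarray(indices, int)
        return RateTensor(
            rates={o: r[idx] for o, r in self.rates.items()},
            event_index=dict(self.event_index),
            snippet_bounds=dict(self.snippet_bounds),
            unit_ids=[self.unit_ids[i] for i in idx],
            trial_ids={o: list(v) for o, v in self.trial_ids.items()},
            context=self.context,
            windows=self.windows,
        )


def _median_durations(trials: list[TrialRecord]) -> dict[str, float]:
    return {
        "delay": float(np.median([t.duration("instruction_off", "go") for t in trials])),
        "reaction": float(np.median([t.duration("go", "movement_on") for t in trials])),
        "movement": float(np.median([t.duration("movement_on", "hold_on") for t in trials])),
    }


def align_and_concatenate(session: SessionDataset, context: str,
                          sigma_s: float = SMOOTH_SIGMA_S) -> RateTensor:
    """Build the per-object N x K x T tensor for one context."""
    if context not in CONTEXTS:
        raise ParameterError(f"unknown context {context!r}")
    by_object = {o: session.trials_for(context, o) for o in OBJECTS}
    for o, trs in by_object.items():
        if not trs:
            raise ParameterError(
                f"object {o!r} has no successful {context} trials")
    all_trials = [t for trs in by_object.values() for t in trs]
    pooled = _median_durations(all_trials)
    windows = AlignmentWindows(
        per_object={o: _median_durations(trs) for o, trs in by_object.items()},
        pooled=pooled,
    )
    md = int(round(pooled["delay"] / BIN_S))            # median delay, ms
    hr = int(round(0.5 * pooled["reaction"] / BIN_S))   # half median reaction, ms
    # snippet extents (samples before / after each event)
    extents = {"I": (500, 500), "G": (md, hr), "M": (hr, 200), "H": (200, 200)}
    snippet_bounds: dict[str, tuple[int, int]] = {}
    event_index: dict[str, int] = {}
    pos = 0
    for ev, (before, after) in extents.items():
        snippet_bounds[ev] = (pos, pos + before + after)
        event_index[ev] = pos + before
        pos += before + after
    T = pos

    n = session.n_units
    unit_ids = session.unit_ids
    rates: dict[str, np.ndarray] = {}
    kept_ids: dict[str, list[str]] = {}
    for o, trs in by_object.items():
        rows = []
        ids = []
        for tr in trs:
            t0, t1 = tr.events["start"], tr.events["end"]
            n_bins = int(round((t1 - t0) / BIN_S))
            ev_bin = {ev: int(round((tr.events[ANCHOR_EVENTS[ev]] - t0) / BIN_S))
                      for ev in extents}
            if any(ev_bin[ev] - b < 0 or ev_bin[ev] + a > n_bins
                   for ev, (b, a) in extents.items()):
                logger.warning("trial %s shorter than its alignment windows; excluded",
                               tr.trial_id)
                continue
            counts = np.stack([
                bin_spikes(session.spikes_for(uid, tr.trial_id), (t0, t1))
                for uid in unit_ids])
            sm = smooth_counts(counts, sigma_s)
            snips = [sm[:, ev_bin[ev] - b: ev_bin[ev] + a]
                     for ev, (b, a) in extents.items()]
            rows.append(np.sqrt(np.concatenate(snips, axis=1)))
            ids.append(tr.trial_id)
        if not rows:
            raise ParameterError(
                f"object {o!r}: every {context} trial was excluded by alignment")
        rates[o] = np.stack(rows, axis=1)  # (N, K, T)
        kept_ids[o] = ids
        assert rates[o].shape == (n, len(rows), T)
    return RateTensor(rates=rates, event_index=event_index,
                      snippet_bounds=snippet_bounds, unit_ids=unit_ids,
                      trial_ids=kept_ids, context=context, windows=windows)


# ---------------------------------------------------------------------------
# Unit classification
# ---------------------------------------------------------------------------

#: the eleven 200-ms count windows: (anchor event, offset of window start in s)
CLASSIFY_WINDOWS: list[tuple[str, float]] = [
    ("instruction_on", -0.2), ("instruction_on", 0.0),
    ("instruction_off", -0.2), ("instruction_off", 0.0),
    ("go", -0.2), ("go", 0.0),
    ("movement_on", -0.2), ("movement_on", 0.0),
    ("hold_on", -0.2), ("hold_on", 0.0),
    ("hold_off", -0.2),
]


@dataclass
class UnitClassification:
    """Per-unit class labels and the per-context ANOVA p-values."""

    classes: dict[str, str]
    pvalues: pd.DataFrame   # unit_id, context, p_object, p_period, p_interaction
    alpha: float
    notes: dict[str, str]

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"unit_id": list(self.classes),
                           "unit_class": list(self.classes.values())})
        wide = self.pvalues.pivot(index="unit_id", columns="context")
        wide.columns = [f"{a}_{b}" for a, b in wide.columns]
        return df.merge(wide.reset_index(), on="unit_id", how="left")


def _dummies(levels: np.ndarray) -> np.ndarray:
    """Treatment-coded dummy columns (first level dropped)."""
    uniq = np.unique(levels)
    return np.column_stack([(levels == u).astype(float) for u in uniq[1:]])


def _rss(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Residual sum of squares of Y (n_obs, n_units) under OLS on X."""
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    res = y - x @ beta
    return np.sum(res * res, axis=0)


def two_way_anova_counts(counts: np.ndarray, objects: np.ndarray,
                         periods: np.ndarray) -> pd.DataFrame:
    """Batched two-way fixed-effects ANOVA with interaction (Type II SS).

    ``counts`` is (n_obs, n_units); ``objects`` and ``periods`` are the
    factor levels per observation.  Returns one row per unit with p-values
    for the object and period main effects and their interaction.  Type II
    sums of squares are computed by model comparison, which handles
    unbalanced trial counts.
    """
    counts = np.asarray(counts, float)
    n_obs, n_units = counts.shape
    ones = np.ones((n_obs, 1))
    d_obj = _dummies(objects)
    d_per = _dummies(periods)
    inter = (d_obj[:, :, None] * d_per[:, None, :]).reshape(n_obs, -1)
    x_full = np.hstack([ones, d_obj, d_per, inter])
    x_add = np.hstack([ones, d_obj, d_per])
    x_obj = np.hstack([ones, d_obj])
    x_per = np.hstack([ones, d_per])

    df_obj = d_obj.shape[1]
    df_per = d_per.shape[1]
    df_int = inter.shape[1]
    rank_full = np.linalg.matrix_rank(x_full)
    df_err = n_obs - rank_full
    if df_err <= 0:
        raise ParameterError("not enough observations for the two-way ANOVA")

    rss_full = _rss(x_full, counts)
    rss_add = _rss(x_add, counts)
    ss = {
        "object": (_rss(x_per, counts) - rss_add, df_obj),
        "period": (_rss(x_obj, counts) - rss_add, df_per),
        "interaction": (rss_add - rss_full, df_int),
    }
    mse = rss_full / df_err
    out = {}
    with np.errstate(divide="ignore", invalid="ignore"):
        for name, (s, df) in ss.items():
            f = (np.clip(s, 0.0, None) / df) / mse
            out[f"p_{name}"] = stats.f.sf(f, df, df_err)
    return pd.DataFrame(out)


def _classify_context(session: SessionDataset, context: str) -> pd.DataFrame | None:
    trials = session.trials_for(context)
    if not trials:
        return None
    for o in OBJECTS:
        if len([t for t in trials if t.object == o]) < 2:
            raise ParameterError(
                f"context {context!r}: need >= 2 successful trials of {o!r}")
    rows = []
    objects, periods = [], []
    for tr in trials:
        missing = [ev for ev, _ in CLASSIFY_WINDOWS if ev not in tr.events]
        if missing:
            logger.warning("trial %s missing events %s; skipped", tr.trial_id, missing)
            continue
        bounds = np.array([(tr.events[ev] + off, tr.events[ev] + off + 0.2)
                           for ev, off in CLASSIFY_WINDOWS]).ravel()
        per_unit = []
        for uid in session.unit_ids:
            s = session.spikes_for(uid, tr.trial_id)
            edges = np.searchsorted(s, bounds)
            per_unit.append(edges[1::2] - edges[0::2])
        counts = np.asarray(per_unit)  # (n_units, 11)
        for w in range(len(CLASSIFY_WINDOWS)):
            rows.append(counts[:, w])
            objects.append(tr.object)
            periods.append(w)
    y = np.asarray(rows, float)
    res = two_way_anova_counts(y, np.asarray(objects), np.asarray(periods, int))
    res.insert(0, "unit_id", session.unit_ids)
    res.insert(1, "context", context)
    return res


def classify_units(session: SessionDataset,
                   alpha: float = DEFAULT_ALPHA) -> UnitClassification:
    """Classify every unit as MN, AE, AO or NS.

    Spike counts in eleven 200-ms windows anchored to the behavioral events
    enter a two-way ANOVA (object x period) per context; any of the three
    effects below ``alpha`` makes the unit task-related in that context.
    """
    frames = []
    related: dict[str, dict[str, bool]] = {u: {} for u in session.unit_ids}
    notes: dict[str, str] = {}
    for context in CONTEXTS:
        res = _classify_context(session, context)
        if res is None:
            logger.info("no %s trials; all units treated as unrelated in it", context)
            for u in session.unit_ids:
                related[u][context] = False
            continue
        frames.append(res)
        p = res[["p_object", "p_period", "p_interaction"]].to_numpy()
        nan_rows = np.isnan(p).all(axis=1)
        for i, u in enumerate(res["unit_id"]):
            if nan_rows[i]:
                related[u][context] = False
                notes[u] = f"undefined p-values in {context} (no count variance); treated as unrelated"
            else:
                related[u][context] = bool(np.nanmin(p[i]) < alpha)
    classes = {}
    for u in session.unit_ids:
        e = related[u].get("execution", False)
        o = related[u].get("observation", False)
        classes[u] = "MN" if (e and o) else "AE" if e else "AO" if o else "NS"
    pvalues = (pd.concat(frames, ignore_index=True) if frames
               else pd.DataFrame(columns=["unit_id", "context", "p_object",
                                          "p_period", "p_interaction"]))
    return UnitClassification(classes=classes, pvalues=pvalues,
                              alpha=alpha, notes=notes)
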