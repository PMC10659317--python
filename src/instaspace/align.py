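"""Canonical-correlation alignment of latent trajectory segments.

Two sets of 3-D latent dynamics — the four object-averaged 100-ms segments
of a population, stacked into a 400 x 3 block and projected into that
population's own event-time subspace — are aligned by CCA: thin QR of each
column-centered block, SVD of ``Q_A^T Q_B = U S V^T``, and new manifold
directions ``M_A = R_A^{-1} U``, ``M_B = R_B^{-1} V``.  The diagonal of S
holds the three canonical correlation coefficients, sorted descending; they
quantify how similar the *relational* geometry of the four object
trajectories is, independent of the subspaces the two populations use.

Bootstrap resampling (20 trials per object with replacement, 500
iterations) yields coefficient distributions for comparisons across
contexts (execution vs observation), populations (mirror vs execution-only
units) and sessions; drawing two independent samples from the *same* source
measures within-group trial-to-trial consistency.  Distributions are
compared with Kruskal-Wallis omnibus tests and pairwise Tukey HSD.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import RateTensor
from .session import OBJECTS
from .subspace import instantaneous_subspace_series
from .trajectory import clip_segments, project_segments

SEGMENT_LEN = 100


class ParameterError(ValueError):
    pass


class RankDeficiencyError(np.linalg.LinAlgError):
    pass


@dataclass
class LatentSegmentBlock:
    """Column-centered 400 x 3 block of stacked object trajectory segments."""

    matrix: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, float)
        if m.ndim != 2:
            raise ParameterError("block must be a 2-D matrix")
        self.matrix = m - m.mean(axis=0, keepdims=True)


@dataclass
class CCAResult:
    coefficients: np.ndarray        # (3,), CC1 >= CC2 >= CC3
    m_a: np.ndarray                 # (3, 3) manifold directions for block A
    m_b: np.ndarray
    aligned_a: np.ndarray           # (400, 3)
    aligned_b: np.ndarray


def cca_align(l_a: LatentSegmentBlock | np.ndarray,
              l_b: LatentSegmentBlock | np.ndarray,
              max_condition: float = 1e10) -> CCAResult:
    """Align two latent blocks by QR + SVD canonical correlation."""
    a = l_a.matrix if isinstance(l_a, LatentSegmentBlock) else np.asarray(l_a, float)
    b = l_b.matrix if isinstance(l_b, LatentSegmentBlock) else np.asarray(l_b, float)
    if a.shape != b.shape:
        raise ParameterError(f"block shapes differ: {a.shape} vs {b.shape}")
    a = a - a.mean(axis=0, keepdims=True)
    b = b - b.mean(axis=0, keepdims=True)
    q_a, r_a = np.linalg.qr(a)
    q_b, r_b = np.linalg.qr(b)
    for name, r in (("A", r_a), ("B", r_b)):
        if np.linalg.cond(r) > max_condition:
            raise RankDeficiencyError(
                f"block {name} is rank deficient (condition number above "
                f"{max_condition:.0e}); consider adding noise regularization")
    u, s, vt = np.linalg.svd(q_a.T @ q_b)
    m_a = np.linalg.solve(r_a, u)
    m_b = np.linalg.solve(r_b, vt.T)
    return CCAResult(coefficients=s, m_a=m_a, m_b=m_b,
                     aligned_a=a @ m_a, aligned_b=b @ m_b)


# ---------------------------------------------------------------------------
# Bootstrap distributions
# ---------------------------------------------------------------------------

@dataclass
class CCASource:
    """One side of a CCA comparison: a population's tensor and an event.

    ``tensor`` should already be restricted to the population of interest
    (e.g. the mirror-neuron units of one context of one session).  The
    projection basis is this source's *own* all-trial instantaneous
    subspace at the event time, computed on first use.
    """

    tensor: RateTensor
    event: str
    label: str = ""
    min_trials_per_object: int = 10
    basis: np.ndarray | None = None

    def __post_init__(self) -> None:
        counts = self.tensor.trial_counts()
        for o in OBJECTS:
            if counts[o] < self.min_trials_per_object:
                raise ParameterError(
                    f"source {self.label or '?'}: object {o!r} has only "
                    f"{counts[o]} trials (< {self.min_trials_per_object}); "
                    f"excluded from CCA analyses")
        if self.basis is None:
            series = instantaneous_subspace_series(
                self.tensor, times=np.array([self.tensor.event_index[self.event]]))
            self.basis = series.basis_at(self.tensor.event_index[self.event])

    def sample_block(self, rng: np.random.Generator,
                     trials_per_object: int) -> LatentSegmentBlock:
        counts = self.tensor.trial_counts()
        subset = {o: rng.integers(0, counts[o], size=trials_per_object)
                  for o in OBJECTS}
        segs = clip_segments(self.tensor, self.event, "trial_averaged", subset)
        # condition-dependent part only: remove the across-object mean
        # trajectory (the condition-independent component) per time point
        ci = np.mean([segs.segments[o] for o in OBJECTS], axis=0)
        for o in OBJECTS:
            segs.segments[o] = segs.segments[o] - ci
        low = project_segments(segs, self.basis)
        stacked = np.concatenate([low.segments[o] for o in OBJECTS], axis=0)
        return LatentSegmentBlock(stacked, provenance={
            "label": self.label, "event": self.event, "context": self.tensor.context})


@dataclass
class BootstrapCCADistribution:
    """n_iter x 3 canonical coefficients from bootstrap resampling."""

    coefficients: np.ndarray
    comparison: str
    event: str

    def __post_init__(self) -> None:
        c = np.asarray(self.coefficients, float)
        self.coefficients = -np.sort(-c, axis=1)   # rows sorted descending

    @property
    def mean(self) -> np.ndarray:
        return self.coefficients.mean(axis=0)

    @property
    def sd(self) -> np.ndarray:
        return self.coefficients.std(axis=0, ddof=1)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "comparison": self.comparison, "event": self.event,
            "iteration": np.arange(len(self.coefficients)),
            "CC1": self.coefficients[:, 0], "CC2": self.coefficients[:, 1],
            "CC3": self.coefficients[:, 2]})


def bootstrap_cca(source_a: CCASource, source_b: CCASource, n_iter: int = 500,
                  trials_per_object: int = 20,
                  seed: int | np.random.Generator = 0) -> BootstrapCCADistribution:
    """Bootstrap CCA between two sources (populations/contexts/sessions)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if source_a.event != source_b.event:
        raise ParameterError("sources must use the same segment event")
    coeffs = np.empty((n_iter, 3))
    for i in range(n_iter):
        block_a = source_a.sample_block(rng, trials_per_object)
        block_b = source_b.sample_block(rng, trials_per_object)
        coeffs[i] = cca_align(block_a, block_b).coefficients
    label = f"{source_a.label or 'A'}/{source_b.label or 'B'}"
    return BootstrapCCADistribution(coeffs, comparison=label, event=source_a.event)


def within_group_cca(source: CCASource, n_iter: int = 500,
                     trials_per_object: int = 20,
                     seed: int | np.random.Generator = 0) -> BootstrapCCADistribution:
    """Within-group consistency: CCA between two independent samples of one
    source (overlapping resamples allowed)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    coeffs = np.empty((n_iter, 3))
    for i in range(n_iter):
        block_a = source.sample_block(rng, trials_per_object)
        block_b = source.sample_block(rng, trials_per_object)
        coeffs[i] = cca_align(block_a, block_b).coefficients
    label = f"{source.label or 'A'} (within)"
    return BootstrapCCADistribution(coeffs, comparison=label, event=source.event)


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

@dataclass
class GroupComparisonReport:
    coefficient: int
    groups: list[str]
    kruskal_p: float | None
    pairwise: pd.DataFrame
    degenerate: bool = False
    note: str = ""

    def summary(self) -> str:
        if self.degenerate:
            return f"CC{self.coefficient}: {self.note}"
        lines = [f"CC{self.coefficient} omnibus Kruskal-Wallis p = {self.kruskal_p:.3g}"]
        for row in self.pairwise.itertuples():
            lines.append(
                f"  {row.group_a} vs {row.group_b}: mean diff = "
                f"{row.mean_diff:+.3f}, Tukey p = {row.p_value:.3g}")
        return "\n".join(lines)


def compare_alignment_groups(distributions: list[BootstrapCCADistribution],
                             coefficient: int = 1) -> GroupComparisonReport:
    """Kruskal-Wallis omnibus test plus pairwise Tukey HSD on one CC.

    ``coefficient`` is 1, 2 or 3.  All groups must have the same number of
    bootstrap iterations.
    """
    if len(distributions) < 2:
        raise ParameterError("need at least two groups to compare")
    if coefficient not in (1, 2, 3):
        raise ParameterError("coefficient index must be 1, 2 or 3")
    n = {len(d.coefficients) for d in distributions}
    if len(n) != 1:
        raise ParameterError("groups must have equal n_iter")
    names = [d.comparison for d in distributions]
    samples = [d.coefficients[:, coefficient - 1] for d in distributions]
    if all(np.ptp(s) == 0 for s in samples) and len({s[0] for s in samples}) == 1:
        return GroupComparisonReport(
            coefficient=coefficient, groups=names, kruskal_p=None,
            pairwise=pd.DataFrame(columns=["group_a", "group_b", "mean_diff",
                                           "p_value"]),
            degenerate=True,
            note="all groups are identical constants; no variance to test")
    kw = stats.kruskal(*samples)
    hsd = stats.tukey_hsd(*samples)
    rows = []
    for i, j in combinations(range(len(samples)), 2):
        rows.append({"group_a": names[i], "group_b": names[j],
                     "mean_diff": float(samples[i].mean() - samples[j].mean()),
                     "p_value": float(hsd.pvalue[i, j])})
    return GroupComparisonReport(coefficient=coefficient, groups=names,
                                 kruskal_p=float(kw.pvalue),
                                 pairwise=pd.DataFrame(rows))
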