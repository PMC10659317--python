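"""Instantaneous condition-dependent subspaces and principal angles.

At every 1-ms step the four object-mean population vectors are centered on
their across-object mean (removing the condition-independent signal) and
decomposed with PCA.  Four centered points span at most three dimensions,
so the top three components capture all of their variance; the resulting
orthonormal N x 3 basis W_i acts as a filter projecting population activity
into the instantaneous condition-dependent subspace.

Principal angles between two such subspaces are the arccosines of the
singular values of ``W_a^T W_b``, sorted ascending; 0 deg means identical,
90 deg orthogonal.  Because a random pair of low-dimensional subspaces in a
modest ambient dimension is typically far from orthogonal, a Monte-Carlo
baseline of randomly drawn subspaces provides the chance reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import RateTensor
from .session import OBJECTS

ANCHORS = ("I", "G", "M", "H")


class ParameterError(ValueError):
    pass


class DegenerateSubspaceError(ValueError):
    """All four condition means coincide; no condition-dependent subspace."""


# ---------------------------------------------------------------------------
# Instantaneous subspace series
# ---------------------------------------------------------------------------

@dataclass
class SubspaceSeries:
    """Time series of instantaneous 3-D bases.

    ``bases`` is (T, N, 3) with orthonormal columns per step; ``means`` the
    (T, 4, N) condition means; ``eigenvalues`` the (T, 3) PCA variances of
    the four centered points; ``degenerate`` flags steps where the four
    means coincide (basis meaningless there).
    """

    times: np.ndarray          # sample indices on the tensor's axis
    bases: np.ndarray          # (T, N, 3)
    means: np.ndarray          # (T, 4, N)
    eigenvalues: np.ndarray    # (T, 3)
    degenerate: np.ndarray     # (T,) bool
    event_index: dict[str, int]

    @property
    def n_units(self) -> int:
        return self.bases.shape[1]

    def basis_at(self, time_index: int, allow_degenerate: bool = False) -> np.ndarray:
        pos = int(np.searchsorted(self.times, time_index))
        if pos >= len(self.times) or self.times[pos] != time_index:
            raise ParameterError(f"no basis computed at sample {time_index}")
        if self.degenerate[pos] and not allow_degenerate:
            raise DegenerateSubspaceError(
                f"subspace at sample {time_index} is degenerate")
        return self.bases[pos]

    def basis_at_event(self, event: str) -> np.ndarray:
        return self.basis_at(self.event_index[event])


def _fix_column_signs(bases: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude loading of every column positive."""
    flat = np.swapaxes(bases, -1, -2)           # (..., 3, N)
    idx = np.argmax(np.abs(flat), axis=-1, keepdims=True)
    signs = np.sign(np.take_along_axis(flat, idx, axis=-1))
    signs[signs == 0] = 1.0
    return bases * np.swapaxes(signs, -1, -2)


def instantaneous_subspace_series(tensor: RateTensor,
                                  trial_subset: dict[str, np.ndarray] | str = "all",
                                  times: np.ndarray | None = None) -> SubspaceSeries:
    """PCA of the four centered condition means at each requested 1-ms step.

    ``trial_subset`` maps object -> trial indices (with repeats allowed, for
    bootstrap folds) or ``"all"``.  ``times`` restricts computation to a
    subset of sample indices (default: every step).
    """
    subset = None if trial_subset == "all" else trial_subset
    means = tensor.condition_means(subset)      # (4, N, T)
    if times is None:
        times = np.arange(means.shape[2])
    else:
        times = np.asarray(times, int)
    pts = means[:, :, times].transpose(2, 0, 1)     # (T, 4, N)
    centered = pts - pts.mean(axis=1, keepdims=True)
    # batched thin SVD of the (4, N) centered point sets
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    bases = _fix_column_signs(vt[:, :3, :].transpose(0, 2, 1))      # (T, N, 3)
    scale = np.maximum(1.0, np.linalg.norm(pts, axis=(1, 2)))
    degenerate = s[:, 0] <= 1e-12 * scale
    eigenvalues = s[:, :3] ** 2 / 3.0           # sample variance over 4 points
    return SubspaceSeries(times=times, bases=bases, means=pts,
                          eigenvalues=eigenvalues, degenerate=degenerate,
                          event_index=dict(tensor.event_index))


# ---------------------------------------------------------------------------
# Principal angles
# ---------------------------------------------------------------------------

def _check_orthonormal(w: np.ndarray, name: str, tol: float = 1e-8) -> None:
    gram = w.T @ w
    if np.max(np.abs(gram - np.eye(w.shape[1]))) > tol:
        raise ParameterError(f"{name} does not have orthonormal columns")


def principal_angles(w_a: np.ndarray, w_b: np.ndarray) -> np.ndarray:
    """Principal angles (degrees, ascending) between two orthonormal bases."""
    w_a, w_b = np.asarray(w_a, float), np.asarray(w_b, float)
    if w_a.ndim != 2 or w_b.ndim != 2 or w_a.shape[0] != w_b.shape[0]:
        raise ParameterError("bases must be 2-D with a common ambient dimension")
    _check_orthonormal(w_a, "first basis")
    _check_orthonormal(w_b, "second basis")
    s = np.linalg.svd(w_a.T @ w_b, compute_uv=False)
    return np.sort(np.degrees(np.arccos(np.clip(s, 0.0, 1.0))))


def _batched_angles(bases: np.ndarray, anchor: np.ndarray) -> np.ndarray:
    """Angles (deg, ascending) of a (T, N, 3) stack against one (N, 3) anchor."""
    cross = np.einsum("tnk,nm->tkm", bases, anchor)
    s = np.linalg.svd(cross, compute_uv=False)
    return np.sort(np.degrees(np.arccos(np.clip(s, 0.0, 1.0))), axis=-1)


# ---------------------------------------------------------------------------
# Bootstrapped angle time courses
# ---------------------------------------------------------------------------

@dataclass
class PrincipalAngleSeries:
    """Fold-resolved principal angles against one anchor subspace."""

    anchor: str
    times: np.ndarray               # sample indices
    fold_angles: np.ndarray         # (n_folds, T, 3), NaN at degenerate steps
    chance_mean: float | None = None
    chance_minus_3sd: float | None = None

    @property
    def mean(self) -> np.ndarray:
        return np.nanmean(self.fold_angles, axis=0)

    @property
    def sd(self) -> np.ndarray:
        return np.nanstd(self.fold_angles, axis=0, ddof=1)


def angle_timecourse(tensor: RateTensor, anchors: tuple[str, ...] = ANCHORS,
                     trials_per_object: int = 20, n_folds: int = 10,
                     seed: int | np.random.Generator = 0,
                     times: np.ndarray | None = None,
                     anchor_series: SubspaceSeries | None = None,
                     ) -> dict[str, PrincipalAngleSeries]:
    """Principal-angle time courses against event-anchored subspaces.

    Anchor subspaces at I, G, M, H are computed from *all* trials (or taken
    from ``anchor_series``, e.g. to compare across contexts); each of the
    ``n_folds`` folds resamples ``trials_per_object`` trials per object with
    replacement, recomputes the instantaneous subspace series, and measures
    its angles to each anchor.  Fold mean and SD describe sampling
    variability; the fold mean at an anchor's own time stays above zero
    because the anchors use all trials.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if anchor_series is None:
        anchor_series = instantaneous_subspace_series(
            tensor, times=np.asarray(sorted(tensor.event_index.values())))
    anchor_bases = {}
    for a in anchors:
        try:
            anchor_bases[a] = anchor_series.basis_at_event(a)
        except DegenerateSubspaceError as err:
            raise DegenerateSubspaceError(f"anchor {a!r} is degenerate") from err
    counts = tensor.trial_counts()
    fold_angles = {a: [] for a in anchors}
    times_out = None
    for _ in range(n_folds):
        subset = {o: rng.integers(0, counts[o], size=trials_per_object)
                  for o in OBJECTS}
        series = instantaneous_subspace_series(tensor, subset, times=times)
        times_out = series.times
        for a in anchors:
            ang = _batched_angles(series.bases, anchor_bases[a])
            ang[series.degenerate] = np.nan
            fold_angles[a].append(ang)
    return {a: PrincipalAngleSeries(anchor=a, times=times_out,
                                    fold_angles=np.stack(fold_angles[a]))
            for a in anchors}


# ---------------------------------------------------------------------------
# Random-subspace chance baseline
# ---------------------------------------------------------------------------

@dataclass
class RandomAngleBaseline:
    """First-principal-angle distribution of random 3-D subspaces in R^N."""

    n_ambient: int
    n_draws: int
    theta1: np.ndarray

    @property
    def mean(self) -> float:
        return float(self.theta1.mean())

    @property
    def sd(self) -> float:
        return float(self.theta1.std(ddof=1))

    @property
    def mean_minus_3sd(self) -> float:
        return self.mean - 3.0 * self.sd


def random_angle_baseline(n_ambient: int, n_draws: int = 5000,
                          seed: int | np.random.Generator = 0) -> RandomAngleBaseline:
    """theta1 between a fixed 3-D subspace and random 3-D subspaces of R^N.

    Random bases are drawn by orthonormalizing standard Gaussian N x 3
    matrices (rotation-invariant), so the fixed reference may be taken as
    the first three coordinate axes without loss of generality.
    """
    if n_ambient < 3:
        raise ParameterError("ambient dimension must be >= 3")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g = rng.standard_normal((n_draws, n_ambient, 3))
    q, _ = np.linalg.qr(g)
    cross = q[:, :3, :]                 # reference = span(e1, e2, e3)
    s = np.linalg.svd(cross, compute_uv=False)
    theta1 = np.degrees(np.arccos(np.clip(s[:, 0], 0.0, 1.0)))
    return RandomAngleBaseline(n_ambient=n_ambient, n_draws=n_draws, theta1=theta1)
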