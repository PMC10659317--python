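"""Instantaneous subspaces, principal angles, and chance baselines."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize

from instaspace.preprocess import align_and_concatenate
from instaspace.subspace import (DegenerateSubspaceError, ParameterError,
                                 angle_timecourse,
                                 instantaneous_subspace_series,
                                 principal_angles, random_angle_baseline)

from conftest import make_tensor


def random_orthonormal(rng, n, k=3):
    q, _ = np.linalg.qr(rng.standard_normal((n, k)))
    return q


# ---------------------------------------------------------------------------
# principal_angles
# ---------------------------------------------------------------------------

def brute_force_angles(w_a: np.ndarray, w_b: np.ndarray) -> np.ndarray:
    """Principal angles by direct correlation maximization (no SVD).

    theta_1 maximizes the cosine between unit vectors of the two spans:
    for a fixed direction ``a`` in span(W_a) the best partner in span(W_b)
    has cosine ||M^T a|| with M = W_a^T W_b, so a coarse grid over the unit
    sphere of coefficients plus a local refinement finds theta_1; the
    search is then repeated inside the orthogonal complements for theta_2
    and theta_3.
    """
    m = w_a.T @ w_b
    angles = []
    for _ in range(3):
        k = m.shape[0]
        if m.shape[1] == 0 or k == 0:
            break

        def neg_cos(x):
            x = x / np.linalg.norm(x)
            return -np.linalg.norm(m.T @ x)

        rng = np.random.default_rng(0)
        best, best_val = None, np.inf
        for x0 in rng.standard_normal((200, k)):
            res = minimize(neg_cos, x0 / np.linalg.norm(x0), method="Nelder-Mead",
                           options={"xatol": 1e-12, "fatol": 1e-14,
                                    "maxiter": 4000})
            if res.fun < best_val:
                best, best_val = res.x / np.linalg.norm(res.x), res.fun
        cos = min(1.0, -best_val)
        angles.append(np.degrees(np.arccos(cos)))
        b_dir = m.T @ best
        nb = np.linalg.norm(b_dir)
        # deflate: restrict both sides to the orthogonal complements
        pa = np.eye(k) - np.outer(best, best)
        qa, ra = np.linalg.qr(pa)
        qa = qa[:, np.abs(np.diag(ra)) > 1e-12]
        if nb > 1e-12:
            b_dir = b_dir / nb
            pb = np.eye(m.shape[1]) - np.outer(b_dir, b_dir)
            qb, rb = np.linalg.qr(pb)
            qb = qb[:, np.abs(np.diag(rb)) > 1e-12]
        else:
            qb = np.eye(m.shape[1])
        m = qa.T @ m @ qb
    return np.sort(np.array(angles))


class TestPrincipalAngles:
    def test_identical_subspaces_give_zero(self):
        w = random_orthonormal(np.random.default_rng(0), 12)
        assert np.allclose(principal_angles(w, w), 0.0, atol=1e-5)

    def test_orthogonal_complement_gives_ninety(self):
        rng = np.random.default_rng(1)
        q, _ = np.linalg.qr(rng.standard_normal((6, 6)))
        assert np.allclose(principal_angles(q[:, :3], q[:, 3:]), 90.0)

    @pytest.mark.parametrize("n", [6, 8, 10])
    def test_matches_brute_force_oracle(self, n):
        rng = np.random.default_rng(n)
        w_a = random_orthonormal(rng, n)
        w_b = random_orthonormal(rng, n)
        fast = principal_angles(w_a, w_b)
        slow = brute_force_angles(w_a, w_b)
        assert np.allclose(fast, slow, atol=1e-3)

    @settings(max_examples=15, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetry_and_rotation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        w_a = random_orthonormal(rng, 9)
        w_b = random_orthonormal(rng, 9)
        ang = principal_angles(w_a, w_b)
        assert np.allclose(ang, principal_angles(w_b, w_a), atol=1e-8)
        r, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        assert np.allclose(ang, principal_angles(w_a @ r, w_b), atol=1e-6)
        big, _ = np.linalg.qr(rng.standard_normal((9, 9)))
        assert np.allclose(ang, principal_angles(big @ w_a, big @ w_b),
                           atol=1e-6)

    def test_non_orthonormal_input_rejected(self):
        w = np.random.default_rng(0).standard_normal((8, 3))
        with pytest.raises(ParameterError):
            principal_angles(w, w)

    def test_dimension_mismatch_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ParameterError):
            principal_angles(random_orthonormal(rng, 8),
                             random_orthonormal(rng, 9))


# ---------------------------------------------------------------------------
# instantaneous_subspace_series
# ---------------------------------------------------------------------------

class TestSubspaceSeries:
    @pytest.fixture()
    def generic_tensor(self):
        rng = np.random.default_rng(5)
        n, k, t = 15, 4, 40
        rates = {o: 0.1 + 0.05 * rng.random((n, k, t))
                 for o in ("sphere", "button", "coax", "perp")}
        return make_tensor(rates, {"I": 5, "G": 15, "M": 25, "H": 35})

    def test_three_components_capture_everything(self, generic_tensor):
        series = instantaneous_subspace_series(generic_tensor)
        means = generic_tensor.condition_means().transpose(2, 0, 1)
        centered = means - means.mean(axis=1, keepdims=True)
        s = np.linalg.svd(centered, compute_uv=False)
        share = (s[:, :3] ** 2).sum(axis=1) / (s ** 2).sum(axis=1)
        assert np.allclose(share, 1.0, atol=1e-9)
        assert np.all(s[:, 3] < 1e-12)
        assert not series.degenerate.any()

    def test_bases_are_orthonormal(self, generic_tensor):
        series = instantaneous_subspace_series(generic_tensor)
        gram = np.einsum("tnk,tnm->tkm", series.bases, series.bases)
        assert np.allclose(gram, np.eye(3)[None], atol=1e-10)

    def test_centered_means_lie_in_span(self, generic_tensor):
        series = instantaneous_subspace_series(generic_tensor)
        centered = series.means - series.means.mean(axis=1, keepdims=True)
        proj = np.einsum("tcn,tnk,tmk->tcm", centered, series.bases,
                         series.bases)
        resid = np.linalg.norm(centered - proj, axis=(1, 2))
        scale = np.linalg.norm(centered, axis=(1, 2))
        assert np.all(resid <= 1e-9 * np.maximum(scale, 1e-30))

    def test_identical_condition_means_flag_degenerate(self):
        base = 0.2 + 0.1 * np.random.default_rng(0).random((6, 3, 20))
        rates = {o: base.copy() for o in ("sphere", "button", "coax", "perp")}
        tensor = make_tensor(rates, {"I": 2, "G": 8, "M": 12, "H": 18})
        series = instantaneous_subspace_series(tensor)
        assert series.degenerate.all()
        with pytest.raises(DegenerateSubspaceError):
            series.basis_at(2)


# ---------------------------------------------------------------------------
# random baseline
# ---------------------------------------------------------------------------

class TestRandomBaseline:
    def test_full_space_has_zero_angle(self):
        b = random_angle_baseline(3, n_draws=50, seed=0)
        assert np.allclose(b.theta1, 0.0, atol=1e-5)

    def test_mean_angle_grows_with_ambient_dimension(self):
        means = [random_angle_baseline(n, n_draws=400, seed=1).mean
                 for n in (5, 10, 50, 200, 500)]
        assert np.all(np.diff(means) > 0)

    def test_seeded_determinism(self):
        a = random_angle_baseline(20, n_draws=100, seed=5)
        b = random_angle_baseline(20, n_draws=100, seed=5)
        assert np.array_equal(a.theta1, b.theta1)

    def test_small_dimension_rejected(self):
        with pytest.raises(ParameterError):
            random_angle_baseline(2)


# ---------------------------------------------------------------------------
# angle time courses on simulated sessions
# ---------------------------------------------------------------------------

class TestAngleTimecourse:
    def test_fold_mean_at_anchor_positive_but_below_chance(self, highsnr_session):
        session, _ = highsnr_session
        tensor = align_and_concatenate(session, "execution")
        grid = np.arange(0, tensor.n_timepoints, 50)
        res = angle_timecourse(tensor, ("M",), trials_per_object=20,
                               n_folds=10, seed=4, times=grid)
        s = res["M"]
        at_anchor = s.mean[np.searchsorted(s.times, tensor.event_index["M"]), 0]
        chance = random_angle_baseline(tensor.n_units, 1000, seed=0).mean
        assert 0.0 < at_anchor < chance

    def test_shifting_subspace_approaches_movement_anchor(self, highsnr_session):
        # planted I->M geodesic shift: theta1 against the M anchor falls
        # monotonically from instruction to movement onset
        from scipy.stats import spearmanr
        session, _ = highsnr_session
        tensor = align_and_concatenate(session, "execution")
        grid = np.arange(tensor.event_index["I"], tensor.event_index["M"], 25)
        res = angle_timecourse(tensor, ("M",), trials_per_object=20,
                               n_folds=5, seed=2, times=grid)
        mean_theta1 = res["M"].mean[:, 0]
        rho = spearmanr(np.arange(len(mean_theta1)), mean_theta1).statistic
        assert rho < -0.9

    def test_static_loading_gives_flat_timecourse(self):
        from instaspace.synth import SynthConfig, generate_session
        cfg = SynthConfig(
            n_units={"MN": 40, "AE": 0, "AO": 0, "NS": 0}, trials_per_object=30,
            baseline_range_hz=(90.0, 120.0), cd_amplitude_hz=250.0,
            ci_amplitude_hz=0.0, score_noise_sd=0.05,
            ramp_instruction_step=1.0,
            planted_angles={("I", "G"): 0.0, ("G", "M"): 0.0, ("M", "H"): 0.0},
            observation_orthogonal=False, seed=21)
        session, _ = generate_session(cfg)
        tensor = align_and_concatenate(session, "execution")
        # sample away from the anchor troughs, inside the delay period
        grid = np.arange(tensor.event_index["I"] + 200,
                         tensor.event_index["G"] - 200, 50)
        res = angle_timecourse(tensor, ("M",), trials_per_object=20,
                               n_folds=5, seed=3, times=grid)
        mean_theta1 = res["M"].mean[:, 0]
        slope = np.polyfit(np.arange(len(mean_theta1)), mean_theta1, 1)[0]
        assert abs(slope * len(mean_theta1)) < 5.0   # < 5 deg drift overall
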