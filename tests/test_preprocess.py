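"""Binning/smoothing/sqrt, alignment, and unit classification."""

import numpy as np
import pandas as pd
import pytest

from instaspace.preprocess import (DEFAULT_ALPHA, ParameterError,
                                   align_and_concatenate, bin_smooth_sqrt,
                                   bin_spikes, classify_units,
                                   two_way_anova_counts)
from instaspace.synth import SynthConfig, generate_session

from conftest import make_session, make_trial


class TestBinSmoothSqrt:
    def test_no_spikes_gives_zero_trace(self):
        trace = bin_smooth_sqrt(np.empty(0), (0.0, 1.0))
        assert trace.shape == (1000,)
        assert np.all(trace == 0.0)

    def test_kernel_mass_is_preserved(self):
        # one spike at window center: pre-sqrt trace integrates to 1
        trace = bin_smooth_sqrt(np.array([0.5]), (0.0, 1.0), sqrt=False)
        assert trace.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.argmax(trace) == 500

    def test_edge_renormalization_keeps_rates_unbiased(self):
        # regular 100 Hz spiking: the truncated-kernel renormalization keeps
        # the rate estimate flat all the way to the window edges
        spikes = np.arange(0.005, 1.0, 0.01)
        trace = bin_smooth_sqrt(spikes, (0.0, 1.0), sqrt=False)
        assert trace[0] == pytest.approx(0.1, rel=0.02)
        assert trace[-1] == pytest.approx(0.1, rel=0.02)
        assert trace[500] == pytest.approx(0.1, rel=0.02)

    def test_spike_at_bin_edge_goes_to_later_bin(self):
        counts = bin_spikes(np.array([0.005]), (0.0, 0.01))
        assert counts[5] == 1.0 and counts.sum() == 1.0

    def test_translation_equivariance(self):
        rng = np.random.default_rng(0)
        spikes = np.sort(rng.uniform(2.0, 8.0, size=200))
        a = bin_smooth_sqrt(spikes, (0.0, 10.0))
        b = bin_smooth_sqrt(spikes + 0.5, (0.5, 10.5))
        assert np.allclose(a, b, atol=1e-12)

    def test_homogeneous_poisson_rate_recovery(self):
        # 100 Hz for 10 s: interior pre-sqrt ~ 0.1/bin, post-sqrt ~ 0.316
        pre, post = [], []
        for s in range(20):
            rng = np.random.default_rng(s)
            n = rng.poisson(100 * 10)
            spikes = np.sort(rng.uniform(0.0, 10.0, size=n))
            pre.append(bin_smooth_sqrt(spikes, (0, 10.0), sqrt=False)[500:-500].mean())
            post.append(bin_smooth_sqrt(spikes, (0, 10.0))[500:-500].mean())
        assert np.mean(pre) == pytest.approx(0.1, rel=0.05)
        assert np.mean(post) == pytest.approx(np.sqrt(0.1), rel=0.05)

    def test_bad_window_rejected(self):
        with pytest.raises(ParameterError):
            bin_smooth_sqrt(np.empty(0), (1.0, 1.0))


class TestAlignAndConcatenate:
    @pytest.fixture()
    def fixed_timing_session(self):
        # identical epochs on every trial: median delay 1.0 s, reaction 0.3 s
        trials = []
        k = 0
        for obj in ("sphere", "button", "coax", "perp"):
            for _ in range(2):
                trials.append(make_trial(f"t{k}", obj, "execution",
                                         start=10.0 * k))
                k += 1
        rng = np.random.default_rng(1)
        rows = []
        for t in trials:
            times = np.sort(rng.uniform(t.events["start"], t.events["end"], 60))
            rows.append(pd.DataFrame({"unit_id": "u0", "trial_id": t.trial_id,
                                      "spike_time_s": times}))
        return make_session(n_units=1, trials=trials, spikes=pd.concat(rows))

    def test_concatenated_length_and_event_indices(self, fixed_timing_session):
        tensor = align_and_concatenate(fixed_timing_session, "execution")
        # T = 1000 + (1000 + 150) + (150 + 200) + 400 = 2900
        assert tensor.n_timepoints == 2900
        assert tensor.event_index == {"I": 500, "G": 2000, "M": 2300, "H": 2700}
        # index(M) - index(G) equals the median reaction time in ms
        assert tensor.event_index["M"] - tensor.event_index["G"] == 300

    def test_identical_trials_have_identical_rows(self):
        trials = [make_trial(f"t{k}", obj, "execution", start=10.0 * k)
                  for k, obj in enumerate(("sphere", "button", "coax", "perp"))]
        trials += [make_trial("t4", "sphere", "execution", start=40.0)]
        spikes = []
        for tid, t in (("t0", trials[0]), ("t4", trials[4])):
            # binary-exact offsets so both trials bin identically
            offsets = np.array([0.875, 1.5, 2.125, 2.75, 3.0])
            spikes.append(pd.DataFrame({
                "unit_id": "u0", "trial_id": tid,
                "spike_time_s": t.events["start"] + offsets}))
        session = make_session(n_units=1, trials=trials,
                               spikes=pd.concat(spikes))
        tensor = align_and_concatenate(session, "execution")
        assert np.allclose(tensor.rates["sphere"][:, 0, :],
                           tensor.rates["sphere"][:, 1, :])

    def test_tensor_invariant_to_trial_order(self, small_session):
        session, _ = small_session
        tensor = align_and_concatenate(session, "execution")
        reversed_trials = list(session.trials)[::-1]
        shuffled = type(session)(units=session.units, trials=reversed_trials,
                                 spikes=session.spikes, meta=session.meta)
        tensor2 = align_and_concatenate(shuffled, "execution")
        for obj in tensor.rates:
            order = [tensor2.trial_ids[obj].index(t)
                     for t in tensor.trial_ids[obj]]
            assert np.allclose(tensor.rates[obj],
                               tensor2.rates[obj][:, order, :])

    def test_missing_object_is_an_error(self):
        trials = [make_trial(f"t{k}", obj, "execution", start=10.0 * k)
                  for k, obj in enumerate(("sphere", "button", "coax"))]
        session = make_session(trials=trials)
        with pytest.raises(ParameterError, match="perp"):
            align_and_concatenate(session, "execution")


class TestClassifyUnits:
    def test_alpha_default_is_bonferroni_over_six(self):
        assert DEFAULT_ALPHA == pytest.approx(0.05 / 6)
        assert round(DEFAULT_ALPHA, 4) == 0.0083

    def test_batched_anova_matches_statsmodels(self):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols
        rng = np.random.default_rng(3)
        n_per = 3
        objs = np.repeat(np.arange(4), 11 * n_per)
        pers = np.tile(np.repeat(np.arange(11), n_per), 4)
        y = rng.poisson(4.0 + objs + 0.3 * pers
                        + 0.2 * objs * (pers % 3)).astype(float)
        # unbalance the design by dropping some observations
        keep = rng.random(y.size) > 0.1
        ours = two_way_anova_counts(y[keep, None], objs[keep], pers[keep]).iloc[0]
        df = pd.DataFrame({"y": y[keep], "obj": objs[keep].astype(str),
                           "per": pers[keep].astype(str)})
        fit = ols("y ~ C(obj) * C(per)", data=df).fit()
        ref = sm.stats.anova_lm(fit, typ=2)
        assert ours["p_object"] == pytest.approx(ref.loc["C(obj)", "PR(>F)"], rel=1e-8)
        assert ours["p_period"] == pytest.approx(ref.loc["C(per)", "PR(>F)"], rel=1e-8)
        assert ours["p_interaction"] == pytest.approx(
            ref.loc["C(obj):C(per)", "PR(>F)"], rel=1e-8)

    def test_planted_classes_recovered(self):
        # sensitivity/specificity on ground truth at default effect sizes
        # needs the full 40 trials per object
        cfg = SynthConfig(n_units={"MN": 10, "AE": 6, "AO": 4, "NS": 4},
                          trials_per_object=40, seed=7)
        session, truth = generate_session(cfg)
        result = classify_units(session)
        agree = np.mean([result.classes[u] == truth.unit_classes[u]
                         for u in session.unit_ids])
        assert agree >= 0.9

    def test_mirror_units_become_ae_when_observation_silent(self):
        cfg = SynthConfig(n_units={"MN": 10, "AE": 0, "AO": 0, "NS": 2},
                          trials_per_object=10, observation_scale=0.0, seed=5,
                          observation_orthogonal=False)
        session, truth = generate_session(cfg)
        result = classify_units(session)
        mn = [u for u, c in truth.unit_classes.items() if c == "MN"]
        assert all(result.classes[u] == "AE" for u in mn)

    def test_all_zero_unit_is_ns_with_note(self):
        session, _ = generate_session(
            SynthConfig(n_units={"MN": 4, "AE": 0, "AO": 0, "NS": 2},
                        trials_per_object=3, seed=9,
                        observation_orthogonal=False))
        silent = session.unit_ids[-1]
        spikes = session.spikes[session.spikes["unit_id"] != silent]
        quiet = type(session)(units=session.units, trials=session.trials,
                              spikes=spikes.copy(), meta=session.meta)
        result = classify_units(quiet)
        assert result.classes[silent] == "NS"
        assert silent in result.notes
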