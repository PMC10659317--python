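"""Shared fixtures: small synthetic sessions and hand-built tensors."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from instaspace.preprocess import AlignmentWindows, RateTensor
from instaspace.session import EVENT_ORDER, SessionDataset, TrialRecord, UnitRecord
from instaspace.synth import SynthConfig, generate_session


def make_trial(trial_id: str, obj: str, context: str, start: float = 0.0,
               initial_hold: float = 0.7, instruction: float = 0.5,
               delay: float = 1.0, reaction: float = 0.3, movement: float = 0.5,
               hold: float = 1.0, pad: float = 0.2, success: bool = True
               ) -> TrialRecord:
    """A trial with exactly specified epoch durations."""
    t = start
    events = {"start": t}
    for name, dur in (("instruction_on", initial_hold),
                      ("instruction_off", instruction), ("go", delay),
                      ("movement_on", reaction), ("hold_on", movement),
                      ("hold_off", hold), ("end", pad)):
        t += dur
        events[name] = t
    return TrialRecord(trial_id, obj, context, events, success)


def make_session(n_units: int = 3, trials: list[TrialRecord] | None = None,
                 spikes: pd.DataFrame | None = None) -> SessionDataset:
    units = [UnitRecord(f"u{i}") for i in range(n_units)]
    if trials is None:
        trials = [make_trial(f"t{j}", obj, "execution", start=10.0 * j)
                  for j, obj in enumerate(("sphere", "button", "coax", "perp"))]
    if spikes is None:
        spikes = pd.DataFrame(columns=["unit_id", "trial_id", "spike_time_s"])
    return SessionDataset(units=units, trials=trials, spikes=spikes)


def make_tensor(rates: dict[str, np.ndarray], event_index: dict[str, int],
                context: str = "execution") -> RateTensor:
    """Wrap raw per-object (N, K, T) arrays in a RateTensor."""
    first = next(iter(rates.values()))
    t_len = first.shape[2]
    bounds = {ev: (0, t_len) for ev in event_index}
    windows = AlignmentWindows(per_object={}, pooled={})
    return RateTensor(
        rates=rates, event_index=event_index, snippet_bounds=bounds,
        unit_ids=[f"u{i}" for i in range(first.shape[0])],
        trial_ids={o: [f"{o}-{k}" for k in range(r.shape[1])]
                   for o, r in rates.items()},
        context=context, windows=windows)


@pytest.fixture(scope="session")
def small_session():
    """A quick low-rate session with all four unit classes (seeded)."""
    cfg = SynthConfig(n_units={"MN": 16, "AE": 6, "AO": 4, "NS": 4},
                      trials_per_object=8, seed=7)
    return generate_session(cfg)


@pytest.fixture(scope="session")
def highsnr_session():
    """A high-rate, slow-kinematics session where planted structure is
    recoverable: strong condition-dependent amplitude relative to the
    Poisson noise floor of sqrt-transformed, 50-ms-smoothed rates."""
    cfg = SynthConfig(
        n_units={"MN": 60, "AE": 0, "AO": 0, "NS": 0}, trials_per_object=40,
        baseline_range_hz=(90.0, 120.0), cd_amplitude_hz=250.0,
        ci_amplitude_hz=0.0, score_noise_sd=0.05, ramp_instruction_step=1.0,
        reaction_mean_s=0.6, movement_mean_s=0.8, seed=11)
    return generate_session(cfg)


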