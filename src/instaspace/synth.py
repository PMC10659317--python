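"""Synthetic RGM sessions with planted latent structure.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage can be validated against known ground truth:

* a delayed-response task timeline (initial hold, 500-ms instruction, a
  500–2000 ms preparatory delay, reaction, movement, final hold);
* condition-independent (CI) rate modulation shared by the four objects;
* condition-dependent (CD) modulation whose 3-D loading subspace shifts
  progressively between event-anchored subspaces at instruction onset (I),
  go cue (G), movement onset (M) and hold start (H);
* object separation that grows over the trial (a score ramp);
* an observation context with lower-amplitude, differently-loaded
  modulation; and
* MN / AE / AO / NS unit classes (mirror, execution-only, observation-only,
  unmodulated).

Per unit *n* on trial *k* (object *o*, context *c*) the firing rate on the
1-ms grid is

    lambda_n(t) = max(0, b_n + g(class_n, c) * [ c_n * A_CI * f_CI(t)
                       + A_CD * a_class * (U_c(t) @ s_{o,k}(t))_n ])

where ``U_c(t)`` geodesically interpolates the planted anchor loadings,
``s_{o,k}(t) = ramp(t) * (d_o + eta_k)`` are the object latent scores with
per-trial noise, and the gate ``g`` is 1 where a class is active, ``gamma``
for mirror units during observation, and 0 otherwise.  Spikes are drawn as
an inhomogeneous Poisson process on the 1-ms grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .session import OBJECTS, SessionDataset, TrialRecord, UnitRecord

ANCHORS = ("I", "G", "M", "H")
#: map from anchor label to the trial event it is locked to
ANCHOR_EVENTS = {"I": "instruction_on", "G": "go", "M": "movement_on", "H": "hold_on"}
CLASSES = ("MN", "AE", "AO", "NS")

#: centered unit-norm object score directions (tetrahedron vertices in R^3)
OBJECT_DIRECTIONS = {
    "sphere": np.array([1.0, 1.0, 1.0]) / np.sqrt(3),
    "button": np.array([1.0, -1.0, -1.0]) / np.sqrt(3),
    "coax": np.array([-1.0, 1.0, -1.0]) / np.sqrt(3),
    "perp": np.array([-1.0, -1.0, 1.0]) / np.sqrt(3),
}


class ParameterError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Loading schedules
# ---------------------------------------------------------------------------

@dataclass
class LoadingSchedule:
    """Anchor loading matrices plus the chain rotations that connect them.

    Between consecutive anchors the loading follows the exact geodesic
    ``U(tau)[:, i] = cos(tau * a) * U_k[:, i] + sin(tau * a) * V_k[:, i]``
    with ``V_k`` orthonormal and orthogonal to ``span(U_k)``; every
    interpolated frame therefore has exactly orthonormal columns and the
    first principal angle to the preceding anchor is exactly ``tau * a``.
    """

    anchor_loadings: dict[str, np.ndarray]          # event -> (N, 3)
    step_directions: dict[tuple[str, str], np.ndarray]   # pair -> (N, 3)
    step_angles_deg: dict[tuple[str, str], float]

    @property
    def n_units(self) -> int:
        return self.anchor_loadings["I"].shape[0]

    def loading_at(self, pair: tuple[str, str], tau: float | np.ndarray) -> np.ndarray:
        """Interpolated loading(s) between a consecutive anchor pair.

        ``tau`` in [0, 1]; scalar tau returns (N, 3), an array of taus
        returns (len(tau), N, 3).
        """
        a = np.deg2rad(self.step_angles_deg[pair])
        u = self.anchor_loadings[pair[0]]
        v = self.step_directions[pair]
        tau = np.asarray(tau, float)
        c, s = np.cos(tau * a), np.sin(tau * a)
        if tau.ndim == 0:
            return c * u + s * v
        return c[:, None, None] * u[None] + s[:, None, None] * v[None]

    def project_scores(self, pair: tuple[str, str], tau: np.ndarray,
                       scores: np.ndarray) -> np.ndarray:
        """``U(tau_t) @ scores[:, t]`` without materializing every frame.

        scores: (3, T); returns (N, T).
        """
        a = np.deg2rad(self.step_angles_deg[pair])
        u = self.anchor_loadings[pair[0]]
        v = self.step_directions[pair]
        c, s = np.cos(tau * a), np.sin(tau * a)
        return (u @ scores) * c[None, :] + (v @ scores) * s[None, :]


def _random_orthonormal(rng: np.random.Generator, n: int, k: int,
                        complement_of: np.ndarray | None = None) -> np.ndarray:
    """Random N x k orthonormal matrix, optionally inside a complement."""
    for _ in range(20):
        g = rng.standard_normal((n, k))
        if complement_of is not None:
            g -= complement_of @ (complement_of.T @ g)
        q, r = np.linalg.qr(g)
        if np.min(np.abs(np.diag(r))) > 1e-10:
            # fix sign for determinism
            q *= np.sign(np.diag(r))[None, :]
            return q
    raise ParameterError("could not draw a full-rank orthonormal frame")


def build_loading_schedule(n_units: int,
                           planted_angles: Mapping[tuple[str, str], float] | float,
                           seed: int | np.random.Generator,
                           within: np.ndarray | None = None) -> LoadingSchedule:
    """Build anchor loadings realizing requested consecutive principal angles.

    Parameters
    ----------
    n_units
        Ambient dimension N (>= 4; >= 6 for any nonzero requested angle).
    planted_angles
        Requested first principal angle in degrees for each consecutive
        anchor pair ``("I","G"), ("G","M"), ("M","H")``; a scalar applies to
        all three steps.  All three principal angles of a consecutive pair
        equal the request by construction.
    within
        Optional orthonormal (N, d) frame; all anchors are drawn inside its
        span's orthogonal complement (used to plant an observation schedule
        orthogonal to the execution one).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pairs = [("I", "G"), ("G", "M"), ("M", "H")]
    if np.isscalar(planted_angles):
        planted_angles = {p: float(planted_angles) for p in pairs}
    angles = {p: float(planted_angles.get(p, 0.0)) for p in pairs}
    if n_units < 4:
        raise ParameterError("n_units must be >= 4")
    for p, a in angles.items():
        if not (0.0 <= a <= 90.0):
            raise ParameterError(f"angle for {p} must be in [0, 90] deg, got {a}")
        if a > 0 and n_units < 6:
            raise ParameterError(
                f"planting a nonzero first principal angle ({a} deg for {p}) "
                f"requires n_units >= 6, got {n_units}"
            )
    used = within
    u = _random_orthonormal(rng, n_units, 3, complement_of=used)
    loadings = {"I": u}
    step_dirs: dict[tuple[str, str], np.ndarray] = {}
    for pair in pairs:
        a, b = pair
        cur = loadings[a]
        comp = cur if within is None else np.hstack([within, cur])
        if angles[pair] == 0.0:
            v = np.zeros_like(cur)
        else:
            v = _random_orthonormal(rng, n_units, 3, complement_of=comp)
        step_dirs[pair] = v
        rad = np.deg2rad(angles[pair])
        loadings[b] = np.cos(rad) * cur + np.sin(rad) * v
    return LoadingSchedule(anchor_loadings=loadings, step_directions=step_dirs,
                           step_angles_deg=angles)


# ---------------------------------------------------------------------------
# Configuration and ground truth
# ---------------------------------------------------------------------------

@dataclass
class SynthConfig:
    """Study conditions for one synthetic session.

    Defaults reflect a mid-sized premotor recording: ~60 units dominated by
    mirror neurons, two dozen successful trials per object and context, a
    ~10 Hz baseline, and observation-context modulation at 70% of the
    execution amplitude with a loading subspace orthogonal to execution but
    the same relational object geometry.
    """

    n_units: dict[str, int] = field(
        default_factory=lambda: {"MN": 40, "AE": 14, "AO": 3, "NS": 6})
    trials_per_object: int = 24
    # epoch duration distributions (seconds)
    initial_hold_range: tuple[float, float] = (0.5, 1.0)
    instruction_s: float = 0.5
    delay_range: tuple[float, float] = (0.5, 2.0)
    reaction_mean_s: float = 0.3
    reaction_sd_s: float = 0.03
    movement_mean_s: float = 0.5
    movement_sd_s: float = 0.05
    hold_s: float = 1.0
    end_pad_s: float = 0.2
    # rate model (Hz)
    baseline_range_hz: tuple[float, float] = (5.0, 15.0)
    ci_amplitude_hz: float = 5.0
    cd_amplitude_hz: float = 12.0
    observation_scale: float = 0.7           # gamma in [0, 1]
    score_noise_sd: float = 0.15
    observation_noise_scale: float = 1.0     # multiplies score noise in observation
    # object-specific fast latent dynamics (looping trajectories within
    # segments); amplitude relative to the unit-norm object directions,
    # frequencies in cycles per inter-anchor interval
    score_dynamics_amp: float = 0.0
    score_dynamics_cycles: tuple[float, float] = (1.5, 4.0)
    class_amplitude: dict[str, float] = field(
        default_factory=lambda: {"MN": 1.0, "AE": 1.0, "AO": 1.0, "NS": 0.0})
    # planted subspace geometry
    planted_angles: dict[tuple[str, str], float] = field(
        default_factory=lambda: {("I", "G"): 45.0, ("G", "M"): 45.0, ("M", "H"): 30.0})
    observation_orthogonal: bool = True
    shared_geometry: bool = True     # same object score directions in both contexts
    # score ramp shape (relative to the peak of 1 at movement onset)
    ramp_instruction_step: float = 0.4
    ramp_end_execution: float = 0.85
    ramp_end_observation: float = 1.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.observation_scale <= 1.0):
            raise ParameterError("observation_scale must be in [0, 1]")
        if self.trials_per_object < 1:
            raise ParameterError("trials_per_object must be >= 1")
        if any(c < 0 for c in self.n_units.values()):
            raise ParameterError("unit counts must be >= 0")


@dataclass
class GroundTruth:
    """Everything planted by the generator, kept for recovery tests."""

    unit_classes: dict[str, str]
    schedules: dict[str, LoadingSchedule]          # context -> schedule
    object_directions: dict[str, dict[str, np.ndarray]]   # context -> object -> R^3
    trial_events: dict[str, dict[str, float]]
    trial_score_noise: dict[str, np.ndarray]
    config: SynthConfig


# ---------------------------------------------------------------------------
# Spike generation
# ---------------------------------------------------------------------------

def rates_to_spikes(rate_hz: np.ndarray, seed: int | np.random.Generator,
                    t0: float = 0.0) -> np.ndarray:
    """Inhomogeneous Poisson spikes from a rate trace on the 1-ms grid.

    Per-bin counts are Poisson(rate * 1 ms); spike times are placed
    uniformly within their bin and offset by ``t0`` (seconds).
    """
    rate_hz = np.asarray(rate_hz, float)
    if rate_hz.ndim != 1:
        raise ParameterError("rate trace must be 1-D")
    if not np.all(np.isfinite(rate_hz)) or np.any(rate_hz < 0):
        raise ParameterError("rates must be finite and non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = rng.poisson(rate_hz * 1e-3)
    total = int(counts.sum())
    if total == 0:
        return np.empty(0)
    bins = np.repeat(np.arange(rate_hz.size), counts)
    times = t0 + (bins + rng.random(total)) * 1e-3
    return np.sort(times)


def _ramp(t: np.ndarray, ev: dict[str, float], end_value: float,
          instruction_step: float = 0.4) -> np.ndarray:
    """Object-score amplitude: zero before instruction onset, a step at
    instruction onset (signal-related discharge), linear rise to 1 at
    movement onset, then linear drift to ``end_value`` at hold start."""
    i_on = ev["instruction_on"]
    xp = [ev["start"], i_on - 1e-4, i_on, ev["movement_on"], ev["hold_on"], ev["end"]]
    fp = [0.0, 0.0, instruction_step, 1.0, end_value, end_value]
    return np.interp(t, xp, fp)


def _progress(t: np.ndarray, ev: dict[str, float]) -> np.ndarray:
    """Trial progress coordinate: 0, 1, 2, 3 at anchors I, G, M, H, linear
    between, linearly extrapolated outside (post-H unit = the M->H span)."""
    a = [ev[ANCHOR_EVENTS[k]] for k in ANCHORS]
    u = np.interp(t, a, [0.0, 1.0, 2.0, 3.0])
    pre = t < a[0]
    u[pre] = (t[pre] - a[0]) / (a[1] - a[0])
    post = t > a[3]
    u[post] = 3.0 + (t[post] - a[3]) / (a[3] - a[2])
    return u


def _ci_profile(t: np.ndarray, ev: dict[str, float]) -> np.ndarray:
    """Condition-independent modulation: rises through the delay, peaks mid
    movement, decays over the final hold."""
    xp = [ev["start"], ev["instruction_on"], ev["go"],
          ev["movement_on"], ev["movement_on"] + 0.6 * (ev["hold_on"] - ev["movement_on"]),
          ev["hold_on"], ev["hold_off"], ev["end"]]
    fp = [0.0, 0.0, 0.4, 0.8, 1.0, 0.6, 0.2, 0.1]
    return np.interp(t, xp, fp)


def _class_gate(cls: str, context: str, gamma: float) -> float:
    if cls == "MN":
        return 1.0 if context == "execution" else gamma
    if cls == "AE":
        return 1.0 if context == "execution" else 0.0
    if cls == "AO":
        return 1.0 if context == "observation" else 0.0
    return 0.0


def _draw_trial_epochs(cfg: SynthConfig, rng: np.random.Generator,
                       start: float) -> dict[str, float]:
    ih = rng.uniform(*cfg.initial_hold_range)
    delay = rng.uniform(*cfg.delay_range)
    reaction = max(0.05, rng.normal(cfg.reaction_mean_s, cfg.reaction_sd_s))
    movement = max(0.1, rng.normal(cfg.movement_mean_s, cfg.movement_sd_s))
    ev = {"start": start}
    ev["instruction_on"] = ev["start"] + ih
    ev["instruction_off"] = ev["instruction_on"] + cfg.instruction_s
    ev["go"] = ev["instruction_off"] + delay
    ev["movement_on"] = ev["go"] + reaction
    ev["hold_on"] = ev["movement_on"] + movement
    ev["hold_off"] = ev["hold_on"] + cfg.hold_s
    ev["end"] = ev["hold_off"] + cfg.end_pad_s
    return ev


def _cd_projection(schedule: LoadingSchedule, t: np.ndarray,
                   ev: dict[str, float], scores: np.ndarray) -> np.ndarray:
    """(U_c(t) @ scores) for a whole trial; scores is (3, T) -> (N, T)."""
    anchor_t = np.array([ev[ANCHOR_EVENTS[a]] for a in ANCHORS])
    out = np.empty((schedule.n_units, t.size))
    pairs = [("I", "G"), ("G", "M"), ("M", "H")]
    # before I: hold U_I; after H: hold U_H
    pre = t <= anchor_t[0]
    if pre.any():
        out[:, pre] = schedule.anchor_loadings["I"] @ scores[:, pre]
    post = t >= anchor_t[-1]
    if post.any():
        out[:, post] = schedule.anchor_loadings["H"] @ scores[:, post]
    for i, pair in enumerate(pairs):
        sel = (t > anchor_t[i]) & (t < anchor_t[i + 1])
        if sel.any():
            tau = (t[sel] - anchor_t[i]) / (anchor_t[i + 1] - anchor_t[i])
            out[:, sel] = schedule.project_scores(pair, tau, scores[:, sel])
    return out


def generate_session(config: SynthConfig) -> tuple[SessionDataset, GroundTruth]:
    """Generate one synthetic session plus its ground truth."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_total = sum(cfg.n_units.values())
    if n_total < 4:
        raise ParameterError("need at least 4 units in total")

    # units: classes laid out in blocks, areas alternating for plumbing realism
    unit_classes: dict[str, str] = {}
    units = []
    i = 0
    for cls in CLASSES:
        for _ in range(cfg.n_units.get(cls, 0)):
            uid = f"u{i:03d}"
            unit_classes[uid] = cls
            units.append(UnitRecord(uid, area="PMv" if i % 2 else "PMd",
                                    quality=("single", "probable_single", "multi")[i % 3]))
            i += 1
    baselines = rng.uniform(*cfg.baseline_range_hz, size=n_total)
    ci_weights = np.abs(rng.normal(1.0, 0.3, size=n_total))
    class_arr = np.array([unit_classes[u.unit_id] for u in units])

    # planted loading schedules per context
    exec_sched = build_loading_schedule(n_total, cfg.planted_angles, rng)
    if cfg.observation_orthogonal:
        exec_span = np.hstack([exec_sched.anchor_loadings[a] for a in ANCHORS]
                              + [exec_sched.step_directions[p]
                                 for p in exec_sched.step_directions])
        q, _ = np.linalg.qr(exec_span)
        # keep only the numerically independent part of the execution span
        rank = np.linalg.matrix_rank(exec_span, tol=1e-8)
        within = q[:, :rank]
        if n_total - rank < 6:
            raise ParameterError(
                "too few units to plant an orthogonal observation schedule")
        obs_sched = build_loading_schedule(n_total, cfg.planted_angles, rng,
                                           within=within)
    else:
        obs_sched = build_loading_schedule(n_total, cfg.planted_angles, rng)
    schedules = {"execution": exec_sched, "observation": obs_sched}

    directions = {ctx: {o: OBJECT_DIRECTIONS[o].copy() for o in OBJECTS}
                  for ctx in ("execution", "observation")}
    if not cfg.shared_geometry:
        # different relational geometry: random rotation + per-object scaling
        q = _random_orthonormal(rng, 3, 3)
        scale = rng.uniform(0.5, 1.5, size=4)
        for j, o in enumerate(OBJECTS):
            directions["observation"][o] = scale[j] * (q @ OBJECT_DIRECTIONS[o])

    amp = {(cls, ctx): cfg.class_amplitude.get(cls, 0.0)
           * _class_gate(cls, ctx, cfg.observation_scale)
           for cls in CLASSES for ctx in ("execution", "observation")}

    # optional object-specific fast latent dynamics (drawn only if enabled,
    # so the default generator output is unchanged)
    wiggles: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    if cfg.score_dynamics_amp > 0:
        for ctx in ("execution", "observation"):
            for o in OBJECTS:
                wiggles[(ctx, o)] = (
                    rng.uniform(*cfg.score_dynamics_cycles, size=2),
                    rng.uniform(0.0, 2.0 * np.pi, size=(3, 2)))

    uid_list = [u.unit_id for u in units]
    spike_unit, spike_trial, spike_time = [], [], []
    trials: list[TrialRecord] = []
    trial_events: dict[str, dict[str, float]] = {}
    trial_noise: dict[str, np.ndarray] = {}
    clock = 0.0
    k = 0
    for context in ("execution", "observation"):
        # pseudorandom block design: each block holds all four objects shuffled
        order: list[str] = []
        for _ in range(cfg.trials_per_object):
            block = list(OBJECTS)
            rng.shuffle(block)
            order.extend(block)
        for obj in order:
            ev = _draw_trial_epochs(cfg, rng, clock)
            clock = ev["end"] + 1.0
            tid = f"t{k:04d}"
            k += 1
            trials.append(TrialRecord(tid, obj, context, dict(ev), success=True))
            trial_events[tid] = dict(ev)
            noise_sd = cfg.score_noise_sd * (cfg.observation_noise_scale
                                             if context == "observation" else 1.0)
            eta = rng.normal(0.0, noise_sd, size=3)
            trial_noise[tid] = eta

            n_bins = int(np.floor((ev["end"] - ev["start"]) / 1e-3))
            t = ev["start"] + (np.arange(n_bins) + 0.5) * 1e-3
            ramp = _ramp(t, ev, cfg.ramp_end_execution if context == "execution"
                         else cfg.ramp_end_observation,
                         cfg.ramp_instruction_step)
            ci = _ci_profile(t, ev)
            base = (directions[context][obj] + eta)[:, None]
            if cfg.score_dynamics_amp > 0:
                freqs, phases = wiggles[(context, obj)]
                u = _progress(t, ev)
                arg = (2.0 * np.pi * freqs[None, :, None] * u[None, None, :]
                       + phases[:, :, None])
                base = base + (cfg.score_dynamics_amp / np.sqrt(2.0)
                               ) * np.sin(arg).sum(axis=1)
            scores = ramp[None, :] * base
            cd = _cd_projection(schedules[context], t, ev, scores)  # (N, T)
            gates = np.array([amp[(c, context)] for c in class_arr])
            rates = (baselines[:, None]
                     + gates[:, None] * (ci_weights[:, None] * cfg.ci_amplitude_hz
                                         * ci[None, :]
                                         + cfg.cd_amplitude_hz * cd))
            np.maximum(rates, 0.0, out=rates)
            counts = rng.poisson(rates * 1e-3)
            nz_unit, nz_bin = np.nonzero(counts)
            if nz_unit.size:
                reps = counts[nz_unit, nz_bin]
                ubin = np.repeat(nz_bin, reps)
                uunit = np.repeat(nz_unit, reps)
                times = ev["start"] + (ubin + rng.random(ubin.size)) * 1e-3
                spike_unit.extend(uid_list[j] for j in uunit)
                spike_trial.extend([tid] * ubin.size)
                spike_time.append(times)

    spikes = pd.DataFrame({
        "unit_id": spike_unit,
        "trial_id": spike_trial,
        "spike_time_s": np.concatenate(spike_time) if spike_time else np.empty(0),
    })
    meta = {"subject": "synthetic", "session": f"seed{cfg.seed}",
            "generator": "instaspace.synth", "n_units": dict(cfg.n_units),
            "trials_per_object": cfg.trials_per_object}
    ds = SessionDataset(units=units, trials=trials, spikes=spikes, meta=meta)
    gt = GroundTruth(unit_classes=unit_classes, schedules=schedules,
                     object_directions=directions, trial_events=trial_events,
                     trial_score_noise=trial_noise, config=cfg)
    return ds, gt
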