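"""Session data model and on-disk formats.

A *session* is one recording: a set of sorted units, a set of behavioral
trials of the delayed-response reach-grasp-manipulate (RGM) task, and the
spike times of every unit on every trial.  Trials carry an object label
(sphere, button, coax, perp), a context label (execution — the subject
performs the task — or observation — the subject watches an experimenter
perform it), and eight behavioral event markers.

Two interchangeable on-disk formats are supported: a single HDF5 file and a
csv-bundle directory (units.csv / trials.csv / spikes.csv).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

OBJECTS = ("sphere", "button", "coax", "perp")
CONTEXTS = ("execution", "observation")
AREAS = ("PMv", "PMd", "other")
QUALITIES = ("single", "probable_single", "multi")

#: Behavioral event markers in their required temporal order.
EVENT_ORDER = (
    "start",
    "instruction_on",
    "instruction_off",
    "go",
    "movement_on",
    "hold_on",
    "hold_off",
    "end",
)


class SchemaError(ValueError):
    """A file does not match the documented session schema."""


class ValidationError(ValueError):
    """A dataset violates a session invariant."""


@dataclass(frozen=True)
class UnitRecord:
    unit_id: str
    area: str = "other"
    quality: str = "single"

    def __post_init__(self) -> None:
        if self.area not in AREAS:
            raise ValidationError(f"unknown area {self.area!r} for unit {self.unit_id}")
        if self.quality not in QUALITIES:
            raise ValidationError(
                f"unknown quality {self.quality!r} for unit {self.unit_id}"
            )


@dataclass(frozen=True)
class TrialRecord:
    trial_id: str
    object: str
    context: str
    events: dict[str, float]
    success: bool = True

    def __post_init__(self) -> None:
        if self.object not in OBJECTS:
            raise ValidationError(f"unknown object {self.object!r} in {self.trial_id}")
        if self.context not in CONTEXTS:
            raise ValidationError(
                f"unknown context {self.context!r} in {self.trial_id}"
            )
        missing = [e for e in EVENT_ORDER if e not in self.events]
        if missing:
            raise ValidationError(f"trial {self.trial_id} missing events {missing}")
        times = [float(self.events[e]) for e in EVENT_ORDER]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValidationError(
                f"trial {self.trial_id}: event times not strictly increasing "
                f"in order {EVENT_ORDER}"
            )

    def duration(self, a: str, b: str) -> float:
        """Seconds between two named events."""
        return float(self.events[b]) - float(self.events[a])


@dataclass
class SessionDataset:
    """Units, trials and spikes of one session.

    ``spikes`` is a DataFrame with columns ``unit_id``, ``trial_id``,
    ``spike_time_s`` (absolute seconds on the session clock; every spike lies
    within its trial's [start, end]).
    """

    units: list[UnitRecord]
    trials: list[TrialRecord]
    spikes: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.spikes = self.spikes.reset_index(drop=True)
        self.validate()

    # -- access helpers -------------------------------------------------
    @property
    def unit_ids(self) -> list[str]:
        return [u.unit_id for u in self.units]

    @property
    def n_units(self) -> int:
        return len(self.units)

    def trial(self, trial_id: str) -> TrialRecord:
        return self._trial_map[trial_id]

    def trials_for(self, context: str, object: str | None = None,
                   successful_only: bool = True) -> list[TrialRecord]:
        out = [t for t in self.trials if t.context == context]
        if object is not None:
            out = [t for t in out if t.object == object]
        if successful_only:
            out = [t for t in out if t.success]
        return out

    def spikes_for(self, unit_id: str, trial_id: str) -> np.ndarray:
        key = (unit_id, trial_id)
        if key in self._spike_map:
            return self._spike_map[key]
        return np.empty(0)

    def subset_units(self, unit_ids: list[str]) -> "SessionDataset":
        """New dataset restricted to the given units (order preserved)."""
        keep = set(unit_ids)
        units = [u for u in self.units if u.unit_id in keep]
        spikes = self.spikes[self.spikes["unit_id"].isin(keep)]
        return SessionDataset(units=units, trials=list(self.trials),
                              spikes=spikes.copy(), meta=dict(self.meta))

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        ids = [u.unit_id for u in self.units]
        if len(ids) != len(set(ids)):
            raise ValidationError("duplicate unit_id in session")
        tids = [t.trial_id for t in self.trials]
        if len(tids) != len(set(tids)):
            raise ValidationError("duplicate trial_id in session")
        self._trial_map = {t.trial_id: t for t in self.trials}

        required = {"unit_id", "trial_id", "spike_time_s"}
        if not required.issubset(self.spikes.columns):
            raise SchemaError(
                f"spikes table missing columns {sorted(required - set(self.spikes.columns))}"
            )
        if len(self.spikes):
            unit_set = set(ids)
            bad_units = set(self.spikes["unit_id"]) - unit_set
            if bad_units:
                raise ValidationError(f"spikes reference unknown units {sorted(bad_units)[:5]}")
            bad_trials = set(self.spikes["trial_id"]) - set(tids)
            if bad_trials:
                raise ValidationError(f"spikes reference unknown trials {sorted(bad_trials)[:5]}")
            t = self.spikes["spike_time_s"].to_numpy(float)
            starts = self.spikes["trial_id"].map(
                {k: v.events["start"] for k, v in self._trial_map.items()}
            ).to_numpy(float)
            ends = self.spikes["trial_id"].map(
                {k: v.events["end"] for k, v in self._trial_map.items()}
            ).to_numpy(float)
            if np.any((t < starts) | (t > ends)):
                i = int(np.argmax((t < starts) | (t > ends)))
                raise ValidationError(
                    f"spike at {t[i]:.4f}s outside bounds of trial "
                    f"{self.spikes['trial_id'].iloc[i]!r}"
                )
        # per-(unit, trial) sorted spike arrays for fast access
        self._spike_map: dict[tuple[str, str], np.ndarray] = {}
        if len(self.spikes):
            for (u, tr), grp in self.spikes.groupby(["unit_id", "trial_id"], sort=False):
                self._spike_map[(u, tr)] = np.sort(grp["spike_time_s"].to_numpy(float))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SessionDataset):
            return NotImplemented
        if self.units != other.units or self.trials != other.trials:
            return False
        a = self.spikes.sort_values(["unit_id", "trial_id", "spike_time_s"]).reset_index(drop=True)
        b = other.spikes.sort_values(["unit_id", "trial_id", "spike_time_s"]).reset_index(drop=True)
        if len(a) != len(b):
            return False
        return (
            a["unit_id"].tolist() == b["unit_id"].tolist()
            and a["trial_id"].tolist() == b["trial_id"].tolist()
            and np.allclose(a["spike_time_s"], b["spike_time_s"], atol=1e-9)
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_TRIAL_COLUMNS = ["trial_id", "object", "context", "success"] + [
    f"t_{e}" for e in EVENT_ORDER
]


def _units_frame(ds: SessionDataset) -> pd.DataFrame:
    return pd.DataFrame(
        {"unit_id": [u.unit_id for u in ds.units],
         "area": [u.area for u in ds.units],
         "quality": [u.quality for u in ds.units]}
    )


def _trials_frame(ds: SessionDataset) -> pd.DataFrame:
    rows = []
    for t in ds.trials:
        row = {"trial_id": t.trial_id, "object": t.object, "context": t.context,
               "success": bool(t.success)}
        for e in EVENT_ORDER:
            row[f"t_{e}"] = float(t.events[e])
        rows.append(row)
    return pd.DataFrame(rows, columns=_TRIAL_COLUMNS)


def _dataset_from_frames(units_df: pd.DataFrame, trials_df: pd.DataFrame,
                         spikes_df: pd.DataFrame, meta: dict) -> SessionDataset:
    for col in ("unit_id", "area", "quality"):
        if col not in units_df.columns:
            raise SchemaError(f"units table missing column {col!r}")
    for col in _TRIAL_COLUMNS:
        if col not in trials_df.columns:
            raise SchemaError(f"trials table missing column {col!r}")
    units = [UnitRecord(str(r.unit_id), str(r.area), str(r.quality))
             for r in units_df.itertuples()]
    trials = []
    for r in trials_df.itertuples():
        events = {e: float(getattr(r, f"t_{e}")) for e in EVENT_ORDER}
        trials.append(TrialRecord(str(r.trial_id), str(r.object), str(r.context),
                                  events, bool(r.success)))
    spikes = spikes_df.copy()
    if len(spikes):
        spikes["unit_id"] = spikes["unit_id"].astype(str)
        spikes["trial_id"] = spikes["trial_id"].astype(str)
        spikes["spike_time_s"] = spikes["spike_time_s"].astype(float)
    return SessionDataset(units=units, trials=trials, spikes=spikes, meta=meta)


def write_session(dataset: SessionDataset, path: str | Path,
                  format: str = "hdf5") -> Path:
    """Write a validated session to disk (``hdf5`` or ``csv-bundle``)."""
    dataset.validate()
    path = Path(path)
    units_df, trials_df = _units_frame(dataset), _trials_frame(dataset)
    spikes_df = dataset.spikes.sort_values(
        ["unit_id", "trial_id", "spike_time_s"]
    ).reset_index(drop=True)
    if len(spikes_df) == 0:
        spikes_df = pd.DataFrame(columns=["unit_id", "trial_id", "spike_time_s"])
    meta_json = json.dumps(dataset.meta, sort_keys=True, default=str)

    if format == "hdf5":
        path.parent.mkdir(parents=True, exist_ok=True)
        with h5py.File(path, "w") as f:
            g = f.create_group("units")
            for col in units_df.columns:
                g.create_dataset(col, data=units_df[col].astype("S"))
            g = f.create_group("trials")
            for col in ("trial_id", "object", "context"):
                g.create_dataset(col, data=trials_df[col].astype("S"))
            g.create_dataset("success", data=trials_df["success"].to_numpy(bool))
            for e in EVENT_ORDER:
                g.create_dataset(f"t_{e}", data=trials_df[f"t_{e}"].to_numpy(float))
            g = f.create_group("spikes")
            g.create_dataset("unit_id", data=spikes_df["unit_id"].astype("S"))
            g.create_dataset("trial_id", data=spikes_df["trial_id"].astype("S"))
            g.create_dataset("time_s", data=spikes_df["spike_time_s"].to_numpy(float))
            f.attrs["meta_json"] = meta_json
    elif format == "csv-bundle":
        path.mkdir(parents=True, exist_ok=True)
        units_df.to_csv(path / "units.csv", index=False)
        trials_df.to_csv(path / "trials.csv", index=False)
        spikes_df.rename(columns={"spike_time_s": "spike_time_s"}).to_csv(
            path / "spikes.csv", index=False)
        (path / "meta.json").write_text(meta_json)
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def read_session(path: str | Path, format: str = "hdf5") -> SessionDataset:
    """Read and validate a session written by :func:`write_session`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "hdf5":
        with h5py.File(path, "r") as f:
            for group in ("units", "trials", "spikes"):
                if group not in f:
                    raise SchemaError(f"missing group /{group}")
            units_df = pd.DataFrame(
                {col: [s.decode() for s in f["units"][col][()]]
                 for col in ("unit_id", "area", "quality")
                 if col in f["units"]}
            )
            if set(units_df.columns) != {"unit_id", "area", "quality"} and len(f["units"]):
                missing = {"unit_id", "area", "quality"} - set(units_df.columns)
                raise SchemaError(f"units group missing datasets {sorted(missing)}")
            tg = f["trials"]
            tdata = {}
            for col in ("trial_id", "object", "context"):
                if col not in tg:
                    raise SchemaError(f"trials group missing dataset {col!r}")
                tdata[col] = [s.decode() for s in tg[col][()]]
            tdata["success"] = np.asarray(tg["success"][()], bool)
            for e in EVENT_ORDER:
                if f"t_{e}" not in tg:
                    raise SchemaError(f"trials group missing dataset t_{e}")
                tdata[f"t_{e}"] = np.asarray(tg[f"t_{e}"][()], float)
            trials_df = pd.DataFrame(tdata)
            sg = f["spikes"]
            spikes_df = pd.DataFrame(
                {"unit_id": [s.decode() for s in sg["unit_id"][()]],
                 "trial_id": [s.decode() for s in sg["trial_id"][()]],
                 "spike_time_s": np.asarray(sg["time_s"][()], float)}
            )
            meta = json.loads(f.attrs.get("meta_json", "{}"))
    elif format == "csv-bundle":
        for name in ("units.csv", "trials.csv", "spikes.csv"):
            if not (path / name).exists():
                raise SchemaError(f"csv-bundle missing {name}")
        units_df = pd.read_csv(path / "units.csv", dtype=str)
        if units_df.empty and list(units_df.columns) != ["unit_id", "area", "quality"]:
            units_df = pd.DataFrame(columns=["unit_id", "area", "quality"])
        trials_df = pd.read_csv(path / "trials.csv", float_precision="round_trip")
        spikes_df = pd.read_csv(path / "spikes.csv", float_precision="round_trip")
        if spikes_df.empty:
            spikes_df = pd.DataFrame(columns=["unit_id", "trial_id", "spike_time_s"])
        meta_path = path / "meta.json"
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    else:
        raise ValueError(f"unknown format {format!r}")
    if trials_df.empty:
        trials_df = pd.DataFrame(columns=_TRIAL_COLUMNS)
    return _dataset_from_frames(units_df, trials_df, spikes_df, meta)
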