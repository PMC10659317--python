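"""Generate a synthetic delayed reach-grasp-manipulate session and save it.

The generator plants everything the downstream analyses look for: four
neuron classes (mirror, execution-only, observation-only, unmodulated), a
condition-dependent subspace that drifts between event-anchored loadings,
object separation that grows over the trial, and weaker observation-context
modulation.
"""

from pathlib import Path

from instaspace import SynthConfig, generate_session, write_session

cfg = SynthConfig(
    n_units={"MN": 16, "AE": 6, "AO": 2, "NS": 4},
    trials_per_object=10,
    seed=1,
)
session, truth = generate_session(cfg)

out = Path("scratch/example_session")
out.mkdir(parents=True, exist_ok=True)
write_session(session, out / "session.h5", "hdf5")
write_session(session, out / "bundle", "csv-bundle")

n_exec = len(session.trials_for("execution"))
n_obs = len(session.trials_for("observation"))
print(f"units: {session.n_units}  "
      f"(planted classes: { {c: sum(1 for v in truth.unit_classes.values() if v == c) for c in ('MN', 'AE', 'AO', 'NS')} })")
print(f"trials: {n_exec} execution + {n_obs} observation")
print(f"spikes: {len(session.spikes)}")
print(f"wrote HDF5 and csv-bundle under {out}/")
# The two files hold identical content; read_session() restores either
# bit-for-bit, so sessions can move between tools without loss.
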