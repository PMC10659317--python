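"""Event-aligned rate tensors and mirror-neuron identification.

Spike trains are binned at 1 ms, smoothed (Gaussian, sigma = 50 ms),
square-root transformed, and cut into four event-aligned snippets
(instruction onset, go cue, movement onset, hold start) that are
concatenated on a common time axis.  A two-way ANOVA (object x period) on
spike counts in eleven 200-ms windows classifies each unit per context at
alpha = 0.05/6.
"""

from collections import Counter

from instaspace import SynthConfig, align_and_concatenate, classify_units, \
    generate_session

session, truth = generate_session(
    SynthConfig(n_units={"MN": 12, "AE": 6, "AO": 2, "NS": 3},
                trials_per_object=40, seed=2))

tensor = align_and_concatenate(session, "execution")
shapes = {o: r.shape for o, r in tensor.rates.items()}
print(f"tensor (N x K x T) per object: {shapes}")
print(f"event sample indices on the concatenated axis: {tensor.event_index}")
print(f"pooled median durations (s): "
      f"{ {k: round(v, 3) for k, v in tensor.windows.pooled.items()} }")

result = classify_units(session)
print(f"assigned classes: {Counter(result.classes.values())}")
agreement = sum(result.classes[u] == truth.unit_classes[u]
                for u in session.unit_ids) / session.n_units
print(f"agreement with planted classes: {agreement:.0%}")
# Mirror neurons (MN) are task-modulated in both contexts; AE only during
# execution.  With 40 trials per object the ANOVA recovers the planted
# classes for the large majority of units.
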