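"""Pulse frequency sets the timing of the quorum-sensing response.

Every expression pulse releases a quantum of autoinducer into a shared,
decaying pool; the response triggers when the pool reaches a threshold.
With a growing population, strains pulsing more frequently cross the
threshold hours earlier and at smaller colony sizes.
"""

from pulsekit import response

pop = response.logistic_population(n0=50.0, rate=0.23, capacity=1e5)
config = response.ResponseConfig(ahl_per_pulse=1.0, ahl_decay=0.1,
                                 threshold=500.0, population=pop,
                                 horizon=100.0)

table = response.onset_vs_frequency([0.004, 0.028, 0.28], config)
print(table.to_string(index=False,
                      formatters={"onset_h": "{:.1f}".format,
                                  "n_at_onset": "{:.0f}".format}))
# onset_h: first threshold crossing (h); n_at_onset: cells at that moment.
# Onset decreases and the colony size at onset shrinks as frequency rises.
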