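"""Population summaries: spot fractions, gated fractions, correlation.

Single-molecule spot counting (fraction of cells with a detection above a
photon threshold), flow-cytometry-style positive gating against a
fluorophore-free control, and the linear correlation between spot fraction
and pulse frequency across conditions.
"""

import numpy as np

from pulsekit import popstats, synthetic

# ~10% of cells carry one bright spot; all cells show dim background
field = synthetic.simulate_spot_field(n_cells=2000, spot_fraction=0.10,
                                      photon_mean=100.0, photon_sd=10.0,
                                      bg_photon_mean=5.0, seed=3)
frac = popstats.spot_fraction(field, threshold=20.0)
print(f"spot-bearing cells: {100 * frac:.1f}% (generative 10%)")

rng = np.random.default_rng(0)
control = rng.lognormal(4.0, 0.3, size=30000)
sample = np.concatenate([rng.lognormal(4.0, 0.3, size=27000),
                         rng.lognormal(6.0, 0.3, size=3000)])
gate = popstats.fraction_positive(rng.permutation(sample), control, seed=1)
print(f"gated positive fraction: {100 * gate.fraction_positive:.1f}% "
      f"(10% bright subpopulation; gate at {gate.gate:.0f})")

# abundance of the scarce activator vs pulse frequency across conditions
spots = np.array([0.015, 0.10, 0.24])        # fraction of cells with spots
freqs = np.array([0.004, 0.028, 0.084])      # pulses / h / cell
corr = popstats.linear_correlation(spots, freqs)
print(f"spot fraction vs pulse frequency: r^2 = {corr.r_squared:.3f}, "
      f"slope = {corr.slope:.3f}")
# a high r^2 supports frequency (not amplitude) encoding activator abundance
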