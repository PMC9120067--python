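"""Calibrate the fluorophore degradation/bleaching constant gamma.

In cells with no discernible promoter activity the expression-rate balance
reduces to gamma = -r - d[log M]/dt: the mean intensity decays only by
dilution (growth) and degradation.  51 simulated non-expressing cells with
5% measurement noise recover the generative gamma.
"""

import numpy as np

from pulsekit import rates, synthetic

records, true_rates = synthetic.simulate_dark_cells(
    n_cells=51, m0=500.0, gamma=0.0015, noise_cv=0.05, dt=20.0,
    n_frames=30, seed=7)

est = rates.estimate_gamma_from_records(records)
print(f"cells used: {est.n_cells}")
print(f"gamma estimate: {est.gamma:.5f} 1/min (generative 0.00150)")
print(f"per-cell spread: sd = {np.std(est.per_cell):.5f} 1/min")
# the pooled estimate averages per-frame values over all cells; per-cell
# scatter reflects the windowed log-M regression noise at 5% intensity noise
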