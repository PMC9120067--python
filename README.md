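# pulsekit

Single-cell time-lapse analysis of **pulsatile gene expression** in growing
bacterial microcolonies, built around the quorum-sensing autoinducer
synthase reporter of *Sinorhizobium meliloti*: rather than expressing the
synthase gene continuously, individual cells fire short, stochastic
expression pulses, and regulation acts on the pulse *frequency* (from
~0.004 to ~0.28 pulses per hour and cell across strains) while pulse
amplitude stays roughly constant.

The package is for researchers analysing tracked fluorescence time-lapse
movies of microcolonies — or benchmarking such analyses — and provides the
full chain from segmentation post-processing to per-colony pulse
statistics, plus a ground-truth simulator so that every stage can be
validated by parameter recovery without any external data.

## What it computes

**Expression rate.** Fluorescent reporters are stable, so the level M
(mean intensity per cell, a per-unit-length concentration) integrates past
expression. The promoter activity per unit cell length is reconstructed as

    P̃ = r·M + γ·M + dM/dt

where `r` is the elongation rate (sliding-window regression of log cell
length, 11 frames = 200 min at 20-min imaging), `γ` the fluorophore
degradation/bleaching constant (default 0.0015 1/min, calibrated from
non-expressing cells via `γ = −r − d[log M]/dt`), and `dM/dt` a windowed
regression slope. Length and intensity series are stitched across division
events (daughter sums / birth-length fractions) so windows can span
divisions.

**Pulse detection.** For every cell in the last frame, the
founder-to-focal *backward lineage* is scanned for local maxima of P̃; a
candidate is kept when its **backward prominence** — the rise above the
lowest P̃ since the last accepted pulse, or since the movie start — exceeds
6 intensity/min. Duplicate detections from lineages sharing ancestors are
removed on the (cell, frame) apex. The per-colony pulse frequency is

    f_pulse = N_pulse / (dt · Σᵢ nᵢ)

pulses per cell-hour, with `nᵢ` the number of cells present at frame i.

**Around the core** sit imaging photometry (probability-map
post-processing, centerline arc-length cell geometry, shading /
Lucy-Richardson / background corrections, eroded-mask mean intensities),
population statistics (flow-cytometry-style positive gating, single-
molecule spot fractions, correlation and fold-change summaries), a
one-phase exponential decay fit for protein half-lives, a minimal
autoinducer-pool model linking pulse frequency to quorum-sensing response
onset, and the microcolony simulator with strain presets
(`expr_minus` 0.028, `wild_type` 0.28, `psinr_star` 0.028/7,
`nurr_pp` 0.028×3 pulses·h⁻¹·cell⁻¹).

## Worked example

```python
from pulsekit import pulses, rates, synthetic

config = synthetic.preset("expr_minus", seed=4)     # 0.028 pulses/h/cell
colony, truth = synthetic.simulate_colony(config)

table = rates.colony_rate_table(colony, gamma=config.gamma)
detected = pulses.detect_pulses(colony, table, threshold=6.0)
summary = pulses.pulse_frequency(colony, detected)
```

prints (via `python examples/simulate_and_detect.py`):

```
colony: 85 cells over 46 frames (185 cell-hours)
ground truth: 7 pulses (0.0378 /h/cell)
detected:     7 pulses, f_pulse = 0.0378 /h/cell, median amplitude 16.4 intensity/min
```

All 7 ground-truth pulses are found; the frequency (pulses per cell-hour
of observation) matches the realized ground-truth rate of this colony
exactly, and sits within Poisson sampling error of the 0.028 /h preset.
The scripts in `examples/` walk through each capability the same way:
γ calibration, half-life fitting, image photometry, gating/spot fractions,
and response-onset modelling. A thin CLI covers the shell workflows:
`pulsekit simulate --preset expr_minus --colonies 9 --seed 1 --out DIR`
and `pulsekit run config.json`.

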