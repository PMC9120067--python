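"""Pulse detection on backward lineages and per-colony pulse frequency.

A pulse is a transient increase in the expression rate P_tilde.  Because a
pulse can outlive a cell (beginning in a mother and continuing in one or
both daughters), detection runs on *backward lineages*: for every cell
present in the last frame, the founder-to-focal chain of per-frame
P_tilde estimates.  On each lineage:

1. all strict local maxima are candidate pulses (plateaus yield their
   first frame; series endpoints are never peaks);
2. candidates are accepted left to right when their *backward prominence*
   — the rise relative to the lowest P_tilde since the last accepted
   pulse, or since the start of the movie — exceeds the detection
   threshold (default 6 intensity/min).

Cells early in the colony belong to many lineages, so the same pulse is
found repeatedly; duplicates are removed on the (cell, frame) apex.  The
per-colony pulse frequency is

    f_pulse = N_pulse / (dt * sum_i n_i),

pulses per cell-hour, where n_i is the number of cells present at frame i:
the denominator is the total observation time of a growing colony.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lineage import Colony, ExtendedLineage, backward_lineages, cells_per_frame

__all__ = [
    "Pulse",
    "PulseSummary",
    "backward_prominence",
    "candidate_peaks",
    "detect_pulses",
    "lineage_series",
    "pulse_frequency",
    "threshold_sensitivity",
]

DEFAULT_THRESHOLD = 6.0  # intensity / min, backward prominence


@dataclass(frozen=True)
class Pulse:
    """One deduplicated expression pulse."""

    colony_id: str
    cell_id: int
    frame: int                      # apex of P_tilde
    time_min: float
    prominence_backward: float      # rise since last pulse / movie start
    height: float                   # absolute P_tilde at the apex
    time_since_last: float | None   # min; None for the first pulse on a lineage


@dataclass
class PulseSummary:
    """Per-colony pulse statistics."""

    colony_id: str
    n_pulses: int
    f_pulse: float          # pulses / h / cell
    median_amplitude: float
    threshold: float


def candidate_peaks(series: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima of a series that may contain NaNs.

    Runs of equal values count once, at their first index; a peak must
    exceed the nearest defined value on both sides, so endpoints (and
    plateaus touching them) are never peaks.  NaN frames are skipped: a
    peak cannot sit on an undefined frame, and comparisons are made against
    the nearest defined neighbours.
    """
    s = np.asarray(series, dtype=float)
    idx = np.nonzero(np.isfinite(s))[0]
    if idx.size < 3:
        return np.empty(0, dtype=int)
    vals = s[idx]
    # compress runs of equal consecutive defined values
    starts = [0]
    for j in range(1, vals.size):
        if vals[j] != vals[starts[-1]]:
            starts.append(j)
    peaks = []
    for pos in range(1, len(starts) - 1):
        v = vals[starts[pos]]
        if vals[starts[pos - 1]] < v and v > vals[starts[pos + 1]]:
            peaks.append(idx[starts[pos]])
    return np.asarray(peaks, dtype=int)


def backward_prominence(series: np.ndarray, apex: int,
                        previous_pulse_apex: int | None = None) -> float:
    """Rise of ``series[apex]`` above its minimum since the previous pulse.

    The minimum is taken over frames in ``(previous_pulse_apex, apex]``,
    or from the start of the series when there is no previous pulse;
    undefined (NaN) frames are ignored.
    """
    s = np.asarray(series, dtype=float)
    lo = 0 if previous_pulse_apex is None else previous_pulse_apex + 1
    window = s[lo:apex + 1]
    return float(s[apex] - np.nanmin(window))


def lineage_series(lineage: ExtendedLineage,
                   rate_table: pd.DataFrame,
                   n_frames: int) -> tuple[np.ndarray, np.ndarray]:
    """P_tilde series (length ``n_frames``, NaN where undefined) and the
    owning cell id per frame (-1 outside the lineage) for one lineage."""
    key = rate_table.set_index(["cell_id", "frame"])["P_tilde"]
    s = np.full(n_frames, np.nan)
    owner = np.full(n_frames, -1, dtype=int)
    for f, cid in zip(lineage.frames, lineage.cell_at_frame):
        s[f] = key.get((int(cid), int(f)), np.nan)
        owner[f] = cid
    return s, owner


def detect_pulses(colony: Colony, rate_table: pd.DataFrame,
                  threshold: float = DEFAULT_THRESHOLD,
                  merge_sibling_apexes: bool = False) -> list[Pulse]:
    """Detect, threshold and deduplicate pulses over all backward lineages.

    On each lineage candidates are accepted sequentially: the backward
    prominence of a candidate is computed against the last *accepted* pulse,
    so sub-threshold wiggles do not reset the baseline.  Duplicate
    detections of one pulse from lineages sharing a prefix collapse on the
    (cell, frame) apex.

    ``merge_sibling_apexes`` additionally collapses apexes detected in two
    sister cells within one frame of their birth and within two frames of
    each other — the signature of a single pulse continuing through a
    division.  Off by default: the standard deduplication is the documented
    behaviour, and the extra rule is a conservative option.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    key = rate_table.set_index(["cell_id", "frame"])["P_tilde"]
    detections: dict[tuple[int, int], Pulse] = {}
    for lineage in backward_lineages(colony):
        s = np.full(colony.n_frames, np.nan)
        owner = np.full(colony.n_frames, -1, dtype=int)
        for f, cid in zip(lineage.frames, lineage.cell_at_frame):
            s[f] = key.get((int(cid), int(f)), np.nan)
            owner[f] = cid
        last_apex: int | None = None
        for apex in candidate_peaks(s):
            prom = backward_prominence(s, int(apex), last_apex)
            if prom > threshold:
                cid = int(owner[apex])
                t_apex = float(apex * colony.dt)
                tsl = None if last_apex is None else t_apex - last_apex * colony.dt
                pulse = Pulse(colony.colony_id, cid, int(apex), t_apex,
                              prom, float(s[apex]), tsl)
                detections.setdefault((cid, int(apex)), pulse)
                last_apex = int(apex)
    pulses = sorted(detections.values(), key=lambda p: (p.frame, p.cell_id))

    if merge_sibling_apexes:
        kept: list[Pulse] = []
        for p in pulses:
            cell = colony.cells[p.cell_id]
            dup = False
            for q in kept:
                if q.cell_id == p.cell_id:
                    continue
                other = colony.cells[q.cell_id]
                if (cell.parent_id is not None
                        and cell.parent_id == other.parent_id
                        and abs(p.frame - cell.first_frame) <= 1
                        and abs(q.frame - other.first_frame) <= 1
                        and abs(p.frame - q.frame) <= 2):
                    dup = True
                    break
            if not dup:
                kept.append(p)
        pulses = kept
    return pulses


def pulse_frequency(colony: Colony, pulses: list[Pulse],
                    threshold: float = DEFAULT_THRESHOLD) -> PulseSummary:
    """Per-colony pulse frequency f = N / (dt_h * sum_i n_i) and amplitude."""
    n_i = cells_per_frame(colony)
    total = int(n_i.sum())
    if total == 0:
        raise ValueError("colony has no observed cell-frames")
    dt_h = colony.dt / 60.0
    f = len(pulses) / (dt_h * total)
    med = float(np.median([p.height for p in pulses])) if pulses else float("nan")
    return PulseSummary(colony_id=colony.colony_id, n_pulses=len(pulses),
                        f_pulse=f, median_amplitude=med, threshold=threshold)


def threshold_sensitivity(colonies: list[Colony],
                          rate_tables: list[pd.DataFrame],
                          thresholds: list[float]) -> pd.DataFrame:
    """Pulse frequency per colony for each detection threshold.

    Thresholds are deduplicated and sorted; frequencies are monotone
    non-increasing in the threshold by construction.
    """
    if len(colonies) != len(rate_tables):
        raise ValueError("need one rate table per colony")
    thr = sorted(set(float(t) for t in thresholds))
    rows = []
    for colony, table in zip(colonies, rate_tables):
        for t in thr:
            pulses = detect_pulses(colony, table, threshold=t)
            summ = pulse_frequency(colony, pulses, threshold=t)
            rows.append((colony.colony_id, t, summ.n_pulses, summ.f_pulse))
    return pd.DataFrame(rows, columns=["colony_id", "threshold", "n_pulses",
                                       "f_pulse"])
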