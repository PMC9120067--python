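"""Pulse detection: peaks, backward prominence, dedup, frequency."""

import numpy as np
import pandas as pd
import pytest

from pulsekit import pulses as pl
from pulsekit import rates, synthetic
from pulsekit.lineage import backward_lineages, cells_per_frame
from pulsekit.pulses import (backward_prominence, candidate_peaks,
                             detect_pulses, pulse_frequency,
                             threshold_sensitivity)
from .conftest import build_binary_tree_colony


# ---------------------------------------------------------------------------
# candidate peaks

def _brute_force_peaks(s):
    """Independent scan: compress equal runs of defined values; a run is a
    peak when both neighbouring runs are lower; boundary runs never are."""
    idx = [i for i in range(len(s)) if np.isfinite(s[i])]
    runs = []
    for i in idx:
        if runs and s[i] == s[runs[-1][0]]:
            runs[-1].append(i)
        else:
            runs.append([i])
    out = []
    for j in range(1, len(runs) - 1):
        v = s[runs[j][0]]
        if s[runs[j - 1][0]] < v and v > s[runs[j + 1][0]]:
            out.append(runs[j][0])
    return np.asarray(out, dtype=int)


@pytest.mark.parametrize("series,expected", [
    ([0, 1, 2, 3, 4], []),                    # monotone: no candidates
    ([0, 3, 9, 4, 1], [2]),
    ([0, 5, 5, 1], [1]),                      # plateau -> first index
    ([5, 1, 0, 1, 5], []),                    # endpoints are not peaks
    ([0, np.nan, 4, 1, 0], [2]),
    ([0, 9, np.nan, 1, 0], [1]),              # compares to nearest defined
])
def test_candidate_peaks_cases(series, expected):
    assert candidate_peaks(np.asarray(series, float)).tolist() == expected


def test_candidate_peaks_match_brute_force_on_random_series():
    rng = np.random.default_rng(123)
    for _ in range(1000):
        n = rng.integers(5, 200)
        s = rng.normal(size=n)
        s[rng.random(n) < 0.05] = np.nan
        np.testing.assert_array_equal(candidate_peaks(s),
                                      _brute_force_peaks(s))


# ---------------------------------------------------------------------------
# backward prominence

def test_backward_prominence_from_series_start():
    assert backward_prominence(np.array([0.0, 2.0, 10.0]), 2) == 10.0


def test_backward_prominence_since_previous_pulse():
    s = np.array([0.0, 8.0, 3.0, 5.0, 10.0])
    assert backward_prominence(s, 4, previous_pulse_apex=1) == 7.0


def test_backward_prominence_matches_min_scan_on_random_series():
    rng = np.random.default_rng(7)
    for _ in range(1000):
        n = rng.integers(10, 120)
        s = rng.normal(size=n)
        peaks = candidate_peaks(s)
        prev = None
        for apex in peaks:
            lo = 0 if prev is None else prev + 1
            expected = s[apex] - np.min(s[lo:apex + 1])
            assert backward_prominence(s, apex, prev) == pytest.approx(expected)
            prev = apex


# ---------------------------------------------------------------------------
# detection and dedup on hand-built colonies

def _flat_rate_table(colony, spikes):
    """P_tilde = 0 everywhere except the given {(cell_id, frame): value}."""
    rows = []
    for cid, cell in colony.cells.items():
        for f in cell.frames:
            rows.append((colony.colony_id, cid, int(f), f * colony.dt,
                         0.0, 0.0, 0.0, spikes.get((cid, int(f)), 0.0)))
    return pd.DataFrame(rows, columns=["colony_id", "cell_id", "frame",
                                       "time_min", "r", "M", "dMdt",
                                       "P_tilde"])


def test_shared_mother_pulse_detected_once():
    colony = build_binary_tree_colony(rounds=1, frames_per_gen=5)
    table = _flat_rate_table(colony, {(1, 2): 20.0})
    det = detect_pulses(colony, table, threshold=6.0)
    assert len(det) == 1
    assert (det[0].cell_id, det[0].frame) == (1, 2)


def test_subthreshold_series_yields_no_pulses():
    colony = build_binary_tree_colony(rounds=1, frames_per_gen=5)
    table = _flat_rate_table(colony, {(1, 2): 5.9})
    assert detect_pulses(colony, table, threshold=6.0) == []


def test_nonpositive_threshold_rejected(tree_colony):
    table = _flat_rate_table(tree_colony, {})
    with pytest.raises(ValueError):
        detect_pulses(tree_colony, table, threshold=0.0)


def test_prominence_measured_against_last_accepted_pulse():
    """A sub-threshold wiggle must not reset the baseline."""
    colony = build_binary_tree_colony(rounds=0, frames_per_gen=12)
    # apex 20 at frame 2; bump 16 at frame 5 (prominence 2, rejected);
    # bump 9 at frame 9 (prominence 8 vs the min since frame 2 -> accepted)
    series = [0.0, 10.0, 20.0, 14.0, 14.0, 16.0, 2.0, 1.0, 5.0, 9.0, 3.0, 0.0]
    table = _flat_rate_table(colony, {(1, f): series[f] for f in range(12)})
    det = detect_pulses(colony, table, threshold=6.0)
    assert [(p.frame, round(p.prominence_backward, 6)) for p in det] == \
        [(2, 20.0), (9, 8.0)]
    assert det[1].time_since_last == pytest.approx((9 - 2) * colony.dt)


def test_detection_idempotent_and_label_invariant(noiseless_colony):
    colony, _ = noiseless_colony
    table = rates.colony_rate_table(colony, gamma=0.0015)
    det1 = detect_pulses(colony, table, threshold=6.0)
    det2 = detect_pulses(colony, table, threshold=6.0)
    assert [(p.cell_id, p.frame) for p in det1] == \
        [(p.cell_id, p.frame) for p in det2]

    # relabel cell ids: frequency and apex frames/prominences are unchanged
    mapping = {cid: 1000 - cid for cid in colony.cells}
    from pulsekit.lineage import CellRecord, Colony
    cells = {}
    for cid, c in colony.cells.items():
        cells[mapping[cid]] = CellRecord(
            cell_id=mapping[cid],
            parent_id=None if c.parent_id is None else mapping[c.parent_id],
            daughter_ids=tuple(sorted(mapping[d] for d in c.daughter_ids)),
            frames=c.frames, time_min=c.time_min, length=c.length,
            mean_intensity=c.mean_intensity)
    relabeled = Colony(colony.colony_id, colony.dt, colony.n_frames, cells)
    table2 = table.copy()
    table2["cell_id"] = table2["cell_id"].map(mapping)
    det3 = detect_pulses(relabeled, table2, threshold=6.0)
    assert sorted((p.frame, round(p.prominence_backward, 9)) for p in det3) == \
        sorted((p.frame, round(p.prominence_backward, 9)) for p in det1)
    assert pulse_frequency(relabeled, det3).f_pulse == \
        pytest.approx(pulse_frequency(colony, det1).f_pulse)


def test_simulated_pulses_recovered_near_truth():
    """Interior high-SNR ground-truth pulses are each matched by a detection
    within the pulse's (regression-broadened) time window."""
    matched = unmatched_gt = surplus = 0
    t_guard = 160.0   # min before movie end where edge losses begin
    for seed in range(1, 10):
        cfg = synthetic.preset("expr_minus", seed=seed)
        colony, gt = synthetic.simulate_colony(cfg)
        table = rates.colony_rate_table(colony, gamma=cfg.gamma)
        det = detect_pulses(colony, table, threshold=6.0)
        t_end = (colony.n_frames - 1) * colony.dt
        used = set()

        def subtree(cid):
            out, stack = {cid}, [cid]
            while stack:
                c = stack.pop()
                for d in colony.cells[c].daughter_ids:
                    out.add(d)
                    stack.append(d)
            par = colony.cells[cid].parent_id
            if par is not None:
                out.add(par)
            return out

        gt_pulses = [(cid, t_on) for cid, onsets in gt.pulse_onsets.items()
                     if cid in colony.cells for t_on in onsets]
        # interior ground-truth pulses must each be found ...
        for cid, t_on in gt_pulses:
            if t_on > t_end - t_guard:
                continue
            near = subtree(cid)
            hits = [i for i, p in enumerate(det)
                    if i not in used and p.cell_id in near
                    and t_on - 60 <= p.time_min <= t_on + 140]
            if hits:
                used.add(hits[0])
                matched += 1
            else:
                unmatched_gt += 1
        # ... while remaining detections may match late pulses; anything
        # left over is a genuine false positive
        for cid, t_on in gt_pulses:
            if t_on <= t_end - t_guard:
                continue
            near = subtree(cid)
            hits = [i for i, p in enumerate(det)
                    if i not in used and p.cell_id in near
                    and t_on - 60 <= p.time_min <= t_on + 140]
            if hits:
                used.add(hits[0])
        surplus += len(det) - len(used)
    assert matched >= 20
    assert unmatched_gt <= 0.1 * matched
    assert surplus <= 0.15 * matched


# ---------------------------------------------------------------------------
# frequency

def test_pulse_frequency_formula():
    colony = build_binary_tree_colony(rounds=2, frames_per_gen=5, dt=20.0)
    n_total = int(cells_per_frame(colony).sum())
    table = _flat_rate_table(colony, {(1, 2): 20.0, (2, 7): 30.0})
    det = detect_pulses(colony, table, threshold=6.0)
    summ = pulse_frequency(colony, det)
    assert summ.n_pulses == 2
    assert summ.f_pulse == pytest.approx(2.0 / ((20.0 / 60.0) * n_total))
    assert summ.median_amplitude == pytest.approx(25.0)


def test_zero_pulses_zero_frequency(tree_colony):
    summ = pulse_frequency(tree_colony, [])
    assert summ.f_pulse == 0.0 and summ.n_pulses == 0


def test_threshold_sensitivity_monotone(noiseless_colony):
    colony, _ = noiseless_colony
    table = rates.colony_rate_table(colony, gamma=0.0015)
    df = threshold_sensitivity([colony], [table], [8.0, 4.0, 6.0, 4.0, 1e9])
    assert df["threshold"].tolist() == [4.0, 6.0, 8.0, 1e9]
    f = df["f_pulse"].to_numpy()
    assert np.all(np.diff(f) <= 1e-12)
    assert f[-1] == 0.0


def test_preset_frequency_ordering():
    """Estimated frequencies across strain presets preserve the generative
    ordering psinr_star < expr_minus < nurr_pp < wild_type."""
    means = {}
    for name in ("psinr_star", "expr_minus", "nurr_pp", "wild_type"):
        fs = []
        for seed in (31, 32, 33):
            cfg = synthetic.preset(name, seed=seed)
            colony, _ = synthetic.simulate_colony(cfg)
            table = rates.colony_rate_table(colony, gamma=cfg.gamma)
            det = detect_pulses(colony, table, threshold=6.0)
            fs.append(pulse_frequency(colony, det).f_pulse)
        means[name] = np.mean(fs)
    assert means["psinr_star"] < means["expr_minus"] < means["wild_type"]
    assert means["expr_minus"] < means["nurr_pp"]
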