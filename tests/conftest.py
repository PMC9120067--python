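import math

import numpy as np
import pytest

from pulsekit.lineage import CellRecord, Colony


def build_binary_tree_colony(rounds: int = 3, frames_per_gen: int = 5,
                             dt: float = 20.0,
                             intensity: float = 50.0) -> Colony:
    """Complete binary lineage tree with exact exponential growth.

    Every generation lives ``frames_per_gen`` frames; lengths double over
    one generation (growth rate ln2 / (frames_per_gen * dt)) and split
    exactly in half at division, so extended log-length is globally linear
    in time.  Intensity is constant everywhere.
    """
    r = math.log(2) / (frames_per_gen * dt)
    n_frames = (rounds + 1) * frames_per_gen
    cells: dict[int, CellRecord] = {}
    specs = {1: (None, 0, 1.0)}  # cell_id -> (parent, generation, birth length)
    next_id = 2
    frontier = [1]
    for gen in range(rounds):
        new_frontier = []
        for cid in frontier:
            parent, g, lb = specs[cid]
            l_div = lb * 2.0 ** ((frames_per_gen * dt) * r / math.log(2))
            for _ in range(2):
                specs[next_id] = (cid, g + 1, l_div / 2.0)
                new_frontier.append(next_id)
                next_id += 1
        frontier = new_frontier
    daughters: dict[int, list[int]] = {cid: [] for cid in specs}
    for cid, (parent, _g, _lb) in specs.items():
        if parent is not None:
            daughters[parent].append(cid)
    for cid, (parent, g, lb) in specs.items():
        f0 = g * frames_per_gen
        frames = np.arange(f0, f0 + frames_per_gen)
        times = frames * dt
        lengths = lb * np.exp(r * (times - f0 * dt))
        cells[cid] = CellRecord(
            cell_id=cid, parent_id=parent,
            daughter_ids=tuple(sorted(daughters[cid])),
            frames=frames, time_min=times, length=lengths,
            mean_intensity=np.full(frames_per_gen, intensity))
    return Colony(colony_id="tree", dt=dt, n_frames=n_frames, cells=cells)


@pytest.fixture(scope="session")
def tree_colony() -> Colony:
    return build_binary_tree_colony(rounds=3, frames_per_gen=5)


@pytest.fixture(scope="session")
def noiseless_colony():
    """A small noise-free simulated colony with a few high-SNR pulses."""
    from pulsekit.synthetic import SimConfig, simulate_colony

    cfg = SimConfig(pulse_rate=0.5, noise_cv=0.0, additive_noise_sd=0.0,
                    n_frames=30, seed=42)
    return simulate_colony(cfg)
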