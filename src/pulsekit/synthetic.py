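"""Ground-truth generators for testing the pulse-analysis pipeline.

The central generator, :func:`simulate_colony`, grows a microcolony of
rod-shaped cells in continuous time: each cell elongates exponentially at a
rate drawn once at birth, divides when it reaches a (noisy) trigger length,
and splits its length between two daughters.  Gene expression pulses
initiate per cell as a Poisson process; while a pulse is active the
per-unit-length production rate P_tilde equals ``pulse_activity`` and is
zero otherwise.  Mean fluorescence intensity M (a per-unit-length
concentration) then follows

    dM/dt = P_tilde - (r + gamma) * M,

i.e. production minus dilution by growth and fluorophore degradation /
bleaching; the linear ODE is solved piecewise analytically between events,
so there is no integrator error.  Observations are taken every ``dt``
minutes with multiplicative lognormal and additive Gaussian measurement
noise on M.

Ground truth (all latent quantities: pulse onset times, noiseless M, true
per-cell elongation rates) is returned alongside the colony so every
downstream stage can be validated by parameter recovery.

Named presets pin the per-cell pulse initiation rates to the frequencies
measured for the quorum-sensing synthase reporter in *S. meliloti*:
``expr_minus`` 0.028 h^-1 (receptor-free strain), ``wild_type`` 0.28 h^-1,
``psinr_star`` 0.028/7 (weakened activator-promoter), ``nurr_pp`` 0.028*3
(activator overproduction).
"""

from __future__ import annotations

import heapq
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .lineage import CellRecord, Colony

__all__ = [
    "PRESET_PULSE_RATES",
    "GroundTruth",
    "SimConfig",
    "preset",
    "simulate_colony",
    "simulate_dark_cells",
    "simulate_decay_curve",
    "simulate_spot_field",
    "render_frames",
]

#: Per-cell pulse initiation rates (pulses / h / cell) for the named strains.
PRESET_PULSE_RATES = {
    "expr_minus": 0.028,
    "wild_type": 0.28,
    "psinr_star": 0.028 / 7.0,
    "nurr_pp": 0.028 * 3.0,
    #: spot-bearing cell fraction observed by single-molecule microscopy
}

#: Fraction of cells carrying a fluorophore-tagged activator spot at a time.
SPOT_FRACTION_PRESET = 0.10


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for a simulated microcolony.

    Units: times and durations in minutes, rates per minute unless noted;
    ``pulse_rate`` is in pulses per hour per cell, matching how pulse
    frequencies are reported.
    """

    pulse_rate: float = 0.028          # pulses / h / cell (Poisson initiation)
    pulse_duration: float = 40.0       # min (2 frames at dt=20)
    pulse_activity: float = 50.0       # intensity / min while a pulse is on
    gamma: float = 0.0015              # 1/min, fluorophore degradation+bleaching
    elong_rate_mean: float = math.log(2) / 180.0  # 1/min (~3 h doubling)
    elong_rate_cv: float = 0.15
    division_length: float = 40.0      # px; trigger length
    division_length_cv: float = 0.07   # relative trigger noise
    division_fraction_sd: float = 0.03  # asymmetry of the daughter split
    dt: float = 20.0                   # min between frames
    n_frames: int = 46                 # ~15 h movies
    noise_cv: float = 0.05             # multiplicative measurement noise on M
    additive_noise_sd: float = 0.5     # intensity units
    founder_intensity: float = 0.0     # M of the founder at t = 0
    max_cells: int = 256               # single-layer cap
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if not (0 <= self.division_fraction_sd < 0.5):
            raise ValueError("division_fraction_sd must be in [0, 0.5)")
        for name in ("pulse_rate", "pulse_duration", "pulse_activity", "gamma",
                     "elong_rate_mean", "elong_rate_cv", "division_length",
                     "division_length_cv", "noise_cv", "additive_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def preset(name: str, **overrides) -> SimConfig:
    """A :class:`SimConfig` whose pulse rate matches a named strain."""
    if name not in PRESET_PULSE_RATES:
        raise KeyError(f"unknown preset {name!r}; choices: "
                       f"{sorted(PRESET_PULSE_RATES)}")
    return SimConfig(pulse_rate=PRESET_PULSE_RATES[name], **overrides)


@dataclass
class GroundTruth:
    """Latent quantities of a simulated colony, for recovery tests."""

    pulse_onsets: dict[int, list[float]]            # cell_id -> onset times (min)
    true_length: dict[int, np.ndarray]              # cell_id -> per-frame L
    true_intensity: dict[int, np.ndarray]           # cell_id -> noiseless M
    true_rate: dict[int, float]                     # cell_id -> elongation rate
    cell_hours: float                               # sum_i n_i * dt / 60
    division_time: dict[int, float] = field(default_factory=dict)
    division_length: dict[int, float] = field(default_factory=dict)
    birth_length: dict[int, float] = field(default_factory=dict)

    @property
    def n_pulses(self) -> int:
        return sum(len(v) for v in self.pulse_onsets.values())

    @property
    def pulse_rate_per_cell_hour(self) -> float:
        return self.n_pulses / self.cell_hours


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given mean and coefficient of
    variation."""
    sigma2 = math.log(1.0 + cv * cv)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def _merge_intervals(intervals: list[list[float]]) -> list[list[float]]:
    out: list[list[float]] = []
    for a, b in sorted(intervals):
        if out and a <= out[-1][1]:
            out[-1][1] = max(out[-1][1], b)
        else:
            out.append([a, b])
    return out


def _integrate_m(m0: float, t0: float, t1: float, k: float, activity: float,
                 intervals: list[list[float]], times: np.ndarray) -> tuple[float, np.ndarray]:
    """Solve dM/dt = P(t) - k M on [t0, t1] with P piecewise constant.

    P(t) = activity inside the given (merged, sorted) intervals, else 0.
    Returns M(t1) and M at the requested sample times (all within [t0, t1]).
    """
    # breakpoints within [t0, t1]
    bps = {t0, t1}
    for a, b in intervals:
        if a < t1 and b > t0:
            bps.add(max(a, t0))
            bps.add(min(b, t1))
    bps = sorted(bps)
    samples = np.full(len(times), np.nan)
    m = m0
    for lo, hi in zip(bps[:-1], bps[1:]):
        p = activity if any(a <= lo and hi <= b for a, b in intervals) else 0.0
        sel = (times >= lo) & (times <= hi)
        ts = times[sel]
        if k > 0:
            ms = p / k + (m - p / k) * np.exp(-k * (ts - lo))
            m = p / k + (m - p / k) * math.exp(-k * (hi - lo))
        else:
            ms = m + p * (ts - lo)
            m = m + p * (hi - lo)
        samples[sel] = ms
    return m, samples


def simulate_colony(config: SimConfig) -> tuple[Colony, GroundTruth]:
    """Grow one microcolony and return it with its ground truth.

    The same seed yields a bit-identical colony.  If the live cell count
    would exceed ``max_cells`` before the movie ends, the movie is cropped
    in time at the last compliant frame (with a warning), so that every
    retained frame is a complete colony snapshot.
    """
    rng = np.random.default_rng(config.seed)
    t_end = (config.n_frames - 1) * config.dt
    frame_times = np.arange(config.n_frames) * config.dt
    lam = config.pulse_rate / 60.0  # initiations per minute per cell
    mu_r, sd_r = _lognormal_params(config.elong_rate_mean, config.elong_rate_cv) \
        if config.elong_rate_cv > 0 else (math.log(config.elong_rate_mean), 0.0)

    records: dict[int, dict] = {}
    onsets: dict[int, list[float]] = {}
    true_len: dict[int, np.ndarray] = {}
    true_m: dict[int, np.ndarray] = {}
    true_r: dict[int, float] = {}

    next_id = [1]
    # event queue of cells to simulate, ordered by birth time then id, so the
    # stream of rng draws is deterministic
    founder_l = rng.uniform(0.55, 0.95) * config.division_length
    heap: list[tuple[float, int, dict]] = []
    heapq.heappush(heap, (0.0, 1, {
        "cell_id": 1, "parent": None, "tb": 0.0, "lb": founder_l,
        "m0": config.founder_intensity, "inherited": []}))
    next_id[0] = 2
    div_time: dict[int, float] = {}
    div_len: dict[int, float] = {}
    birth_len: dict[int, float] = {}

    while heap:
        tb, cid, st = heapq.heappop(heap)
        r = float(np.exp(mu_r + sd_r * rng.standard_normal()))
        ldiv = config.division_length * float(
            np.exp(config.division_length_cv * rng.standard_normal()))
        ldiv = max(ldiv, st["lb"] * 1.05)  # trigger must exceed birth length
        td = tb + math.log(ldiv / st["lb"]) / r

        # pulse initiations over the cell's observable life
        life_end = min(td, t_end)
        n_init = rng.poisson(lam * max(0.0, life_end - tb))
        inits = np.sort(rng.uniform(tb, life_end, size=n_init)) if n_init else []

        intervals = [list(iv) for iv in st["inherited"]]
        cell_onsets: list[float] = []
        for ti in inits:
            covered = any(a <= ti <= b for a, b in intervals)
            intervals.append([ti, ti + config.pulse_duration])
            intervals = _merge_intervals(intervals)
            if not covered:
                cell_onsets.append(float(ti))

        # observed frames: birth <= t < division (division frame goes to the
        # daughters)
        sel = (frame_times >= tb) & (frame_times < td)
        cell_times = frame_times[sel]
        if cell_times.size == 0:
            # born and divided between frames, or born after movie end; with
            # cycle times >> dt this only happens past the movie end
            continue
        k = r + config.gamma
        m_end, m_frames = _integrate_m(st["m0"], tb, max(life_end, cell_times[-1]),
                                       k, config.pulse_activity, intervals,
                                       cell_times)
        lengths = st["lb"] * np.exp(r * (cell_times - tb))

        records[cid] = {
            "cell_id": cid, "parent_id": st["parent"],
            "frames": np.round(cell_times / config.dt).astype(int),
            "time_min": cell_times, "length": lengths, "m": m_frames,
            "daughters": [],
        }
        onsets[cid] = cell_onsets
        true_len[cid] = lengths.copy()
        true_m[cid] = m_frames.copy()
        true_r[cid] = r
        birth_len[cid] = st["lb"]

        if td < t_end:
            phi = 0.5 + config.division_fraction_sd * rng.standard_normal()
            phi = min(max(phi, 0.2), 0.8)
            l_at_div = st["lb"] * math.exp(r * (td - tb))
            m_at_div, _ = _integrate_m(st["m0"], tb, td, k,
                                       config.pulse_activity, intervals,
                                       np.empty(0))
            carry = [[max(a, td), b] for a, b in intervals if b > td]
            d1, d2 = next_id[0], next_id[0] + 1
            next_id[0] += 2
            records[cid]["daughters"] = [d1, d2]
            div_time[cid] = td
            div_len[cid] = l_at_div
            for did, fr in ((d1, phi), (d2, 1.0 - phi)):
                heapq.heappush(heap, (td, did, {
                    "cell_id": did, "parent": cid, "tb": td,
                    "lb": fr * l_at_div, "m0": m_at_div,
                    "inherited": [list(iv) for iv in carry]}))

    # drop daughters that were never observed
    for rec in records.values():
        rec["daughters"] = [d for d in rec["daughters"] if d in records]
        if len(rec["daughters"]) == 1:  # one daughter unobserved: treat as leaf
            rec["daughters"] = []

    # enforce the single-layer cap by cropping the movie in time
    n_i = np.zeros(config.n_frames, dtype=int)
    for rec in records.values():
        n_i[rec["frames"][0]:rec["frames"][-1] + 1] += 1
    over = np.nonzero(n_i > config.max_cells)[0]
    n_frames = config.n_frames
    if over.size:
        n_frames = int(over[0])
        warnings.warn(f"colony exceeded max_cells={config.max_cells} at frame "
                      f"{n_frames}; movie truncated to {n_frames} frames")
        for cid in list(records):
            rec = records[cid]
            keep = rec["frames"] < n_frames
            if not keep.any():
                del records[cid]
                onsets.pop(cid, None)
                true_len.pop(cid, None)
                true_m.pop(cid, None)
                true_r.pop(cid, None)
                continue
            for key in ("frames", "time_min", "length", "m"):
                rec[key] = rec[key][keep]
        for rec in records.values():
            rec["daughters"] = [d for d in rec["daughters"] if d in records]
            if len(rec["daughters"]) == 1:
                rec["daughters"] = []

    # measurement noise
    sigma_ln = math.sqrt(math.log(1.0 + config.noise_cv ** 2)) \
        if config.noise_cv > 0 else 0.0
    cells = {}
    for cid in sorted(records):
        rec = records[cid]
        m_obs = rec["m"].copy()
        if sigma_ln > 0:
            m_obs = m_obs * np.exp(sigma_ln * rng.standard_normal(m_obs.size))
        if config.additive_noise_sd > 0:
            m_obs = m_obs + config.additive_noise_sd * rng.standard_normal(m_obs.size)
        cells[cid] = CellRecord(
            cell_id=cid, parent_id=rec["parent_id"],
            daughter_ids=tuple(rec["daughters"]),
            frames=rec["frames"], time_min=rec["time_min"],
            length=rec["length"], mean_intensity=m_obs)

    colony = Colony(colony_id=f"sim-{config.seed}", dt=config.dt,
                    n_frames=n_frames, cells=cells)
    n_i = np.zeros(n_frames, dtype=int)
    for c in cells.values():
        n_i[c.first_frame:c.last_frame + 1] += 1
    gt = GroundTruth(pulse_onsets=onsets, true_length=true_len,
                     true_intensity=true_m, true_rate=true_r,
                     cell_hours=float(n_i.sum()) * config.dt / 60.0,
                     division_time={c: t for c, t in div_time.items() if c in cells},
                     division_length={c: l for c, l in div_len.items() if c in cells},
                     birth_length={c: l for c, l in birth_len.items() if c in cells})
    return colony, gt


def simulate_dark_cells(n_cells: int = 51, m0: float = 500.0,
                        gamma: float = 0.0015,
                        elong_rate_mean: float = math.log(2) / 180.0,
                        elong_rate_cv: float = 0.15,
                        noise_cv: float = 0.05, dt: float = 20.0,
                        n_frames: int = 30,
                        seed: int | None = None) -> tuple[list[CellRecord], np.ndarray]:
    """Non-expressing cells for degradation-rate calibration.

    Each cell starts at intensity ``m0`` and produces nothing, so its mean
    intensity decays purely by dilution and degradation,
    M(t) = m0 * exp(-(r + gamma) t).  Division is suppressed: the estimator
    gamma = -r - d[log M]/dt is insensitive to it, and single uninterrupted
    series keep the calibration fixture transparent.  Returns the records
    and the true per-cell elongation rates.
    """
    rng = np.random.default_rng(seed)
    mu_r, sd_r = _lognormal_params(elong_rate_mean, elong_rate_cv) \
        if elong_rate_cv > 0 else (math.log(elong_rate_mean), 0.0)
    times = np.arange(n_frames) * dt
    sigma_ln = math.sqrt(math.log(1.0 + noise_cv ** 2)) if noise_cv > 0 else 0.0
    records, rates = [], []
    for i in range(n_cells):
        r = float(np.exp(mu_r + sd_r * rng.standard_normal()))
        m_true = m0 * np.exp(-(r + gamma) * times)
        m_obs = m_true * np.exp(sigma_ln * rng.standard_normal(n_frames)) \
            if sigma_ln > 0 else m_true.copy()
        l0 = 20.0
        records.append(CellRecord(
            cell_id=i + 1, parent_id=None, daughter_ids=(),
            frames=np.arange(n_frames), time_min=times,
            length=l0 * np.exp(r * times), mean_intensity=m_obs))
        rates.append(r)
    return records, np.asarray(rates)


def simulate_decay_curve(half_life: float, timepoints: Sequence[float],
                         noise_sd: float = 0.05, replicates: int = 3,
                         seed: int | None = None) -> pd.DataFrame:
    """Replicate relative-abundance decay curves (antibiotic-chase style).

    Each replicate is exp(-ln2 * t / half_life) plus Gaussian noise,
    renormalized so that abundance is exactly 1 at t = 0.  Returns a tidy
    DataFrame with columns ``replicate, time_min, abundance``.
    """
    if half_life <= 0:
        raise ValueError("half_life must be positive")
    t = np.asarray(timepoints, dtype=float)
    if np.any(t < 0):
        raise ValueError("timepoints must be nonnegative")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(1, replicates + 1):
        y = np.exp(-math.log(2) * t / half_life)
        if noise_sd > 0:
            y = y + noise_sd * rng.standard_normal(t.size)
        if np.any(t == 0):
            y = y / y[t == 0][0]
        rows.append(pd.DataFrame({"replicate": rep, "time_min": t, "abundance": y}))
    return pd.concat(rows, ignore_index=True)


def simulate_spot_field(n_cells: int, spot_fraction: float,
                        photon_mean: float = 100.0, photon_sd: float = 10.0,
                        bg_photon_mean: float = 5.0, bg_photon_sd: float = 2.0,
                        seed: int | None = None) -> list[np.ndarray]:
    """Per-cell photon-count lists emulating single-molecule spot detection.

    A Binomial(n_cells, spot_fraction) subset of cells carries one true spot
    with Normal(photon_mean, photon_sd) photons; every cell may additionally
    carry dim background detections well below a typical photon threshold.
    """
    if not 0 <= spot_fraction <= 1:
        raise ValueError("spot_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_cells):
        counts = list(np.clip(
            rng.normal(bg_photon_mean, bg_photon_sd, size=rng.poisson(1.0)),
            0.0, None))
        if rng.random() < spot_fraction:
            counts.append(max(0.0, rng.normal(photon_mean, photon_sd)))
        out.append(np.asarray(counts))
    return out


# ---------------------------------------------------------------------------
# image rendering (fixtures for the imaging stage)

def _rasterize_rod(shape: tuple[int, int], center: tuple[float, float],
                   angle: float, length: float, width: float) -> np.ndarray:
    """Boolean mask of a square-ended rod (oriented box) of given extent."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = center
    ux, uy = math.cos(angle), math.sin(angle)
    px, py = xx - cx, yy - cy
    along = px * ux + py * uy
    across = -px * uy + py * ux
    return (np.abs(along) <= length / 2.0) & (np.abs(across) <= width / 2.0)


def render_frames(colony: Colony, psf: np.ndarray | None = None,
                  shading: np.ndarray | None = None,
                  background_level: float = 10.0,
                  cell_width: float = 8.0,
                  image_shape: tuple[int, int] | None = None,
                  seed: int | None = None):
    """Render a colony into fluorescence frames, label masks and probability
    maps.

    Each cell is drawn as a rod of its recorded length, filled with its
    recorded mean intensity; the scene is convolved with the PSF, multiplied
    by the shading field and offset by the background level, mirroring the
    corrections the photometry stage inverts.  Cell placement is a seeded
    rejection layout (cells keep one position for life and never overlap).

    Returns ``(stack, masks, prob_maps, label_maps)`` where ``label_maps``
    maps each frame to ``{label: cell_id}``.
    """
    from scipy.ndimage import gaussian_filter
    from scipy.signal import fftconvolve

    rng = np.random.default_rng(seed)
    max_len = {cid: float(c.length.max()) for cid, c in colony.cells.items()}
    pad = cell_width
    if image_shape is None:
        n_final = max(1, sum(1 for c in colony.cells.values()
                             if c.last_frame == colony.n_frames - 1))
        biggest = max(max_len.values(), default=40.0)
        side = int(math.ceil(math.sqrt(n_final) * (biggest + 3 * pad) * 1.4)) + 40
        image_shape = (side, side)
    h, w = image_shape

    placements: dict[int, tuple[tuple[float, float], float]] = {}
    order = sorted(colony.cells, key=lambda cid: colony.cells[cid].first_frame)
    for cid in order:
        radius = max_len[cid] / 2.0 + pad
        for _ in range(2000):
            cy = rng.uniform(radius, h - radius)
            cx = rng.uniform(radius, w - radius)
            angle = rng.uniform(0, math.pi)
            ok = True
            for other, ((oy, ox), _a) in placements.items():
                min_gap = radius + max_len[other] / 2.0 + pad
                if (cy - oy) ** 2 + (cx - ox) ** 2 < min_gap ** 2:
                    ok = False
                    break
            if ok:
                placements[cid] = ((cy, cx), angle)
                break
        else:
            raise ValueError("could not place all cells without overlap; "
                             "supply a larger image_shape")

    if shading is not None:
        shading = np.asarray(shading, dtype=float)
        if shading.shape != image_shape:
            raise ValueError("shading shape must match image_shape")

    stack = np.empty((colony.n_frames, h, w))
    masks = np.zeros((colony.n_frames, h, w), dtype=np.uint16)
    probs = np.empty((colony.n_frames, h, w), dtype=np.float32)
    label_maps: dict[int, dict[int, int]] = {}
    for f in range(colony.n_frames):
        scene = np.zeros((h, w))
        label = 0
        label_maps[f] = {}
        for cid in order:
            cell = colony.cells[cid]
            if not (cell.first_frame <= f <= cell.last_frame):
                continue
            i = f - cell.first_frame
            m = _rasterize_rod(image_shape, placements[cid][0],
                               placements[cid][1],
                               float(cell.length[i]), cell_width)
            label += 1
            masks[f][m] = label
            label_maps[f][label] = cid
            scene[m] = cell.mean_intensity[i]
        img = scene
        if psf is not None:
            kern = np.asarray(psf, dtype=float)
            if np.any(kern < 0):
                raise ValueError("psf must be nonnegative")
            kern = kern / kern.sum()
            img = fftconvolve(img, kern, mode="same")
        img = img + background_level
        if shading is not None:
            img = img * shading
        stack[f] = img
        pm = gaussian_filter((masks[f] > 0).astype(float), 1.0)
        probs[f] = np.clip(pm, 0.0, 1.0)
    return stack, masks, probs, label_maps
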