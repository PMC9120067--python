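"""Per-cell rate estimation: growth rate, expression rate, degradation.

The promoter activity per unit cell length is reconstructed from the
measured mean fluorescence intensity M as

    P_tilde = r M + gamma M + dM/dt,

where r is the elongation (growth) rate, gamma the fluorophore
degradation/bleaching constant, and dM/dt the change in mean intensity.
Both r and dM/dt are sliding-window linear-regression slopes (default
window: 11 frames = 200 min at 20-min imaging): r from log-transformed
extended cell lengths, dM/dt from extended mean intensities.  Series are
extended across division events (see :mod:`pulsekit.lineage`) so windows
near birth and division stay full.

The degradation constant is calibrated on non-expressing cells: with
P_tilde = 0 the balance above gives gamma = -r - d[log M]/dt, pooled over
cells and frames.

All sliding-window slopes go through a single routine,
:func:`sliding_slope`; near series ends the window truncates down to a
minimum of 6 points, below which the estimate is undefined (NaN) rather
than fabricated.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .lineage import Colony, extend_series

__all__ = [
    "DecayFit",
    "GammaEstimate",
    "colony_rate_table",
    "estimate_gamma",
    "estimate_gamma_from_records",
    "expression_rate",
    "fit_exponential_decay",
    "growth_rate",
    "sliding_slope",
]

DEFAULT_WINDOW = 11
MIN_POINTS = 6


def sliding_slope(values: np.ndarray, times: np.ndarray,
                  w: int = DEFAULT_WINDOW,
                  min_points: int = MIN_POINTS) -> np.ndarray:
    """Centred sliding-window least-squares slope of ``values`` vs ``times``.

    Near the series ends the window is not truncated but *shifted* to keep
    its full width inside the series (the standard edge treatment of
    Savitzky-Golay-type smoothers): all positions within half a window of an
    end share the slope of the first/last full window.  A truncated window
    would weight the trailing points ever more strongly and systematically
    drag reconstruction maxima onto the series endpoints, hiding late
    events.  For series shorter than ``w``, all points are used; positions
    with fewer than ``min_points`` finite points get NaN.  NaNs in
    ``values`` are skipped within a window.
    """
    if w % 2 == 0:
        raise ValueError("window must be odd")
    y = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    if y.shape != t.shape:
        raise ValueError("values and times must have the same shape")
    n = y.size
    half = w // 2
    out = np.full(n, np.nan)
    for i in range(n):
        lo = min(max(0, i - half), max(0, n - w))
        hi = min(n, lo + w)
        ys, ts = y[lo:hi], t[lo:hi]
        ok = np.isfinite(ys)
        if ok.sum() < min_points:
            continue
        ys, ts = ys[ok], ts[ok]
        tc = ts - ts.mean()
        denom = float(tc @ tc)
        if denom == 0:
            continue
        out[i] = float(tc @ (ys - ys.mean())) / denom
    return out


def growth_rate(log_length: np.ndarray, times: np.ndarray,
                w: int = DEFAULT_WINDOW,
                min_points: int = MIN_POINTS) -> np.ndarray:
    """Elongation rate r (1/min) from a log-length series.

    The series should already be extended across divisions so interior
    windows stay full; pass log-transformed lengths.
    """
    ll = np.asarray(log_length, dtype=float)
    if not np.all(np.isfinite(ll) | np.isnan(ll)):
        raise ValueError("log lengths contain non-finite values")
    return sliding_slope(ll, times, w=w, min_points=min_points)


def expression_rate(M: np.ndarray, r: np.ndarray, gamma: float,
                    times: np.ndarray, w: int = DEFAULT_WINDOW,
                    min_points: int = MIN_POINTS) -> np.ndarray:
    """P_tilde = r M + gamma M + dM/dt for aligned per-frame series."""
    M = np.asarray(M, dtype=float)
    r = np.asarray(r, dtype=float)
    if M.shape != r.shape:
        raise ValueError("M and r series lengths differ")
    dmdt = sliding_slope(M, times, w=w, min_points=min_points)
    return r * M + gamma * M + dmdt


def colony_rate_table(colony: Colony, gamma: float = 0.0015,
                      w: int = DEFAULT_WINDOW) -> pd.DataFrame:
    """Per-cell per-frame r, M, dM/dt and P_tilde for a whole colony.

    Length and intensity series are extended across divisions before the
    windowed regressions; the returned table covers each cell's own frames
    only, so the estimate at a given (cell, frame) is unique and shared by
    every lineage passing through it.
    """
    half = w // 2
    rows = []
    for cid in sorted(colony.cells):
        cell = colony.cells[cid]
        fr_l, logl = extend_series(colony, cid, "log_length", n_extend=half)
        fr_m, m_ext = extend_series(colony, cid, "intensity", n_extend=half)
        t_l = fr_l * colony.dt
        t_m = fr_m * colony.dt
        r_ext = growth_rate(logl, t_l, w=w)
        dmdt_ext = sliding_slope(m_ext, t_m, w=w)
        own = np.isin(fr_l, cell.frames)
        own_m = np.isin(fr_m, cell.frames)
        r_own = r_ext[own]
        dmdt_own = dmdt_ext[own_m]
        M_own = cell.mean_intensity
        p = r_own * M_own + gamma * M_own + dmdt_own
        for j, f in enumerate(cell.frames):
            rows.append((colony.colony_id, cid, int(f), float(cell.time_min[j]),
                         r_own[j], M_own[j], dmdt_own[j], p[j]))
    return pd.DataFrame(rows, columns=["colony_id", "cell_id", "frame",
                                       "time_min", "r", "M", "dMdt", "P_tilde"])


@dataclass
class GammaEstimate:
    """Pooled degradation/bleaching constant from non-expressing cells."""

    gamma: float            # 1/min
    n_cells: int
    per_cell: np.ndarray    # per-cell mean estimates

    def __post_init__(self) -> None:
        if not np.isfinite(self.gamma):
            raise ValueError("gamma estimate is not finite")


def estimate_gamma(cells, times=None, dt: float = 20.0,
                   w: int = DEFAULT_WINDOW) -> GammaEstimate:
    """Degradation constant from cells with no discernible expression.

    ``cells`` is a sequence of ``(r_series, M_series)`` pairs.  For each
    cell gamma = -r - d[log M]/dt per frame (windowed log-M regression);
    the pooled value is the unweighted mean over all cell-frame estimates.
    Cells with nonpositive M anywhere are excluded with a warning.
    """
    per_cell = []
    all_vals = []
    n_used = 0
    for r_series, m_series in cells:
        r_series = np.asarray(r_series, dtype=float)
        m_series = np.asarray(m_series, dtype=float)
        if np.any(m_series <= 0):
            warnings.warn("cell with nonpositive M excluded from gamma "
                          "calibration")
            continue
        t = (np.arange(m_series.size) * dt if times is None
             else np.asarray(times, dtype=float))
        dlogm = sliding_slope(np.log(m_series), t, w=w)
        vals = -r_series - dlogm
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            continue
        n_used += 1
        per_cell.append(float(vals.mean()))
        all_vals.append(vals)
    if not all_vals:
        raise ValueError("no usable cells for gamma calibration")
    pooled = float(np.concatenate(all_vals).mean())
    return GammaEstimate(gamma=pooled, n_cells=n_used,
                         per_cell=np.asarray(per_cell))


def estimate_gamma_from_records(records, dt: float | None = None,
                                w: int = DEFAULT_WINDOW) -> GammaEstimate:
    """Gamma calibration directly from :class:`~pulsekit.lineage.CellRecord`
    objects (r is estimated from their length series first)."""
    pairs = []
    for rec in records:
        t = rec.time_min
        r = growth_rate(np.log(rec.length), t, w=w)
        pairs.append((r, rec.mean_intensity))
    dt_eff = dt if dt is not None else float(np.median(np.diff(records[0].time_min)))
    times = records[0].time_min if len({r.frames.size for r in records}) == 1 else None
    if times is not None:
        return estimate_gamma(pairs, times=times, dt=dt_eff, w=w)
    return estimate_gamma(pairs, dt=dt_eff, w=w)


@dataclass
class DecayFit:
    """One-phase exponential decay fit y = plateau + span * exp(-k t)."""

    half_life: float     # min; inf when no decay
    k: float             # 1/min
    plateau: float
    span: float
    no_decay: bool = False
    rep_sd: pd.Series | None = None   # per-timepoint SD across replicates

    def __post_init__(self) -> None:
        if not self.no_decay and not math.isclose(
                self.k, math.log(2) / self.half_life, rel_tol=1e-9):
            raise ValueError("k and half-life inconsistent")


def fit_exponential_decay(curves: pd.DataFrame,
                          fix_plateau: bool = True) -> DecayFit:
    """Least-squares one-phase decay fit to replicate decay curves.

    ``curves`` is tidy with columns ``replicate, time_min, abundance``;
    replicate means are fitted and per-timepoint SDs reported.  The plateau
    is fixed at 0 by default (relative abundances); pass
    ``fix_plateau=False`` to free it.  Non-decaying data (fitted k <= 0)
    yields a flagged fit with infinite half-life.
    """
    mean = curves.groupby("time_min")["abundance"].mean()
    sd = curves.groupby("time_min")["abundance"].std()
    t = mean.index.to_numpy(float)
    y = mean.to_numpy(float)
    if t.size < 3:
        raise ValueError("need at least 3 timepoints")

    pos = y > 0
    if pos.sum() >= 2:
        slope, icept = np.polyfit(t[pos], np.log(y[pos]), 1)
        k0, span0 = max(1e-4, -slope), math.exp(icept)
    else:
        k0, span0 = 0.1, float(y[0])

    try:
        if fix_plateau:
            popt, _ = curve_fit(lambda tt, span, k: span * np.exp(-k * tt),
                                t, y, p0=(span0, k0), maxfev=10000)
            span, k = popt
            plateau = 0.0
        else:
            popt, _ = curve_fit(lambda tt, plateau, span, k:
                                plateau + span * np.exp(-k * tt),
                                t, y, p0=(0.0, span0, k0), maxfev=10000)
            plateau, span, k = popt
    except RuntimeError:
        k, span, plateau = 0.0, float(y[0]), 0.0

    # no measurable decay: k nonpositive, or negligible over the sampled span
    if k <= 0 or k * (t.max() - t.min()) < 1e-8:
        return DecayFit(half_life=math.inf, k=0.0, plateau=float(plateau),
                        span=float(span), no_decay=True, rep_sd=sd)
    return DecayFit(half_life=math.log(2) / float(k), k=float(k),
                    plateau=float(plateau), span=float(span), rep_sd=sd)
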