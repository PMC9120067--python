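"""Pulse frequency to quorum-sensing response onset: a minimal pool model.

The analysis stages measure *per-cell* pulse frequencies; this module makes
the population-level consequence explicit.  Every pulse releases a fixed
amount of autoinducer into a shared pool A that decays first order, so with
per-cell frequency f and population size N(t)

    dA/dt = a * f * N(t) - delta * A,       A(0) = 0,

and the quorum-sensing response switches on when A first reaches the
threshold A_thr.  The model is deliberately the simplest one consistent
with frequency-modulated pulsing driving threshold crossing: it carries no
spatial structure, no receptor kinetics, and its per-pulse yield and
threshold are not identifiable from data — only orderings (higher f, earlier
onset, smaller colony at onset) are meaningful, and only those are tested.

A deterministic mode integrates the rate equation; a stochastic mode draws
individual pulse events from the time-inhomogeneous Poisson process with
rate f * N(t) and adds a quantum of autoinducer per event.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "ResponseConfig",
    "logistic_population",
    "onset_vs_frequency",
    "simulate_response_onset",
]


@dataclass
class ResponseConfig:
    """Parameters of the shared autoinducer pool.

    ``population`` is either a constant cell count or a callable N(t) with
    t in hours.
    """

    ahl_per_pulse: float = 1.0        # a.u. released per pulse
    ahl_decay: float = 0.1            # delta, 1/h
    threshold: float = 50.0           # A_thr, a.u.
    population: float | Callable[[float], float] = 100.0
    horizon: float = 200.0            # h

    def __post_init__(self) -> None:
        if self.ahl_per_pulse < 0 or self.ahl_decay < 0:
            raise ValueError("rates must be nonnegative")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")

    def n_of_t(self, t: float) -> float:
        return self.population(t) if callable(self.population) \
            else float(self.population)


def logistic_population(n0: float, rate: float, capacity: float
                        ) -> Callable[[float], float]:
    """Logistic growth N(t) = K / (1 + (K/n0 - 1) e^{-rate t}), t in hours."""
    return lambda t: capacity / (1.0 + (capacity / n0 - 1.0) *
                                 math.exp(-rate * t))


def simulate_response_onset(f: float, config: ResponseConfig,
                            mode: str = "deterministic",
                            seed: int | None = None,
                            dt: float = 0.01):
    """Onset time (h) of the threshold crossing and the A(t) trajectory.

    Returns ``(onset, times, A)``; ``onset`` is ``inf`` when the threshold
    is not reached within the horizon.  The deterministic mode integrates
    the rate equation (exactly for a constant population, including the
    closed form onset = A_thr / (a f N) when delta = 0); the stochastic
    mode simulates discrete pulse events.
    """
    if f < 0:
        raise ValueError("frequency must be nonnegative")
    a, d, thr = config.ahl_per_pulse, config.ahl_decay, config.threshold

    if mode == "deterministic":
        if not callable(config.population):
            n = config.n_of_t(0.0)
            rate = a * f * n
            times = np.arange(0.0, config.horizon + dt, dt)
            if rate == 0:
                return math.inf, times, np.zeros_like(times)
            if d == 0:
                traj = rate * times
                onset = thr / rate
            else:
                amax = rate / d
                traj = amax * (1.0 - np.exp(-d * times))
                onset = (-math.log(1.0 - thr / amax) / d) if thr < amax \
                    else math.inf
            return (onset if onset <= config.horizon else math.inf), times, traj
        # time-varying population: exact linear-ODE update on a fine grid
        times = np.arange(0.0, config.horizon + dt, dt)
        traj = np.zeros_like(times)
        onset = math.inf
        A = 0.0
        for i in range(1, times.size):
            prod = a * f * config.n_of_t(times[i - 1])
            if d > 0:
                A = prod / d + (A - prod / d) * math.exp(-d * dt)
            else:
                A = A + prod * dt
            traj[i] = A
            if onset is math.inf and A >= thr:
                # linear interpolation inside the step
                lo, hi = traj[i - 1], A
                frac = (thr - lo) / (hi - lo) if hi > lo else 1.0
                onset = times[i - 1] + frac * dt
        return onset, times, traj

    if mode != "stochastic":
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    t, A = 0.0, 0.0
    times, traj = [0.0], [0.0]
    # thinning bound over a step horizon
    while t < config.horizon:
        lam_max = f * max(config.n_of_t(t), config.n_of_t(min(t + 1.0,
                                                              config.horizon)))
        if lam_max <= 0:
            break
        wait = rng.exponential(1.0 / lam_max)
        if wait > 1.0:           # no event in this lookahead window
            t_new = t + 1.0
        else:
            t_new = t + wait
        A = A * math.exp(-d * (t_new - t)) if d > 0 else A
        t = t_new
        if t >= config.horizon:
            break
        if wait <= 1.0 and rng.random() < f * config.n_of_t(t) / lam_max:
            A += a
        times.append(t)
        traj.append(A)
        if A >= thr:
            return t, np.asarray(times), np.asarray(traj)
    return math.inf, np.asarray(times), np.asarray(traj)


def onset_vs_frequency(freqs, config: ResponseConfig,
                       mode: str = "deterministic",
                       seed: int | None = None) -> pd.DataFrame:
    """Onset time and colony size at onset for each pulse frequency."""
    freqs = list(freqs)
    if not freqs:
        raise ValueError("freqs must be nonempty")
    rows = []
    for i, f in enumerate(freqs):
        onset, _, _ = simulate_response_onset(
            f, config, mode=mode,
            seed=None if seed is None else seed + i)
        n_at = config.n_of_t(onset) if math.isfinite(onset) else float("nan")
        rows.append((f, onset, n_at))
    return pd.DataFrame(rows, columns=["frequency", "onset_h", "n_at_onset"])
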