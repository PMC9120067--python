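"""Rate estimation: windowed slopes, expression rate, gamma, decay fits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pulsekit import rates, synthetic
from pulsekit.rates import (estimate_gamma, expression_rate,
                            fit_exponential_decay, growth_rate, sliding_slope)


def _oracle_slope(y, t, w=11, min_points=6):
    """Independent least-squares slope with the documented shifted window."""
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
        A = np.column_stack([ts[ok], np.ones(ok.sum())])
        coef, *_ = np.linalg.lstsq(A, ys[ok], rcond=None)
        out[i] = coef[0]
    return out


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.integers(min_value=0, max_value=10 ** 6),
       st.integers(min_value=3, max_value=60))
def test_sliding_slope_matches_lstsq_oracle(seed, n):
    rng = np.random.default_rng(seed)
    y = rng.normal(size=n)
    y[rng.random(n) < 0.1] = np.nan
    t = np.arange(n) * 20.0
    np.testing.assert_allclose(sliding_slope(y, t), _oracle_slope(y, t),
                               rtol=1e-8, atol=1e-12, equal_nan=True)


def test_interior_windows_are_centred():
    rng = np.random.default_rng(1)
    y = rng.normal(size=40)
    t = np.arange(40.0)
    s = sliding_slope(y, t, w=11)
    i = 20
    coef = np.polyfit(t[i - 5:i + 6], y[i - 5:i + 6], 1)
    assert s[i] == pytest.approx(coef[0], rel=1e-9)


def test_growth_rate_exact_on_exponential():
    t = np.arange(30) * 20.0
    r0 = 0.004
    r = growth_rate(np.log(2.0 * np.exp(r0 * t)), t)
    np.testing.assert_allclose(r, r0, rtol=1e-9)


def test_growth_rate_zero_for_constant_length():
    t = np.arange(20) * 20.0
    r = growth_rate(np.log(np.full(20, 3.0)), t)
    np.testing.assert_allclose(r, 0.0, atol=1e-12)


def test_growth_rate_recovery_on_simulated_colony():
    """Colony-pooled mean growth rate matches the generative rates within
    5%; per-frame estimates near divisions blend mother and daughter rates,
    which is why the comparison is pooled."""
    cfg = synthetic.SimConfig(pulse_rate=0.0, seed=17)
    colony, gt = synthetic.simulate_colony(cfg)
    table = rates.colony_rate_table(colony, gamma=cfg.gamma)
    true_mean = np.average(
        [gt.true_rate[cid] for cid in sorted(colony.cells)],
        weights=[colony.cells[cid].frames.size for cid in sorted(colony.cells)])
    assert table["r"].mean() == pytest.approx(true_mean, rel=0.05)
    # interior frames of long-lived cells are individually accurate
    for cid, grp in table.groupby("cell_id"):
        if len(grp) >= 9:
            mid = grp.iloc[4:-4]["r"]
            assert np.abs(mid - gt.true_rate[cid]).max() < \
                0.15 * gt.true_rate[cid] + 1e-4


def test_expression_rate_zero_cases():
    t = np.arange(20) * 20.0
    M = np.full(20, 40.0)
    p = expression_rate(M, np.zeros(20), gamma=0.0, times=t)
    np.testing.assert_allclose(p, 0.0, atol=1e-12)


def test_expression_rate_steady_state_identity():
    """Constant M: production exactly balances dilution, P = (r+gamma)M."""
    t = np.arange(25) * 20.0
    rng = np.random.default_rng(4)
    for _ in range(20):
        m0 = rng.uniform(5, 500)
        r0 = rng.uniform(0.0, 0.01)
        g = rng.uniform(0.0, 0.01)
        p = expression_rate(np.full(25, m0), np.full(25, r0), g, times=t)
        np.testing.assert_allclose(p, (r0 + g) * m0, rtol=1e-9)


def test_expression_rate_equivariance():
    t = np.arange(30) * 20.0
    rng = np.random.default_rng(9)
    M = rng.uniform(10, 100, size=30)
    r = rng.uniform(0, 0.01, size=30)
    base = expression_rate(M, r, 0.0015, times=t)
    shifted = expression_rate(M, r, 0.0015, times=t + 1234.5)
    np.testing.assert_allclose(base, shifted, rtol=1e-9)
    scaled = expression_rate(3.0 * M, r, 0.0015, times=t)
    np.testing.assert_allclose(scaled, 3.0 * base, rtol=1e-9)


def test_long_pulse_peak_recovers_activity():
    """A rectangular activity pulse much longer than the window is broadened
    but its plateau height is recovered within 25%."""
    dt, n = 20.0, 60
    t = np.arange(n) * dt
    r0, g, A = 0.004, 0.0015, 50.0
    k = r0 + g
    on, off = 20, 32          # 240 min pulse
    M = np.zeros(n)
    for i in range(1, n):
        p = A if on <= i - 1 < off else 0.0
        M[i] = p / k + (M[i - 1] - p / k) * math.exp(-k * dt)
    p_hat = expression_rate(M, np.full(n, r0), g, times=t)
    assert np.nanmax(p_hat) == pytest.approx(A, rel=0.25)


# ---------------------------------------------------------------------------
# gamma calibration

def test_gamma_exact_on_noiseless_decay():
    t = np.arange(30) * 20.0
    g0 = 0.0015
    M = 500.0 * np.exp(-g0 * t)
    est = estimate_gamma([(np.zeros(30), M)], times=t)
    assert est.gamma == pytest.approx(g0, rel=1e-9)


def test_gamma_independent_of_growth_rate():
    t = np.arange(30) * 20.0
    g0 = 0.0015
    for r0 in (0.002, 0.006):
        M = 500.0 * np.exp(-(r0 + g0) * t)
        est = estimate_gamma([(np.full(30, r0), M)], times=t)
        assert est.gamma == pytest.approx(g0, rel=1e-9)


def test_gamma_recovery_on_noisy_dark_cells():
    records, _ = synthetic.simulate_dark_cells(51, noise_cv=0.05, seed=7)
    est = rates.estimate_gamma_from_records(records)
    assert est.n_cells == 51
    assert est.gamma == pytest.approx(0.0015, rel=0.10)


def test_gamma_closes_expression_rate_on_calibration_cells():
    """Feeding the calibrated gamma back into the expression rate yields
    P_tilde ~ 0 on the very cells used for calibration."""
    records, true_r = synthetic.simulate_dark_cells(51, noise_cv=0.05, seed=7)
    est = rates.estimate_gamma_from_records(records)
    resid = []
    scale = []
    for rec, r0 in zip(records, true_r):
        r_hat = growth_rate(np.log(rec.length), rec.time_min)
        p = expression_rate(rec.mean_intensity, r_hat, est.gamma,
                            times=rec.time_min)
        resid.append(np.nanmean(p))
        scale.append(np.nanmean((r_hat + est.gamma) * rec.mean_intensity))
    assert abs(np.mean(resid)) < 0.1 * np.mean(scale)


def test_gamma_excludes_nonpositive_cells():
    t = np.arange(30) * 20.0
    good = 500.0 * np.exp(-0.0015 * t)
    bad = good.copy()
    bad[5] = -1.0
    with pytest.warns(UserWarning, match="nonpositive"):
        est = estimate_gamma([(np.zeros(30), good), (np.zeros(30), bad)],
                             times=t)
    assert est.n_cells == 1
    with pytest.raises(ValueError):
        estimate_gamma([(np.zeros(30), bad)], times=t)


# ---------------------------------------------------------------------------
# decay fits

def test_decay_fit_exact_closed_form():
    t = np.arange(9.0)
    curves = synthetic.simulate_decay_curve(3.0, t, noise_sd=0.0, replicates=1)
    fit = fit_exponential_decay(curves)
    assert fit.half_life == pytest.approx(3.0, rel=1e-6)
    assert fit.k == pytest.approx(math.log(2) / 3.0, rel=1e-6)


def test_decay_fit_flags_non_decaying_data():
    import pandas as pd

    curves = pd.DataFrame({"replicate": 1, "time_min": np.arange(6.0),
                           "abundance": np.ones(6)})
    fit = fit_exponential_decay(curves)
    assert fit.no_decay and math.isinf(fit.half_life)


def test_decay_fit_free_plateau():
    import pandas as pd

    t = np.arange(0.0, 15.0)
    y = 0.2 + 0.8 * np.exp(-(math.log(2) / 3.0) * t)
    curves = pd.DataFrame({"replicate": 1, "time_min": t, "abundance": y})
    fit = fit_exponential_decay(curves, fix_plateau=False)
    assert fit.plateau == pytest.approx(0.2, abs=1e-6)
    assert fit.half_life == pytest.approx(3.0, rel=1e-6)


def test_decay_fit_recovery_from_noisy_replicates():
    curves = synthetic.simulate_decay_curve(3.0, np.arange(9.0), noise_sd=0.05,
                                            replicates=3, seed=11)
    fit = fit_exponential_decay(curves)
    assert abs(fit.half_life - 3.0) < 0.5
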