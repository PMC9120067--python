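"""Population-level summaries: gating, spot fractions, correlations.

Implements the flow-cytometry-style positive-fraction gate (events brighter
than a matched fluorophore-free control after downsampling both samples to
equal size), the single-molecule spot fraction at a photon threshold, the
per-colony mean intensity used for late, three-dimensional colonies, linear
correlation summaries (Pearson r^2, Spearman rho) and fold-change tables
across conditions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationResult",
    "GatedSample",
    "colony_mean_intensity",
    "fold_change_table",
    "fraction_positive",
    "linear_correlation",
    "spot_fraction",
]


@dataclass
class GatedSample:
    """Positive-fraction gating result for one sample."""

    n: int                       # events after downsampling
    gate: float                  # intensity threshold from the control
    fraction_positive: float
    median_positive: float       # median intensity of positive events (NaN if none)

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_positive <= 1.0:
            raise ValueError("fraction_positive outside [0, 1]")


def fraction_positive(sample: np.ndarray, control: np.ndarray,
                      n_down: int = 15000, control_quantile: float = 0.999,
                      seed: int | None = None) -> GatedSample:
    """Fraction of sample events brighter than a negative control.

    Both sample and control are downsampled without replacement to
    ``n_down`` events (skipped with a warning for smaller inputs); the gate
    is the ``control_quantile`` quantile of the control — a quantile rather
    than the maximum, to be robust to single outlier events.
    """
    import warnings

    sample = np.asarray(sample, dtype=float).ravel()
    control = np.asarray(control, dtype=float).ravel()
    if sample.size == 0 or control.size == 0:
        raise ValueError("sample and control must be nonempty")
    rng = np.random.default_rng(seed)
    if sample.size >= n_down:
        sample = rng.choice(sample, size=n_down, replace=False)
    else:
        warnings.warn(f"sample has {sample.size} < {n_down} events; "
                      "downsampling skipped")
    if control.size >= n_down:
        control = rng.choice(control, size=n_down, replace=False)
    else:
        warnings.warn(f"control has {control.size} < {n_down} events; "
                      "downsampling skipped")
    gate = float(np.quantile(control, control_quantile))
    positive = sample[sample > gate]
    return GatedSample(
        n=int(sample.size), gate=gate,
        fraction_positive=positive.size / sample.size,
        median_positive=float(np.median(positive)) if positive.size else float("nan"))


def spot_fraction(per_cell_photons: Sequence[Sequence[float]],
                  threshold: float = 20.0) -> float:
    """Fraction of cells with at least one spot above the photon threshold."""
    cells = list(per_cell_photons)
    if not cells:
        raise ValueError("no cells")
    hits = sum(1 for counts in cells
               if np.any(np.asarray(counts, dtype=float) >= threshold))
    return hits / len(cells)


@dataclass
class CorrelationResult:
    slope: float
    intercept: float
    r_squared: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float

    def __post_init__(self) -> None:
        if not -1.0 <= self.spearman_rho <= 1.0:
            raise ValueError("spearman rho outside [-1, 1]")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r^2 outside [0, 1]")


def linear_correlation(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    """Least-squares line with Pearson r^2 and Spearman rho (two-tailed p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired points")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    lin = stats.linregress(x, y)
    if np.ptp(y) == 0:
        r2, pp = 0.0, 1.0
    else:
        r2, pp = lin.rvalue ** 2, lin.pvalue
    sp = stats.spearmanr(x, y)
    rho = 0.0 if np.isnan(sp.statistic) else float(sp.statistic)
    return CorrelationResult(slope=float(lin.slope),
                             intercept=float(lin.intercept),
                             r_squared=float(r2), pearson_p=float(pp),
                             spearman_rho=rho,
                             spearman_p=float(sp.pvalue) if np.isfinite(sp.pvalue) else 1.0)


def colony_mean_intensity(fluor_image: np.ndarray, colony_mask: np.ndarray,
                          background_value: float = 0.0) -> float:
    """Total fluorescence per colony area, minus background."""
    mask = np.asarray(colony_mask).astype(bool)
    if not mask.any():
        raise ValueError("empty colony mask")
    img = np.asarray(fluor_image, dtype=float)
    return float(img[mask].sum() / mask.sum() - background_value)


def fold_change_table(summaries: Mapping[str, Mapping[str, float]] | pd.DataFrame
                      ) -> pd.DataFrame:
    """Max/min fold changes of each metric across conditions.

    ``summaries`` maps condition -> {metric: value} (or an equivalent
    DataFrame with conditions as the index).  Returns one row per metric
    with the fold change and the extreme conditions; a zero minimum is
    flagged and yields an infinite fold.
    """
    df = pd.DataFrame(summaries).T if not isinstance(summaries, pd.DataFrame) \
        else summaries
    if len(df) < 2:
        raise ValueError("need at least 2 conditions")
    rows = []
    for metric in df.columns:
        col = df[metric].astype(float)
        hi, lo = col.idxmax(), col.idxmin()
        zero_min = col[lo] == 0
        fold = float("inf") if zero_min else float(col[hi] / col[lo])
        rows.append((metric, fold, hi, lo, zero_min))
    return pd.DataFrame(rows, columns=["metric", "fold", "max_condition",
                                       "min_condition", "zero_denominator"])
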