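"""Cumulative-distribution shift curves for gene-set length biases.

The curve reports delta(x) = F_background(x) - F_set(x) on the pooled
sorted unique values of the measured quantity (exonic length, intronic
length or exonic content), so a gene set shifted towards larger values has
positive delta.  The maximum of |delta| is exactly the two-sample
Kolmogorov-Smirnov statistic; a 3-point moving average is applied for
display only — statistics always use the unsmoothed curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CumulativeCurve", "cumulative_delta", "smooth3", "ks_compare"]


@dataclass
class CumulativeCurve:
    """Background-minus-set cumulative difference over a value grid."""

    grid: np.ndarray
    delta: np.ndarray
    delta_smooth: np.ndarray
    set_median: float
    background_median: float
    ks_statistic: float
    ks_p: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"value": self.grid, "delta": self.delta, "delta_smooth": self.delta_smooth}
        )


def smooth3(values) -> np.ndarray:
    """Centered 3-point moving average; edge windows shrink to 2 points."""
    v = np.asarray(values, dtype=float)
    if v.size <= 2:
        return v.copy()
    out = np.empty_like(v)
    out[1:-1] = (v[:-2] + v[1:-1] + v[2:]) / 3.0
    out[0] = (v[0] + v[1]) / 2.0
    out[-1] = (v[-2] + v[-1]) / 2.0
    return out


def ks_compare(set_values, background_values) -> tuple[float, float]:
    """Two-sided two-sample KS test (exact for small samples)."""
    a = np.asarray(set_values, dtype=float)
    b = np.asarray(background_values, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("KS comparison needs at least 2 values per sample")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        raise ValueError("degenerate samples: all values identical")
    method = "exact" if max(a.size, b.size) <= 50 else "asymp"
    res = stats.ks_2samp(a, b, method=method)
    return float(res.statistic), float(res.pvalue)


def _ecdf(sample: np.ndarray, grid: np.ndarray) -> np.ndarray:
    return np.searchsorted(np.sort(sample), grid, side="right") / sample.size


def cumulative_delta(set_values, background_values) -> CumulativeCurve:
    """Compute the background-minus-set cumulative-difference curve.

    The grid is the pooled sorted unique values (exact empirical CDFs);
    medians of both samples are recorded for annotation.
    """
    a = np.asarray(set_values, dtype=float)
    b = np.asarray(background_values, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    grid = np.unique(np.concatenate([a, b]))
    delta = _ecdf(b, grid) - _ecdf(a, grid)
    if a.size >= 2 and b.size >= 2 and not (np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]):
        ks_stat, ks_p = ks_compare(a, b)
    else:
        ks_stat, ks_p = float(np.max(np.abs(delta))), 1.0
    return CumulativeCurve(
        grid=grid,
        delta=delta,
        delta_smooth=smooth3(delta),
        set_median=float(np.median(a)),
        background_median=float(np.median(b)),
        ks_statistic=ks_stat,
        ks_p=ks_p,
    )


def plot_curves(curves: dict[str, CumulativeCurve], path: str, log_x: bool = True) -> None:
    """Thin plotting layer: one panel per measured quantity."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(curves), figsize=(4 * len(curves), 3.2), squeeze=False)
    for ax, (name, curve) in zip(axes[0], curves.items()):
        ax.plot(curve.grid, curve.delta_smooth, lw=1.5)
        ax.axhline(0.0, color="0.6", lw=0.8)
        ax.axvline(curve.set_median, color="tab:orange", lw=0.8, ls="--")
        ax.axvline(curve.background_median, color="0.3", lw=0.8, ls="--")
        if log_x and np.all(curve.grid > 0):
            ax.set_xscale("log")
        ax.set_title(f"{name}\nKS={curve.ks_statistic:.3f}, p={curve.ks_p:.2g}", fontsize=9)
        ax.set_ylabel("F_bg - F_set")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
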