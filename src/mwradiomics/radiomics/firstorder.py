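"""First-order intensity features: statistics, histogram, intensity-volume
histogram.

All operate on the 1D array of in-mask HU values.  Histogram features use
the same fixed-bin-count discretization (default 32 bins over the in-mask
range) as the texture families.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

__all__ = ["stat_features", "hist_features", "hist_gradient_features", "ivh_features"]


def stat_features(values: np.ndarray) -> dict[str, float]:
    """The 25 intensity-statistics features (F1-F25)."""
    x = np.asarray(values, dtype=np.float64)
    n = x.size
    mean = float(x.mean())
    var = float(x.var())  # population variance
    sd = float(np.sqrt(var))
    med = float(np.median(x))
    p5, p10, p25, p75, p90, p95 = (float(v) for v in
                                   np.percentile(x, [5, 10, 25, 75, 90, 95]))
    if sd > 0:
        skew = float(((x - mean) ** 3).mean() / sd ** 3)
        kurt = float(((x - mean) ** 4).mean() / sd ** 4 - 3.0)
    else:
        skew = 0.0
        kurt = 0.0
    inner = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(inner - inner.mean()).mean()) if inner.size else 0.0
    denom = med if med != 0 else np.nan
    qsum = p75 + p25
    return {
        "stat_mean": mean,
        "stat_variance": var,
        "stat_skewness": skew,
        "stat_kurtosis": kurt,
        "stat_median": med,
        "stat_minimum": float(x.min()),
        "stat_maximum": float(x.max()),
        "stat_p10": p10,
        "stat_p25": p25,
        "stat_p75": p75,
        "stat_p90": p90,
        "stat_iqr": p75 - p25,
        "stat_range": float(x.max() - x.min()),
        "stat_mean_abs_dev": float(np.abs(x - mean).mean()),
        "stat_robust_mean_abs_dev": rmad,
        "stat_median_abs_dev": float(np.abs(x - med).mean()),
        "stat_coeff_variation": sd / mean if mean != 0 else np.nan,
        "stat_quartile_coeff_dispersion": (p75 - p25) / qsum if qsum != 0 else np.nan,
        "stat_rms": float(np.sqrt((x ** 2).mean())),
        "stat_energy": float((x ** 2).sum()),
        "stat_sd": sd,
        "stat_sum": float(x.sum()),
        "stat_p5": p5,
        "stat_p95": p95,
        "stat_decile_range": p90 - p10,
    }


def discretize(values: np.ndarray, n_bins: int = 32) -> np.ndarray:
    """Fixed-bin-count discretization to integer levels 1..n_bins.

    Bins span the in-mask intensity range; a constant region maps to
    level 1 everywhere.
    """
    x = np.asarray(values, dtype=np.float64)
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        return np.ones(x.shape, dtype=np.int64)
    g = np.floor(n_bins * (x - lo) / (hi - lo)).astype(np.int64) + 1
    return np.clip(g, 1, n_bins)


def hist_features(values: np.ndarray, n_bins: int = 32) -> dict[str, float]:
    """The 15 intensity-histogram features (F26-F40) on discretized levels."""
    g = discretize(values, n_bins).astype(np.float64)
    n = g.size
    counts = np.bincount(g.astype(np.int64), minlength=n_bins + 1)[1:]
    p = counts / n
    mean = float(g.mean())
    var = float(g.var())
    sd = float(np.sqrt(var))
    med = float(np.median(g))
    p10, p25, p75, p90 = (float(v) for v in np.percentile(g, [10, 25, 75, 90]))
    if sd > 0:
        skew = float(((g - mean) ** 3).mean() / sd ** 3)
        kurt = float(((g - mean) ** 4).mean() / sd ** 4 - 3.0)
    else:
        skew, kurt = 0.0, 0.0
    nz = p[p > 0]
    qsum = p75 + p25
    return {
        "hist_mean": mean,
        "hist_variance": var,
        "hist_skewness": skew,
        "hist_kurtosis": kurt,
        "hist_median": med,
        "hist_mode": float(np.argmax(counts) + 1),
        "hist_p10": p10,
        "hist_p90": p90,
        "hist_iqr": p75 - p25,
        "hist_range": float(g.max() - g.min()),
        "hist_mean_abs_dev": float(np.abs(g - mean).mean()),
        "hist_coeff_variation": sd / mean if mean != 0 else np.nan,
        "hist_entropy": float(-(nz * np.log2(nz)).sum()),
        "hist_uniformity": float((p ** 2).sum()),
        "hist_quartile_coeff_dispersion": (p75 - p25) / qsum if qsum != 0 else np.nan,
    }


def hist_gradient_features(values: np.ndarray, n_bins: int = 32) -> dict[str, float]:
    """Histogram-gradient features (F361-F364)."""
    g = discretize(values, n_bins)
    counts = np.bincount(g, minlength=n_bins + 1)[1:].astype(np.float64)
    if counts.size < 3:
        grad = np.zeros_like(counts)
    else:
        grad = np.gradient(counts)
    return {
        "hist_max_gradient": float(grad.max()),
        "hist_max_gradient_intensity": float(np.argmax(grad) + 1),
        "hist_min_gradient": float(grad.min()),
        "hist_min_gradient_intensity": float(np.argmin(grad) + 1),
    }


def ivh_features(values: np.ndarray) -> dict[str, float]:
    """Intensity-volume histogram features (F41-F49).

    ``vol_frac_q``: fraction of the mask volume whose intensity is at least
    ``min + q/100 * (max - min)``.  ``int_frac_q``: the minimum intensity of
    the hottest ``q`` percent of the volume, expressed as a fraction of the
    intensity range.  ``auc`` integrates the fractional-volume curve over
    intensity fraction.
    """
    x = np.sort(np.asarray(values, dtype=np.float64))
    n = x.size
    lo, hi = float(x[0]), float(x[-1])
    rng = hi - lo

    def vol_at_frac(q: float) -> float:
        if rng == 0:
            return 1.0
        thr = lo + q * rng
        return float((x >= thr).sum() / n)

    def int_at_volfrac(q: float) -> float:
        # intensity threshold above which at least q of the volume lies
        if rng == 0:
            return 0.0
        k = int(np.ceil(q * n))
        thr = x[n - k] if k >= 1 else hi
        return float((thr - lo) / rng)

    # AUC of fractional volume vs intensity fraction on a fine grid
    if rng == 0:
        auc = 1.0
    else:
        qs = np.linspace(0.0, 1.0, 101)
        vs = np.array([vol_at_frac(q) for q in qs])
        auc = float(np.trapezoid(vs, qs))
    return {
        "ivh_vol_frac_10": vol_at_frac(0.10),
        "ivh_vol_frac_25": vol_at_frac(0.25),
        "ivh_vol_frac_50": vol_at_frac(0.50),
        "ivh_vol_frac_90": vol_at_frac(0.90),
        "ivh_int_frac_10": int_at_volfrac(0.10),
        "ivh_int_frac_25": int_at_volfrac(0.25),
        "ivh_int_frac_50": int_at_volfrac(0.50),
        "ivh_int_frac_90": int_at_volfrac(0.90),
        "ivh_auc": auc,
    }
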