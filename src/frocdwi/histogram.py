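"""Whole-lesion first-order histogram features.

Seven distribution statistics of the voxel values inside a lesion ROI:
10th/90th percentiles, mean, median, entropy, kurtosis, skewness.  The
conventions are fixed for reproducibility:

* percentiles: linear interpolation;
* skewness ``m3 / m2**1.5`` and kurtosis ``m4 / m2**2`` with *population*
  central moments (kurtosis is non-excess / Pearson, so a Gaussian scores 3);
* entropy ``-sum p_i * log2(p_i)`` over ``n_bins`` equal-width bins spanning
  the data's own [min, max] (empty bins contribute zero), hence in bits and
  bounded by ``log2(n_bins)``; equal-width bins over the data range make
  entropy invariant under affine transforms of the values;
* a constant input has zero variance: skewness and kurtosis are reported as
  0 by convention and entropy is 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["HistogramMetrics", "REPORTING_SCALE", "compute_histogram_metrics",
           "features_for_lesion"]

#: multiplicative factors taking internal units to the reporting scale:
#: diffusivities mm^2/s -> 1e-6 mm^2/s; beta (dimensionless) and mu (mm,
#: i.e. 1e-3 um) -> 1e-3 units.
REPORTING_SCALE = {"adc": 1e6, "ADC": 1e6, "D": 1e6, "beta": 1e3, "mu": 1e6}

FEATURE_NAMES = ("p10", "p90", "mean", "median", "entropy", "kurtosis", "skewness")


@dataclass(frozen=True)
class HistogramMetrics:
    p10: float
    p90: float
    mean: float
    median: float
    entropy: float      # bits
    kurtosis: float     # Pearson (normal = 3)
    skewness: float
    n_voxels: int
    n_bins: int

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


def compute_histogram_metrics(values, n_bins: int = 100) -> HistogramMetrics:
    """First-order histogram statistics of a 1D value list."""
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty value list")
    finite = np.isfinite(x)
    if not finite.all():
        warnings.warn(f"excluding {int((~finite).sum())} non-finite values", stacklevel=2)
        x = x[finite]
        if x.size == 0:
            raise ValueError("all values non-finite")

    p10, p90 = np.percentile(x, [10, 90])
    mean = float(x.mean())
    median = float(np.median(x))

    if np.ptp(x) == 0:
        skew = kurt = entropy = 0.0
    else:
        skew = float(stats.skew(x, bias=True))
        kurt = float(stats.kurtosis(x, fisher=False, bias=True))
        counts, _ = np.histogram(x, bins=n_bins, range=(x.min(), x.max()))
        p = counts[counts > 0] / x.size
        entropy = float(-(p * np.log2(p)).sum())

    return HistogramMetrics(
        p10=float(p10), p90=float(p90), mean=mean, median=median,
        entropy=entropy, kurtosis=kurt, skewness=skew,
        n_voxels=int(x.size), n_bins=n_bins,
    )


def features_for_lesion(maps, roi3d, n_bins: int = 100) -> dict[str, HistogramMetrics]:
    """Histogram metrics per parameter map over a 3D lesion ROI.

    Values are converted to the reporting scale before the statistics are
    computed (shape metrics are affine-invariant, so only the location
    metrics are affected).  Voxels whose fit failed — and, for mu, voxels
    where mu is unidentifiable (beta at its upper limit) — are excluded.
    ``S0`` is a nuisance amplitude, not a diffusion metric, and is skipped.
    """
    from .segmentation import copy_roi_to_maps

    values, _excluded = copy_roi_to_maps(roi3d, maps)
    out: dict[str, HistogramMetrics] = {}
    for name, vals in values.items():
        if name == "S0":
            continue
        scale = REPORTING_SCALE.get(name, 1.0)
        out[name] = compute_histogram_metrics(vals * scale, n_bins=n_bins)
    return out


def lesion_feature_row(lesion_id, model: str,
                       metrics: dict[str, HistogramMetrics]) -> list[dict]:
    """Flatten per-parameter metrics into long-format table rows."""
    rows = []
    for param, m in metrics.items():
        row = {"lesion_id": lesion_id, "model": model, "parameter": param,
               "n_voxels": m.n_voxels}
        row.update(m.as_dict())
        rows.append(row)
    return rows
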