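"""Synthetic data: multi-b DWI phantoms and lesion-level cohorts.

Two generators make every pipeline stage testable without any image
download:

* :func:`make_phantom` builds a 4D multi-b volume from known voxel-wise
  fractional-order parameters — an ellipsoidal "lesion" with low
  diffusivity and low beta embedded in a smoother "parenchyma" background,
  spatially correlated parameter heterogeneity, and Rician magnitude noise
  calibrated to a target SNR at the highest b-value.

* :func:`make_cohort` draws lesion-level histogram-metric tables directly:
  per-group correlated multivariate-normal metrics whose marginal means and
  SDs default to the reference benign/malignant distributions, categorical
  prognostic labels assigned by prevalence, estrogen-receptor-conditional
  mean shifts, and optional duplicate-reader columns for reproducibility
  analysis.  Metrics are simulated at lesion level because the reference
  distributions are published as mean +/- SD only; Gaussian marginals are
  the minimal faithful choice (real metric distributions are right-skewed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .acquisition import AcquisitionProtocol, GAMMA_PROTON
from .fitting import ParameterMaps
from .models import froc_decay_exponent
from .reference import (ER_GROUP_MEANS, GROUP_STATS, LABEL_PREVALENCE,
                        SNR_B2000, SUBTYPE_PREVALENCE)
from .segmentation import RoiMask

__all__ = [
    "DEFAULT_B_VALUES",
    "default_protocol",
    "PhantomSpec",
    "CohortSpec",
    "Phantom",
    "rician_noise",
    "make_phantom",
    "make_cohort",
]

#: default multi-b scheme (s/mm^2) of the emulated breast protocol.
DEFAULT_B_VALUES = (0.0, 50.0, 100.0, 200.0, 400.0, 800.0, 1200.0, 2000.0)


def default_protocol() -> AcquisitionProtocol:
    """The emulated acquisition: 8 b-values, delta = 19.3 ms, Delta = 40 ms."""
    return AcquisitionProtocol(DEFAULT_B_VALUES, delta=0.0193, Delta=0.040,
                               gamma=GAMMA_PROTON)


def rician_noise(signal, sigma: float, seed=0):
    """Rician magnitude noise: sqrt((S + e1)^2 + e2^2), e ~ N(0, sigma^2).

    ``seed`` may be an integer or a ``numpy.random.Generator``.  With
    ``sigma = 0`` the input is returned unchanged.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    s = np.asarray(signal, dtype=float)
    if sigma == 0:
        return s.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    e1 = rng.normal(0.0, sigma, size=s.shape)
    e2 = rng.normal(0.0, sigma, size=s.shape)
    return np.sqrt((s + e1) ** 2 + e2**2)


# ---------------------------------------------------------------------------
# voxel-level phantom

# (mean, SD) per parameter, internal units; lesion values emulate a
# malignant mass (low D, low beta), background values looser parenchyma.
_LESION_PARAMS = {"S0": (800.0, 40.0), "D": (0.93e-3, 0.13e-3),
                  "beta": (0.78, 0.04), "mu": (6.5e-3, 0.35e-3)}
_BACKGROUND_PARAMS = {"S0": (400.0, 40.0), "D": (1.5e-3, 0.25e-3),
                      "beta": (0.90, 0.04), "mu": (7.3e-3, 0.4e-3)}
_PARAM_BOUNDS = {"S0": (1.0, np.inf), "D": (1e-5, 5e-3),
                 "beta": (0.2, 1.0), "mu": (5e-4, 2e-2)}


@dataclass
class PhantomSpec:
    """Geometry, parameter fields, and noise level of a synthetic DWI volume."""

    shape: tuple[int, int, int] = (64, 64, 16)
    lesion_center: tuple[float, float, float] = (32.0, 32.0, 8.0)
    lesion_semi_axes: tuple[float, float, float] = (10.0, 10.0, 4.0)
    lesion_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_LESION_PARAMS))
    background_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_BACKGROUND_PARAMS))
    corr_length: float = 2.0        # voxels, Gaussian smoothing scale
    snr_b2000: float = SNR_B2000["malignant"]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.snr_b2000 <= 0:
            raise ValueError("snr_b2000 must be positive")
        for params in (self.lesion_params, self.background_params):
            for name, (_, sd) in params.items():
                if sd < 0:
                    raise ValueError(f"negative SD for {name}")
        center = np.asarray(self.lesion_center)
        semi = np.asarray(self.lesion_semi_axes)
        if np.any(center - semi < 0) or np.any(center + semi >= np.asarray(self.shape)):
            raise ValueError("lesion ellipsoid must lie inside the grid")


@dataclass
class Phantom:
    dwi: np.ndarray                 # (x, y, z, frames)
    truth: ParameterMaps            # ground-truth parameter fields
    lesion: RoiMask                 # true 3D lesion mask
    sigma: float                    # Gaussian channel noise SD
    protocol: AcquisitionProtocol


def _correlated_field(shape, corr_length, rng) -> np.ndarray:
    """Zero-mean unit-variance Gaussian random field with smooth correlation."""
    white = rng.standard_normal(shape)
    if corr_length <= 0:
        return white
    smooth = ndimage.gaussian_filter(white, sigma=corr_length, mode="wrap")
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def make_phantom(spec: PhantomSpec | None = None,
                 protocol: AcquisitionProtocol | None = None) -> Phantom:
    """Generate a noisy multi-b DWI volume with known ground truth.

    Per-voxel parameters are ``mean + SD * correlated field``, with lesion
    and background drawing from separate means; values are clipped to the
    model bounds (clip counts are warned about).  The channel noise SD is
    set so that the mean lesion signal at the highest b divided by sigma
    equals ``spec.snr_b2000``.  Deterministic per seed.
    """
    spec = spec or PhantomSpec()
    protocol = protocol or default_protocol()
    rng = np.random.default_rng(spec.seed)

    idx = np.indices(spec.shape, dtype=float)
    center = np.asarray(spec.lesion_center).reshape(3, 1, 1, 1)
    semi = np.asarray(spec.lesion_semi_axes).reshape(3, 1, 1, 1)
    lesion = (((idx - center) / semi) ** 2).sum(axis=0) <= 1.0

    maps: dict[str, np.ndarray] = {}
    n_clipped = 0
    for name in ("S0", "D", "beta", "mu"):
        bg_mean, bg_sd = spec.background_params[name]
        le_mean, le_sd = spec.lesion_params[name]
        fld = _correlated_field(spec.shape, spec.corr_length, rng)
        arr = np.where(lesion, le_mean + le_sd * fld, bg_mean + bg_sd * fld)
        lo, hi = _PARAM_BOUNDS[name]
        clipped = np.clip(arr, lo, hi)
        n_clipped += int((clipped != arr).sum())
        maps[name] = clipped
    if n_clipped:
        warnings.warn(f"{n_clipped} parameter values clipped to model bounds",
                      stacklevel=2)

    b = protocol.b_array()
    expo = np.empty(spec.shape + (b.size,))
    for j, bj in enumerate(b):
        expo[..., j] = froc_decay_exponent(maps["D"], maps["beta"], maps["mu"],
                                           protocol, bj)
    clean = maps["S0"][..., None] * np.exp(-expo)

    b_top = b.max()
    top_frames = np.flatnonzero(b == b_top)
    mean_lesion_signal = float(clean[lesion][:, top_frames].mean())
    sigma = mean_lesion_signal / spec.snr_b2000
    dwi = rician_noise(clean, sigma, rng)

    truth = ParameterMaps(
        model="froc", maps=maps,
        residual=np.zeros(spec.shape),
        mask=np.ones(spec.shape, dtype=bool),
    )
    return Phantom(dwi=dwi, truth=truth, lesion=RoiMask(lesion, kind="3d"),
                   sigma=sigma, protocol=protocol)


# ---------------------------------------------------------------------------
# lesion-level cohort

@dataclass
class CohortSpec:
    """Sampling plan for a lesion-level metric table.

    ``group_stats`` maps metric name to (benign mean, benign SD, malignant
    mean, malignant SD) on the reporting scale.  ``rho`` is a single
    exchangeable inter-metric correlation.  ``label_shifts`` maps label ->
    {metric: (negative-status mean, positive-status mean)} applied to
    malignant rows after label assignment.  ``reader_sd_frac`` adds a
    duplicate-reader column per metric, ``value + N(0, frac * group SD)``.
    """

    n_benign: int = 50
    n_malignant: int = 109
    group_stats: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(GROUP_STATS))
    prevalence: dict[str, float] = field(
        default_factory=lambda: dict(LABEL_PREVALENCE))
    subtype_prevalence: dict[str, float] = field(
        default_factory=lambda: dict(SUBTYPE_PREVALENCE))
    label_shifts: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {"ER": dict(ER_GROUP_MEANS)})
    rho: float = 0.5
    reader_sd_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, p in self.prevalence.items():
            if not 0 <= p <= 1:
                raise ValueError(f"prevalence of {name} outside [0, 1]")
        for _, (_, sb, _, sm) in self.group_stats.items():
            if sb < 0 or sm < 0:
                raise ValueError("negative SD in group_stats")
        k = len(self.group_stats)
        if k > 1 and not (-1.0 / (k - 1) < self.rho < 1.0):
            raise ValueError(
                f"exchangeable correlation rho={self.rho} is not positive "
                f"definite for {k} metrics")


def _draw_group(rng, n, means, sds, rho):
    # factorize the exchangeable correlation (always PD for valid rho) and
    # scale by the SDs afterwards, so zero-SD metrics degrade gracefully
    k = means.size
    corr = np.full((k, k), rho)
    np.fill_diagonal(corr, 1.0)
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal((n, k))
    return means[None, :] + (z @ chol.T) * sds[None, :]


def make_cohort(spec: CohortSpec | None = None) -> pd.DataFrame:
    """Draw a lesion-by-metric table with clinical labels.

    Returns a DataFrame with one row per lesion: ``malignant`` (bool), one
    column per metric, categorical label columns (positive/negative status
    for ER/PR/HER2/Ki67/ALN, subtype for malignant lesions), and — when
    ``reader_sd_frac > 0`` — a ``<metric>__reader2`` column per metric.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    metric_names = list(spec.group_stats)
    stats_arr = np.array([spec.group_stats[m] for m in metric_names])
    mb, sb, mm, sm = stats_arr.T

    benign = _draw_group(rng, spec.n_benign, mb, sb, spec.rho)
    malignant = _draw_group(rng, spec.n_malignant, mm, sm, spec.rho)

    labels: dict[str, np.ndarray] = {}
    for name, p in spec.prevalence.items():
        labels[name] = rng.random(spec.n_malignant) < p
    subtype_names = list(spec.subtype_prevalence)
    probs = np.asarray([spec.subtype_prevalence[s] for s in subtype_names])
    subtype = rng.choice(subtype_names, size=spec.n_malignant, p=probs / probs.sum())

    # label-conditional mean shifts on the malignant group
    for label, shifts in spec.label_shifts.items():
        if label not in labels:
            continue
        status = labels[label]
        for metric, (mean_neg, mean_pos) in shifts.items():
            if metric not in metric_names:
                continue
            j = metric_names.index(metric)
            target = np.where(status, mean_pos, mean_neg)
            malignant[:, j] += target - mm[j]

    n = spec.n_benign + spec.n_malignant
    data = {"lesion_id": np.arange(n),
            "malignant": np.repeat([False, True], [spec.n_benign, spec.n_malignant])}
    values = np.vstack([benign, malignant])
    for j, m in enumerate(metric_names):
        data[m] = values[:, j]
    for name, status in labels.items():
        col = np.full(n, "", dtype=object)
        col[spec.n_benign:] = np.where(status, "positive", "negative")
        data[name] = col
    sub_col = np.full(n, "", dtype=object)
    sub_col[spec.n_benign:] = subtype
    data["subtype"] = sub_col

    if spec.reader_sd_frac > 0:
        group_sd = np.where(data["malignant"][:, None], sm[None, :], sb[None, :])
        noise = rng.normal(0.0, spec.reader_sd_frac, size=(n, len(metric_names)))
        reader2 = values + noise * group_sd
        for j, m in enumerate(metric_names):
            data[f"{m}__reader2"] = reader2[:, j]

    return pd.DataFrame(data)
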