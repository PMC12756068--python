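"""Forward diffusion signal models.

Two voxel-level models of multi-b signal decay:

* mono-exponential: ``S(b) = S0 * exp(-b * ADC)`` — Gaussian diffusion.
* fractional-order calculus (FROC): a three-parameter non-Gaussian model

  ``S = S0 * exp[-D * mu**(2*(beta-1)) * (gamma*G_d*delta)**(2*beta)
               * (Delta - (2*beta-1)/(2*beta+1) * delta)]``

  with diffusivity ``D`` (mm^2/s), spatial fractional order ``beta`` in
  (0, 1] (sensitivity to intravoxel heterogeneity; beta = 1 recovers the
  mono-exponential model with ADC = D), and a spatial constant ``mu`` (mm,
  a length scale).  ``mu`` enters through ``mu**(2*(beta-1))`` and is
  therefore unidentifiable at beta = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .acquisition import AcquisitionProtocol, gradient_amplitude_for_b

__all__ = ["FrocParams", "MonoParams", "froc_signal", "mono_signal"]


@dataclass(frozen=True)
class FrocParams:
    """Fractional-order model parameters: S0 (a.u.), D (mm^2/s), beta, mu (mm)."""

    S0: float
    D: float
    beta: float
    mu: float

    def __post_init__(self) -> None:
        if not self.S0 > 0:
            raise ValueError("S0 must be positive")
        if not self.D > 0:
            raise ValueError("D must be positive")
        if not 0 < self.beta <= 1:
            raise ValueError(f"beta must lie in (0, 1], got {self.beta}")
        if not self.mu > 0:
            raise ValueError("mu must be positive")


@dataclass(frozen=True)
class MonoParams:
    """Mono-exponential parameters: S0 (a.u.) and ADC (mm^2/s, >= 0)."""

    S0: float
    adc: float

    def __post_init__(self) -> None:
        if not self.S0 > 0:
            raise ValueError("S0 must be positive")
        if self.adc < 0:
            raise ValueError("adc must be non-negative")


def froc_decay_exponent(
    D: float, beta: float, mu: float, protocol: AcquisitionProtocol, b=None
) -> np.ndarray:
    """Dimensionless decay exponent of the fractional-order model per b-value.

    Unchecked kernel shared by :func:`froc_signal` and the voxel fitters (the
    optimizer probes parameter values outside the dataclass invariants).
    """
    b_arr = protocol.b_array() if b is None else np.asarray(b, dtype=float)
    g = gradient_amplitude_for_b(b_arr, protocol)
    q = protocol.gamma * np.asarray(g) * protocol.delta  # 1/mm
    t_eff = protocol.Delta - (2 * beta - 1) / (2 * beta + 1) * protocol.delta
    return D * mu ** (2 * (beta - 1)) * q ** (2 * beta) * t_eff


def froc_signal(params: FrocParams, protocol: AcquisitionProtocol, b=None) -> np.ndarray:
    """Evaluate the fractional-order signal at the protocol's b-values.

    Returns one value per b-value (frame order), with ``S(0) = S0`` and every
    value in ``(0, S0]``.  ``b`` overrides the protocol's b-values when given.
    """
    expo = froc_decay_exponent(params.D, params.beta, params.mu, protocol, b)
    return params.S0 * np.exp(-expo)


def mono_signal(params: MonoParams, b_values) -> np.ndarray:
    """Mono-exponential decay ``S0 * exp(-b * ADC)`` over ``b_values``."""
    b = np.asarray(b_values, dtype=float)
    if np.any(b < 0):
        raise ValueError("b must be non-negative")
    return params.S0 * np.exp(-b * params.adc)
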