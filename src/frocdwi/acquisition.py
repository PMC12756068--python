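"""Multi-b diffusion acquisition description and b-value <-> gradient conversion.

The anomalous-diffusion signal equation is written in terms of the diffusion
gradient amplitude ``G_d`` rather than the b-value, so every signal evaluation
needs the pulse timing (gradient pulse width ``delta``, lobe separation
``Delta``) and the gyromagnetic ratio ``gamma``.  The rectangular-pulse
Stejskal-Tanner relation

    b = (gamma * G_d * delta)**2 * (Delta - delta / 3)

links the two descriptions; under this convention the beta = 1 limit of the
fractional-order model collapses exactly to ``exp(-b * D)``.

Internal unit system: seconds, s/mm^2, T/mm, mm, mm^2/s.  With those units
``gamma * G_d * delta`` is in 1/mm and every model exponent is dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from os import PathLike

import numpy as np

__all__ = [
    "GAMMA_PROTON",
    "AcquisitionProtocol",
    "gradient_amplitude_for_b",
    "b_from_gradient",
    "read_protocol",
]

#: Gyromagnetic ratio of the proton, rad s^-1 T^-1.
GAMMA_PROTON = 2.675222e8


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Multi-b DWI acquisition: b-values in frame order plus diffusion timing.

    Parameters
    ----------
    b_values : tuple of float
        Diffusion weightings in s/mm^2, one per 4D frame.  Frames may repeat
        a b-value (on-scanner averaging); the *distinct* values must be
        non-negative.
    delta : float
        Diffusion gradient pulse width, seconds.
    Delta : float
        Gradient lobe separation, seconds.  Must exceed ``delta``.
    gamma : float
        Gyromagnetic ratio, rad s^-1 T^-1 (proton by default).
    """

    b_values: tuple[float, ...]
    delta: float
    Delta: float
    gamma: float = GAMMA_PROTON

    def __post_init__(self) -> None:
        b = np.asarray(self.b_values, dtype=float)
        if b.size == 0:
            raise ValueError("protocol needs at least one b-value")
        if not np.all(np.isfinite(b)):
            raise ValueError("b-values must be finite")
        if np.any(b < 0):
            raise ValueError("b-values must be non-negative")
        if not (0 < self.delta < self.Delta):
            raise ValueError(
                f"need 0 < delta < Delta, got delta={self.delta}, Delta={self.Delta}"
            )
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        object.__setattr__(self, "b_values", tuple(float(x) for x in b))

    @property
    def unique_b(self) -> np.ndarray:
        """Sorted distinct b-values."""
        return np.unique(np.asarray(self.b_values))

    @property
    def n_frames(self) -> int:
        return len(self.b_values)

    def b_array(self) -> np.ndarray:
        return np.asarray(self.b_values, dtype=float)


def gradient_amplitude_for_b(b, protocol: AcquisitionProtocol):
    """Diffusion gradient amplitude ``G_d`` (T/mm) producing weighting ``b``.

    Inverts the rectangular-pulse Stejskal-Tanner relation
    ``b = (gamma*G_d*delta)**2 * (Delta - delta/3)``.  Vectorized over ``b``.
    """
    b_arr = np.asarray(b, dtype=float)
    if np.any(b_arr < 0):
        raise ValueError("b must be non-negative")
    scale = protocol.gamma * protocol.delta
    g = np.sqrt(b_arr / (protocol.Delta - protocol.delta / 3.0)) / scale
    return g if g.shape else float(g)


def b_from_gradient(g_d, protocol: AcquisitionProtocol):
    """Forward Stejskal-Tanner relation: b (s/mm^2) from ``G_d`` (T/mm)."""
    g = np.asarray(g_d, dtype=float)
    b = (protocol.gamma * g * protocol.delta) ** 2 * (
        protocol.Delta - protocol.delta / 3.0
    )
    return b if b.shape else float(b)


def read_protocol(
    bval_path: str | PathLike,
    delta: float,
    Delta: float,
    gamma: float = GAMMA_PROTON,
    n_frames: int | None = None,
) -> AcquisitionProtocol:
    """Read an FSL-style ``.bval`` sidecar (whitespace-separated, one line).

    ``n_frames``, when given, is checked against the number of tokens so a
    sidecar/volume mismatch fails loudly instead of mis-assigning frames.
    """
    with open(bval_path) as fh:
        tokens = fh.read().split()
    if not tokens:
        raise ValueError(f"empty b-value sidecar: {bval_path}")
    try:
        b_values = [float(t) for t in tokens]
    except ValueError as exc:
        raise ValueError(f"non-numeric token in b-value sidecar: {exc}") from None
    if n_frames is not None and len(b_values) != n_frames:
        raise ValueError(
            f"sidecar lists {len(b_values)} b-values but volume has {n_frames} frames"
        )
    return AcquisitionProtocol(tuple(b_values), delta=delta, Delta=Delta, gamma=gamma)
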