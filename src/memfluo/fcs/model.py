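"""Autocorrelation model for membrane FCS.

The fitted model combines 2D diffusion of membrane-bound fluorophores,
3D diffusion of free fluorophores in solution through an elongated
Gaussian detection volume, and reversible triplet blinking:

    G(τ) = 1 + [ (1/PN2D)·(1 + τ/τ2D)⁻¹
               + (1/PN3D)·(1 + τ/τ3D)⁻¹·(1 + SP·τ/τ3D)^(−1/2) ]
             · (1 − T + T·e^(−τ/τT)) / (1 − T)

PN2D and PN3D are effective particle numbers in the detection area and
volume, τ2D/τ3D the diffusion times, SP = (w0/wz)² the squared ratio of
lateral to axial beam waist, and T/τT the triplet fraction and lifetime.

The axial factor of the 3D term is rendered inconsistently across the
z-scan FCS literature; the exponent of (1 + SP·τ/τ3D) defaults to the
standard −1/2 but is switchable via ``sp_exponent``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = ["AcfParams", "acf_model", "InvalidParameterError"]


class InvalidParameterError(ValueError):
    """Raised when FCS model parameters are non-finite or out of range."""


@dataclass(frozen=True)
class AcfParams:
    """Parameters of the membrane FCS correlation model.

    ``pn3d=None`` means the bulk term is switched off entirely
    (1/PN3D = 0), the convention used at the membrane plane where the
    bulk contribution to the signal is negligible.
    """

    pn2d: float
    tau2d: float
    pn3d: float | None = None
    tau3d: float = 1.0e-3
    sp: float = 0.04
    t_frac: float = 0.0
    tau_t: float = 5.0e-6

    def __post_init__(self) -> None:
        vals = [self.pn2d, self.tau2d, self.tau3d, self.sp, self.t_frac, self.tau_t]
        if self.pn3d is not None:
            vals.append(self.pn3d)
        if not all(math.isfinite(v) for v in vals):
            raise InvalidParameterError("non-finite model parameter")
        if self.pn2d <= 0:
            raise InvalidParameterError(f"pn2d must be > 0, got {self.pn2d}")
        if self.pn3d is not None and self.pn3d <= 0:
            raise InvalidParameterError(f"pn3d must be > 0, got {self.pn3d}")
        if self.tau2d <= 0 or self.tau3d <= 0 or self.tau_t <= 0:
            raise InvalidParameterError("diffusion/triplet times must be > 0")
        if self.sp < 0:
            raise InvalidParameterError(f"sp must be >= 0, got {self.sp}")
        if not 0.0 <= self.t_frac < 1.0:
            raise InvalidParameterError(f"t_frac must be in [0, 1), got {self.t_frac}")

    def replace(self, **kwargs) -> "AcfParams":
        return replace(self, **kwargs)


def acf_model(tau, params: AcfParams, sp_exponent: float = -0.5):
    """Evaluate G(τ) for the combined 2D + 3D + triplet model.

    Parameters
    ----------
    tau : float or array
        Lag time(s) in seconds, > 0.
    params : AcfParams
        Model parameters (validated on construction).
    sp_exponent : float
        Exponent of the axial factor (1 + SP·τ/τ3D); −1/2 for the
        standard elongated Gaussian volume.

    Returns
    -------
    float or ndarray — dimensionless correlation, →1 as τ→∞.
    """
    tau = np.asarray(tau, dtype=float)
    if np.any(~np.isfinite(tau)) or np.any(tau <= 0):
        raise InvalidParameterError("lag times must be finite and > 0")

    g = (1.0 / params.pn2d) / (1.0 + tau / params.tau2d)
    if params.pn3d is not None:
        x = tau / params.tau3d
        g = g + (1.0 / params.pn3d) / (1.0 + x) * (1.0 + params.sp * x) ** sp_exponent
    t = params.t_frac
    if t > 0:
        g = g * (1.0 - t + t * np.exp(-tau / params.tau_t)) / (1.0 - t)
    out = 1.0 + g
    return out if out.ndim else float(out)
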