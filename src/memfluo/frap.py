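"""FRAP recovery analysis: single-exponential fit, mobile fraction, D.

The post-bleach recovery is modeled as I(t) = I0 + A·(1 − e^(−t/τ)).
The mobile fraction compares the recovered plateau with the pre-bleach
level:  mf = (I0 + A − I_post) / (I_pre − I_post).  The diffusion
constant uses the square-bleach convention D = L²/(4τ) with L equal to
half the bleach-square side; the convention is declared rather than
universal, so it is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = ["FrapFit", "fit_frap"]


@dataclass
class FrapFit:
    tau: float  # s
    mobile_fraction: float  # in [0, 1]
    diffusion_coeff: float  # µm²/s
    roi_side: float  # µm
    flagged: bool = False
    note: str = ""

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if not -0.05 <= self.mobile_fraction <= 1.05:
            raise ValueError("mobile_fraction grossly outside [0, 1]")


def frap_d_from_tau(tau: float, roi_side: float, geometry_factor: float = 4.0) -> float:
    """D = (roi_side/2)² / (geometry_factor·τ)."""
    half = roi_side / 2.0
    return half**2 / (geometry_factor * tau)


def fit_frap(
    time: np.ndarray,
    intensity: np.ndarray,
    roi_side: float,
    pre_bleach: float = 1.0,
    geometry_factor: float = 4.0,
) -> FrapFit:
    """Fit a post-bleach recovery curve.

    ``time`` starts at (or just after) the bleach; ``intensity`` is
    normalized so the pre-bleach level is ``pre_bleach``.  A recovery
    that is non-monotone beyond noise, or that overshoots the
    pre-bleach level, is flagged rather than rejected.
    """
    t = np.asarray(time, dtype=float)
    y = np.asarray(intensity, dtype=float)
    if t.size != y.size or t.size < 10:
        raise ValueError("need >= 10 post-bleach points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time must be strictly increasing")

    i_post = float(y[0])
    span = max(pre_bleach - i_post, 1e-12)
    a0 = max(float(y[-1]) - i_post, 1e-6 * span)
    tau0 = float(t[t.size // 3]) if t.size > 3 else float(t.max() / 3)

    def resid(p):
        i0, a, tau = p
        return i0 + a * (1.0 - np.exp(-t / tau)) - y

    sol = least_squares(
        resid, x0=[i_post, a0, max(tau0, 1e-6)],
        bounds=([-np.inf, 0.0, 1e-9], [np.inf, np.inf, np.inf]),
        method="trf",
    )
    i0, a, tau = sol.x
    mf = (i0 + a - i_post) / span
    flagged = False
    note = ""
    # non-monotone beyond noise: residual rms much larger than local noise
    noise = 1.4826 * np.median(np.abs(np.diff(y))) / np.sqrt(2.0)
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    if noise > 0 and rms > 3.0 * noise:
        flagged = True
        note = "recovery deviates from single exponential beyond noise"
    if mf > 1.02:
        flagged = True
        note = (note + "; " if note else "") + "recovery overshoots pre-bleach level"
    mf = float(np.clip(mf, 0.0, 1.0))
    # a near-zero amplitude leaves tau unconstrained
    if a < 0.02 * span:
        tau = float(t[-1])
        note = (note + "; " if note else "") + "no recovery: tau unconstrained"
    return FrapFit(
        tau=float(tau),
        mobile_fraction=mf,
        diffusion_coeff=frap_d_from_tau(tau, roi_side, geometry_factor),
        roi_side=roi_side,
        flagged=flagged,
        note=note,
    )
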