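"""Least-squares fitting of correlation curves and z-profiles.

Correlation fits use trust-region least squares with a coarse
multi-start over (PN2D, τ2D, T) because the combined 2D/3D/triplet
model is multi-modal at low signal-to-noise.  z-profiles (particle
number or diffusion time versus axial position) are fitted with a
quadratic; the Gaussian beam expansion makes both exactly parabolic
in z.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .curve import CorrelationCurve
from .model import AcfParams, acf_model

__all__ = ["AcfFit", "fit_acf", "ParabolaFit", "fit_parabola", "InsufficientDataError"]

# fit-parameter order; inv_pn3d = 1/PN3D so that "no bulk term" is the
# natural boundary value 0
_PARAM_NAMES = ("pn2d", "tau2d", "inv_pn3d", "tau3d", "sp", "t_frac", "tau_t")

DEFAULT_BOUNDS = {
    "pn2d": (1.0e-3, 1.0e9),
    "tau2d": (1.0e-6, 10.0),
    "inv_pn3d": (0.0, 1.0e3),
    "tau3d": (1.0e-6, 10.0),
    "sp": (0.0, 10.0),
    "t_frac": (0.0, 0.5),
    "tau_t": (1.0e-7, 1.0e-3),
}


class InsufficientDataError(ValueError):
    pass


@dataclass
class AcfFit:
    """Result of a correlation-model fit."""

    params: AcfParams
    converged: bool
    cost: float
    rms_residual: float
    red_chi2: float | None
    noise_floor: float
    lack_of_fit: bool
    n_points: int
    param_se: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)


def _params_to_vector(p: AcfParams) -> dict:
    return {
        "pn2d": p.pn2d,
        "tau2d": p.tau2d,
        "inv_pn3d": 0.0 if p.pn3d is None else 1.0 / p.pn3d,
        "tau3d": p.tau3d,
        "sp": p.sp,
        "t_frac": p.t_frac,
        "tau_t": p.tau_t,
    }


def _vector_to_params(v: dict) -> AcfParams:
    inv = v["inv_pn3d"]
    return AcfParams(
        pn2d=v["pn2d"],
        tau2d=v["tau2d"],
        pn3d=None if inv <= 0 else 1.0 / inv,
        tau3d=v["tau3d"],
        sp=v["sp"],
        t_frac=v["t_frac"],
        tau_t=v["tau_t"],
    )


def initial_guess(curve: CorrelationCurve) -> AcfParams:
    """Heuristic starting parameters from the curve shape.

    Amplitude of the first lags sets 1/PN2D; the lag where the
    correlation has decayed to half its amplitude sets τ2D.
    """
    g = curve.values - 1.0
    amp = float(np.mean(g[: max(3, g.size // 20)]))
    amp = max(amp, 1.0e-6)
    half = amp / 2.0
    below = np.nonzero(g < half)[0]
    tau_half = float(curve.lags[below[0]]) if below.size else float(curve.lags[-1])
    return AcfParams(pn2d=1.0 / amp, tau2d=max(tau_half, 2.0 * curve.lags[0]))


def _noise_floor(residual_source: np.ndarray) -> float:
    """Robust per-point noise estimate from successive differences."""
    d = np.diff(residual_source)
    if d.size == 0:
        return 0.0
    return 1.4826 * float(np.median(np.abs(d))) / np.sqrt(2.0)


def fit_acf(
    curve: CorrelationCurve,
    init: AcfParams | None = None,
    fixed: tuple = (),
    bounds: dict | None = None,
    multistart: bool = True,
    min_points: int = 20,
) -> AcfFit:
    """Weighted least-squares fit of the correlation model to a curve.

    Parameters
    ----------
    curve : CorrelationCurve (>= ``min_points`` lags).
    init : starting parameters; derived from the curve when omitted.
        ``init.pn3d is None`` fixes the bulk term off (1/PN3D = 0).
    fixed : names of parameters to hold at their initial values; use
        "inv_pn3d" to pin the bulk amplitude.
    bounds : per-parameter (lo, hi) overrides of DEFAULT_BOUNDS.
    multistart : start from a 3×3×3 grid over (PN2D, τ2D, T); the best
        few starts are polished.  The model is multi-modal at low SNR.

    Non-convergence is reported via ``converged=False``, never silently.
    """
    if len(curve) < min_points:
        raise InsufficientDataError(f"need >= {min_points} lags, got {len(curve)}")
    if init is None:
        init = initial_guess(curve)
    fixed = set(fixed)
    if init.pn3d is None:
        fixed.add("inv_pn3d")
    bnds = dict(DEFAULT_BOUNDS)
    if bounds:
        bnds.update(bounds)

    v0 = _params_to_vector(init)
    for name in _PARAM_NAMES:
        lo, hi = bnds[name]
        if not lo <= v0[name] <= hi:
            raise ValueError(f"init {name}={v0[name]} outside bounds ({lo}, {hi})")

    free = [n for n in _PARAM_NAMES if n not in fixed]
    if not free:
        raise ValueError("all parameters fixed")
    weights = 1.0 / curve.se if curve.se is not None and np.all(curve.se > 0) else None

    def residuals(x: np.ndarray) -> np.ndarray:
        v = dict(v0)
        v.update(zip(free, x))
        r = acf_model(curve.lags, _vector_to_params(v)) - curve.values
        return r * weights if weights is not None else r

    # multi-start grid over the dominant parameters
    starts = [np.array([v0[n] for n in free])]
    if multistart:
        fac = (0.3, 1.0, 3.0)
        tvals = (0.0, 0.1, 0.3) if "t_frac" in free else (None,)
        for fp in fac:
            for ft in fac:
                for tv in tvals:
                    v = dict(v0)
                    if "pn2d" in free:
                        v["pn2d"] = np.clip(v0["pn2d"] * fp, *bnds["pn2d"])
                    if "tau2d" in free:
                        v["tau2d"] = np.clip(v0["tau2d"] * ft, *bnds["tau2d"])
                    if tv is not None:
                        v["t_frac"] = tv
                    starts.append(np.array([v[n] for n in free]))

    costs = [0.5 * float(np.sum(residuals(s) ** 2)) for s in starts]
    order = np.argsort(costs)
    lo = np.array([bnds[n][0] for n in free])
    hi = np.array([bnds[n][1] for n in free])
    best = None
    for idx in order[:3]:
        try:
            sol = least_squares(
                residuals, starts[idx], bounds=(lo, hi), method="trf", ftol=1e-9,
                xtol=1e-12, gtol=1e-12, max_nfev=2000,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol

    if best is None:
        return AcfFit(
            params=init, converged=False, cost=np.inf,
            rms_residual=np.inf, red_chi2=None, noise_floor=0.0,
            lack_of_fit=True, n_points=len(curve),
        )

    v = dict(v0)
    v.update(zip(free, best.x))
    params = _vector_to_params(v)
    # parameter standard errors from the Gauss-Newton approximation;
    # scaled by the residual variance when the fit is unweighted
    param_se: dict[str, float] = {}
    try:
        jtj = best.jac.T @ best.jac
        cov = np.linalg.pinv(jtj)
        dof = max(1, len(curve) - len(free))
        if weights is None:
            cov = cov * (2.0 * best.cost / dof)
        for i, name in enumerate(free):
            param_se[name] = float(np.sqrt(max(cov[i, i], 0.0)))
    except Exception:
        pass
    raw_res = acf_model(curve.lags, params) - curve.values
    rms = float(np.sqrt(np.mean(raw_res**2)))
    red_chi2 = None
    if weights is not None:
        dof = max(1, len(curve) - len(free))
        red_chi2 = float(np.sum((raw_res * weights) ** 2) / dof)
    floor = _noise_floor(curve.values)
    # lack of fit: weighted residuals against known errors when
    # available, otherwise raw rms against the empirical noise floor
    if red_chi2 is not None:
        lack = bool(red_chi2 > 3.0)
    else:
        lack = bool(rms > 3.0 * floor) if floor > 0 else False
    return AcfFit(
        params=params,
        converged=bool(best.status > 0),
        cost=float(best.cost),
        rms_residual=rms,
        red_chi2=red_chi2,
        noise_floor=floor,
        lack_of_fit=lack,
        n_points=len(curve),
        param_se=param_se,
    )


@dataclass
class ParabolaFit:
    """Quadratic fit of a positive quantity versus axial position."""

    vertex_x: float
    vertex_y: float
    curvature: float  # coefficient of x²
    fallback: bool  # True when the sample minimum was used instead
    coeffs: np.ndarray | None = None

    def __call__(self, x):
        if self.coeffs is None:
            raise ValueError("no polynomial available (degenerate fit)")
        return np.polyval(self.coeffs, x)


def fit_parabola(
    x: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    min_points: int = 5,
) -> ParabolaFit:
    """Least-squares parabola with a flagged fall-back to the sample minimum.

    ``weights`` multiply the residuals (use 1/σ for known per-point
    uncertainties).  The vertex is preferred unless it lies outside the
    scanned range, the curvature is non-positive (no interior minimum)
    or the vertex value is non-positive; in those cases the sample
    minimum is returned with ``fallback=True``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise InsufficientDataError(f"need >= 3 points, got {x.size}")
    if x.size < min_points:
        raise InsufficientDataError(f"need >= {min_points} points, got {x.size}")
    if np.any(y <= 0):
        raise ValueError("profile values must be > 0")
    w = None
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if not np.all(np.isfinite(w)) or np.any(w <= 0):
            w = None  # degenerate weights: fall back to uniform

    # center x for conditioning
    x0 = x.mean()
    c = np.polyfit(x - x0, y, 2, w=w)
    a, b, c0 = c
    coeffs = np.array([a, b - 2 * a * x0, c0 - b * x0 + a * x0**2])
    if a > 0:
        vx = -b / (2 * a) + x0
        vy = c0 - b**2 / (4 * a)
        # the parabola must actually rise across the scanned range;
        # otherwise the profile is flat and the vertex is numerical dust
        rise = a * float(np.max((x - vx) ** 2))
        if x.min() <= vx <= x.max() and vy > 0 and rise > 1e-3 * abs(vy):
            return ParabolaFit(float(vx), float(vy), float(a), False, coeffs)
    i = int(np.argmin(y))
    return ParabolaFit(float(x[i]), float(y[i]), float(a), True, coeffs)
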