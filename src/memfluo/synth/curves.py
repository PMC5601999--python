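"""Synthetic titration and FRAP curve generators."""

from __future__ import annotations

import numpy as np

from ..binding import TitrationSeries, titration_model
from ..frap import frap_d_from_tau

__all__ = ["synth_titration", "synth_frap", "DEFAULT_LIGAND_GRID"]

# ligand grid up to a 900 µM titrant stock against 80 µM protein
DEFAULT_LIGAND_GRID = np.array(
    [0.0, 5.0, 10.0, 20.0, 40.0, 80.0, 160.0, 320.0, 640.0, 900.0]
)


def synth_titration(
    kd: float,
    ddmax_per_residue: dict,
    protein_conc: float = 80.0,
    ligand_grid: np.ndarray | None = None,
    noise: float = 0.0,
    seed: int = 0,
    model: str = "quadratic",
) -> list:
    """Two-state titration curves with Gaussian noise on Δδ.

    The noise fraction applies to each residue's Δδmax; the combined
    perturbation is split between the ¹H and ¹⁵N axes so both carry
    signal.  Returns one TitrationSeries per residue.
    """
    if ligand_grid is None:
        ligand_grid = DEFAULT_LIGAND_GRID
    lig = np.asarray(ligand_grid, dtype=float)
    rng = np.random.default_rng(seed)
    out = []
    for res, ddmax in ddmax_per_residue.items():
        dd = titration_model(lig, kd, ddmax, protein_conc, model)
        if noise > 0:
            dd = dd + noise * ddmax * rng.standard_normal(lig.size)
            dd = np.clip(dd, 0.0, None)
        dd[0] = 0.0  # reference point defines the zero
        # split Δδ between axes: 60% on ¹H, the rest on ¹⁵N (w = 0.15)
        dh = 0.6 * dd
        dn = np.sqrt(np.clip(dd**2 - dh**2, 0.0, None)) / 0.15
        out.append(
            TitrationSeries(
                residue_label=str(res), ligand_conc=lig,
                delta_h=dh, delta_n=dn, protein_conc=protein_conc,
            )
        )
    return out


def synth_frap(
    d_true: float,
    mobile_fraction: float,
    roi_side: float = 2.0,
    pre_bleach: float = 1.0,
    bleach_depth: float = 0.1,
    n_points: int = 60,
    t_max_factor: float = 6.0,
    noise: float = 0.0,
    seed: int = 0,
    geometry_factor: float = 4.0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Single-exponential FRAP recovery with the package D convention.

    τ is derived from d_true through D = (roi_side/2)²/(g·τ); the curve
    recovers from ``bleach_depth`` toward the mobile-fraction plateau.
    Returns (time, intensity, truth).
    """
    if not 0.0 <= mobile_fraction <= 1.0:
        raise ValueError("mobile_fraction must be in [0, 1]")
    half = roi_side / 2.0
    tau = half**2 / (geometry_factor * d_true)
    t = np.linspace(0.0, t_max_factor * tau, n_points)
    i_post = bleach_depth * pre_bleach
    plateau = i_post + mobile_fraction * (pre_bleach - i_post)
    y = i_post + (plateau - i_post) * (1.0 - np.exp(-t / tau))
    if noise > 0:
        rng = np.random.default_rng(seed)
        y = y + noise * pre_bleach * rng.standard_normal(t.size)
    truth = {
        "tau": tau,
        "mobile_fraction": mobile_fraction,
        "D": frap_d_from_tau(tau, roi_side, geometry_factor),
        "seed": seed,
    }
    return t, y, truth
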