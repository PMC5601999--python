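"""Synthetic z-scan series generator.

Two modes:

* ``fast`` — per-z correlation curves are generated directly from the
  analytic model with the Gaussian-beam expansion
  PN2D(z) = c·π·w(z)² and τ2D(z) = w(z)²/(4D), plus seeded
  multiplicative noise whose per-lag standard deviation follows the
  simplified Koppel scaling sd ∝ √(τ/duration).
* ``oracle`` — the Brownian-dynamics photon simulator is run at every
  z-position with the local beam radius w(z) and the curves are
  computed with the multiple-tau correlator.  Slow; exists so the fast
  shortcut is always checkable against first principles.

Defaults mirror a typical membrane z-scan protocol: 20 steps of
150 nm starting 1.5 µm below the waist, 60 s per correlation curve.
"""

from __future__ import annotations

import numpy as np

from ..fcs.correlate import correlate_trace
from ..fcs.curve import CorrelationCurve
from ..fcs.model import AcfParams, acf_model
from ..fcs.zscan import InstrumentConfig, ZScanSeries
from .trace import SimConfig, simulate_membrane_trace

__all__ = ["simulate_zscan_series", "default_lag_grid"]


def default_lag_grid(n: int = 128, tau_min: float = 4.0e-6, tau_max: float = 10.0) -> np.ndarray:
    """Log-spaced lag grid resembling a multiple-tau correlator ladder."""
    return np.geomspace(tau_min, tau_max, n)


def _fast_curve(
    rng: np.random.Generator,
    params: AcfParams,
    duration: float,
    noise_scale: float,
    lags: np.ndarray,
    mean_intensity: float,
) -> CorrelationCurve:
    g = acf_model(lags, params)
    # simplified Koppel scaling: absolute G noise grows as sqrt(τ/T),
    # proportional to the zero-lag amplitude (calibrated against the
    # Brownian-dynamics oracle simulator)
    amp = acf_model(lags[0] * 1e-3 + 1e-12, params) - 1.0
    sd = noise_scale * amp * np.sqrt(lags / duration)
    noisy = g + sd * rng.standard_normal(lags.size)
    return CorrelationCurve(
        lags=lags, values=noisy, se=sd, duration=duration,
        mean_intensity=mean_intensity,
    )


def simulate_zscan_series(
    config: SimConfig,
    instrument: InstrumentConfig | None = None,
    mode: str = "fast",
    membrane_z: float = 0.0,
    z_start: float = -1.5,
    noise_scale: float = 1.0,
    intensity_noise: float = 0.01,
    curve_duration: float = 60.0,
    with_lipid_channel: bool = False,
    lipid_density: float = 500.0,
    lipid_d: float = 3.0,
) -> tuple[ZScanSeries, dict]:
    """Simulate one z-scan of a membrane carrying a single cluster species.

    Parameters
    ----------
    config : SimConfig whose first (and only) n_species entry defines
        the oligomer size, surface density and D of the clusters.
    membrane_z : true membrane position on the scan axis (µm).
    z_start : first scan position relative to the waist (µm).
    noise_scale : multiplier of the √(τ/duration) per-lag noise law.
    with_lipid_channel : also emit membrane-marker curves for QC.

    Returns the ZScanSeries and a ground-truth record.
    """
    if instrument is None:
        instrument = InstrumentConfig(w0=config.w0)
    if len(config.n_species) != 1:
        raise ValueError("z-scan generator supports exactly one cluster species")
    if mode not in ("fast", "oracle"):
        raise ValueError(f"unknown mode {mode!r}")

    n_mono, density, d_coeff = config.n_species[0]
    rng = np.random.default_rng(config.seed)
    z = z_start + instrument.z_step * np.arange(instrument.n_steps)
    w2 = instrument.beam_radius_sq(z - membrane_z)  # µm²

    pn2d_z = density * np.pi * w2
    tau2d_z = w2 / (4.0 * d_coeff)
    # detected rate: clusters x n x q x (area integral of the profile)
    q = config.brightness_per_monomer
    intens_z = density * n_mono * q * (np.pi * w2 / 2.0) + config.background

    truth = {
        "seed": config.seed,
        "mode": mode,
        "n": n_mono,
        "density": density,
        "D": d_coeff,
        "membrane_z": membrane_z,
        "pn2d_min": float(density * np.pi * instrument.w0**2),
        "tau2d_min": float(instrument.w0**2 / (4.0 * d_coeff)),
        "phi_cluster": float(n_mono * q / 2.0),
        "background": config.background,
        "w0": instrument.w0,
    }

    curves: list[CorrelationCurve] = []
    lipid: list[CorrelationCurve] | None = [] if with_lipid_channel else None
    if mode == "fast":
        lags = default_lag_grid()
        for i in range(z.size):
            p = AcfParams(
                pn2d=pn2d_z[i],
                tau2d=tau2d_z[i],
                pn3d=None,
                t_frac=config.triplet[0] if config.triplet else 0.0,
                tau_t=config.triplet[1] if config.triplet else 5e-6,
            )
            curves.append(
                _fast_curve(rng, p, curve_duration, noise_scale, lags, intens_z[i])
            )
            if lipid is not None:
                lp = AcfParams(
                    pn2d=lipid_density * np.pi * w2[i],
                    tau2d=w2[i] / (4.0 * lipid_d),
                    pn3d=None,
                )
                lipid.append(
                    _fast_curve(rng, lp, curve_duration, noise_scale, lags, 1.0)
                )
        intensities = intens_z * (1.0 + intensity_noise * rng.standard_normal(z.size))
    else:
        intensities = np.empty(z.size)
        for i in range(z.size):
            w_i = float(np.sqrt(w2[i]))
            cfg_i = SimConfig(
                n_species=((n_mono, density, d_coeff),),
                bulk=config.bulk,
                brightness_per_monomer=q,
                w0=w_i,
                wz=config.wz,
                box_size=max(config.box, 20.0 * w_i),
                triplet=config.triplet,
                bin_width=config.bin_width,
                duration=curve_duration,
                background=config.background,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            counts, _ = simulate_membrane_trace(cfg_i)
            cur = correlate_trace(counts, cfg_i.bin_width)
            curves.append(cur)
            intensities[i] = cur.mean_intensity
            if lipid is not None:
                raise NotImplementedError("lipid channel is fast-mode only")

    series = ZScanSeries(
        z_positions=z, curves=curves, intensities=intensities, lipid_curves=lipid,
        meta={"truth": truth},
    )
    return series, truth
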