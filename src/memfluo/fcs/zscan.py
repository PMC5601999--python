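"""z-scan FCS analysis: from per-z correlation curves to oligomeric state.

A membrane positioned in a Gaussian beam is scanned axially; the beam
cross-section w(z)² grows quadratically with distance from the waist,
so both the effective particle number PN2D(z) and the diffusion time
τ2D(z) trace parabolas whose minima report the in-membrane values.
From the minima and the mean count rate at the membrane plane the
analysis derives:

* cluster brightness  ϕ_cluster = I / min PN2D         (counts/s/particle)
* oligomeric state    ϕ_cluster / ϕ_monomer
* diffusion constant  D = w0² / (4 · min τ2D)
* surface concentration  c = state · min PN2D / (π w0²), in nmol/m²

The membrane-marker (lipid) channel, when present, is used as a
bilayer quality control: its in-membrane diffusion must be free and
plausibly fast, and a single-component fit must describe it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .. import units
from .curve import CorrelationCurve
from .fitting import AcfFit, ParabolaFit, fit_acf, fit_parabola
from .model import AcfParams, InvalidParameterError

__all__ = [
    "InstrumentConfig",
    "ZScanSeries",
    "ZScanResult",
    "MonomerReference",
    "analyze_zscan",
    "oligomeric_state",
    "diffusion_coefficient",
    "surface_concentration_fcs",
    "surface_concentration_intensity",
    "monomer_reference_from_results",
]

# plausible free-lipid diffusion range for the bilayer QC, µm²/s
LIPID_D_RANGE = (0.5, 20.0)


@dataclass(frozen=True)
class InstrumentConfig:
    """Optical configuration of the z-scan instrument."""

    w0: float = 0.25  # beam-waist radius, µm
    wavelength: float = 488.0  # nm
    refractive_index: float = 1.33
    z_step: float = 0.15  # µm
    n_steps: int = 20

    def __post_init__(self) -> None:
        if self.w0 <= 0:
            raise ValueError("w0 must be > 0")
        if self.n_steps < 5:
            raise ValueError("need >= 5 z-steps for a stable parabola fit")

    def beam_radius_sq(self, dz) -> np.ndarray:
        """w(z)² in µm² at axial distance dz (µm) from the waist."""
        lam_um = units.nm_to_um(self.wavelength)
        a = lam_um / (np.pi * self.refractive_index * self.w0**2)
        return self.w0**2 * (1.0 + (a * np.asarray(dz, dtype=float)) ** 2)


@dataclass
class ZScanSeries:
    """Per-z correlation curves and mean intensities from one membrane scan."""

    z_positions: np.ndarray  # µm, strictly increasing, constant spacing
    curves: list  # CorrelationCurve per z
    intensities: np.ndarray  # counts/s per z
    lipid_curves: list | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.z_positions = np.asarray(self.z_positions, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        n = self.z_positions.size
        if len(self.curves) != n or self.intensities.size != n:
            raise ValueError("per-z sequences must have equal lengths")
        if self.lipid_curves is not None and len(self.lipid_curves) != n:
            raise ValueError("lipid_curves length mismatch")
        dz = np.diff(self.z_positions)
        if np.any(dz <= 0):
            raise ValueError("z_positions must be strictly increasing")
        if n > 2 and (dz.max() - dz.min()) > 0.01 * dz.mean():
            raise ValueError("z spacing must be constant within 1%")


@dataclass(frozen=True)
class MonomerReference:
    """Brightness of the monomeric reference construct."""

    phi_monomer: float  # counts/s per particle
    n_measurements: int = 1
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.phi_monomer <= 0:
            raise InvalidParameterError("phi_monomer must be > 0")


@dataclass
class ZScanResult:
    min_pn2d: float
    min_tau2d: float
    intensity_at_min: float  # counts/s
    phi_cluster: float  # counts/s/particle
    oligomeric_state: float | None
    diffusion_coeff: float  # µm²/s
    surface_conc: float | None  # nmol/m²
    fit_quality: np.ndarray  # per-z rms residuals
    qc_pass: bool
    vertex_z: float = np.nan
    pn_parabola: ParabolaFit | None = None
    tau_parabola: ParabolaFit | None = None
    notes: list = field(default_factory=list)


def oligomeric_state(phi_cluster: float, phi_monomer: float) -> float:
    """Average oligomeric state: ratio of cluster to monomer brightness."""
    if phi_monomer <= 0:
        raise InvalidParameterError("phi_monomer must be > 0")
    if phi_cluster <= 0:
        raise InvalidParameterError("phi_cluster must be > 0")
    return phi_cluster / phi_monomer


def diffusion_coefficient(min_tau2d: float, w0: float) -> float:
    """Lateral diffusion constant D = w0² / (4·min τ2D), µm²/s."""
    if min_tau2d <= 0 or w0 <= 0:
        raise InvalidParameterError("min_tau2d and w0 must be > 0")
    return w0**2 / (4.0 * min_tau2d)


def surface_concentration_fcs(state: float, pn2d: float, w0: float) -> float:
    """Surface concentration c = state·PN2D/(π·w0²), returned in nmol/m²."""
    if state <= 0 or pn2d <= 0 or w0 <= 0:
        raise InvalidParameterError("state, pn2d and w0 must be > 0")
    per_um2 = state * pn2d / (np.pi * w0**2)
    return units.molecules_per_um2_to_nmol_per_m2(per_um2)


def surface_concentration_intensity(membrane_intensity: float, calibration: float) -> float:
    """Surface concentration from intensity via a calibration factor.

    ``calibration`` is counts/s per nmol/m², obtained from a reference
    solution of known concentration; it has no default on purpose.
    """
    if calibration is None or calibration <= 0:
        raise InvalidParameterError("a positive intensity calibration is required")
    if membrane_intensity < 0:
        raise InvalidParameterError("intensity must be >= 0")
    return membrane_intensity / calibration


def monomer_reference_from_results(results: list) -> MonomerReference:
    """Pool ϕ_cluster of replicate monomer-control scans into a reference."""
    phis = np.array([r.phi_cluster for r in results], dtype=float)
    if phis.size == 0 or np.any(phis <= 0):
        raise InvalidParameterError("monomer scans must yield positive brightness")
    return MonomerReference(
        phi_monomer=float(phis.mean()),
        n_measurements=phis.size,
        sd=float(phis.std(ddof=1)) if phis.size > 1 else 0.0,
    )


def _fit_all_z(curves, fixed, init) -> list[AcfFit]:
    fits = []
    for c in curves:
        try:
            fits.append(fit_acf(c, init=init, fixed=fixed))
        except Exception:
            fits.append(None)
    return fits


def analyze_zscan(
    series: ZScanSeries,
    instrument: InstrumentConfig,
    monomer: MonomerReference | None = None,
    background: float = 0.0,
    fixed: tuple = ("tau3d", "sp", "tau_t"),
    init: AcfParams | None = None,
) -> ZScanResult:
    """Full z-scan analysis of one membrane scan.

    Per-z correlation curves are fitted with the bulk amplitude free;
    parabolas are then fitted to PN2D(z) and τ2D(z) over the z-points
    whose correlation fit converged, and the curve nearest the PN2D
    vertex is refit with the bulk term pinned off (1/PN3D = 0), since
    the bulk contribution is negligible at the membrane plane.

    ``background`` (counts/s) is subtracted from the mean intensity
    before the brightness is formed.  QC fails when the PN2D parabola
    degenerates to a sample-minimum fall-back in both channels or when
    the lipid-channel control does not behave like a freely diffusing
    single component.
    """
    notes: list[str] = []
    fits = _fit_all_z(series.curves, fixed, init)
    ok = np.array([f is not None and f.converged for f in fits])
    if ok.sum() < 5:
        raise InvalidParameterError("fewer than 5 usable z-points")

    z = series.z_positions[ok]
    good = [f for f, o in zip(fits, ok) if o]
    pn = np.array([f.params.pn2d for f in good])
    tau = np.array([f.params.tau2d for f in good])

    def _weights(key: str, values: np.ndarray) -> np.ndarray | None:
        se = np.array([f.param_se.get(key, np.nan) for f in good])
        if np.any(~np.isfinite(se)) or np.any(se <= 0):
            return None
        return 1.0 / se

    pn_par = fit_parabola(z, pn, weights=_weights("pn2d", pn))
    tau_par = fit_parabola(z, tau, weights=_weights("tau2d", tau))
    if pn_par.fallback:
        notes.append("PN2D(z) parabola fell back to sample minimum")
    if tau_par.fallback:
        notes.append("tau2D(z) parabola fell back to sample minimum")

    vertex_z = pn_par.vertex_x
    # refit the vertex-nearest curve with the bulk term off
    i_vertex = int(np.argmin(np.abs(series.z_positions - vertex_z)))
    vertex_fit = fits[i_vertex]
    if vertex_fit is not None:
        refit = fit_acf(
            series.curves[i_vertex],
            init=vertex_fit.params.replace(pn3d=None),
            fixed=tuple(set(fixed) | {"inv_pn3d"}),
        )
        if refit.converged:
            fits[i_vertex] = refit

    min_pn2d = pn_par.vertex_y
    min_tau2d = tau_par.vertex_y
    if min_pn2d <= 0 or min_tau2d <= 0:
        raise InvalidParameterError("degenerate z-profile: non-positive vertex")

    # mean intensity at the membrane plane: quadratic in z as well
    int_par = fit_parabola(series.z_positions, series.intensities)
    if int_par.coeffs is not None and not int_par.fallback:
        intensity_at_min = float(int_par(vertex_z))
    else:
        intensity_at_min = float(series.intensities[i_vertex])

    phi_cluster = (intensity_at_min - background) / min_pn2d
    if phi_cluster <= 0:
        raise InvalidParameterError("non-positive cluster brightness")

    d_coeff = diffusion_coefficient(min_tau2d, instrument.w0)
    state = None
    conc = None
    if monomer is not None:
        state = oligomeric_state(phi_cluster, monomer.phi_monomer)
        conc = surface_concentration_fcs(state, min_pn2d, instrument.w0)

    # ---- QC ----
    qc = not (pn_par.fallback and tau_par.fallback)
    if series.lipid_curves is not None:
        lipid_fit = None
        try:
            lipid_fit = fit_acf(
                series.lipid_curves[i_vertex],
                init=AcfParams(pn2d=10.0, tau2d=1e-3, pn3d=None),
                fixed=("inv_pn3d", "tau3d", "sp", "tau_t"),
            )
        except Exception:
            notes.append("lipid-channel fit failed")
        if lipid_fit is None or not lipid_fit.converged:
            qc = False
            notes.append("lipid channel: no converged fit")
        else:
            d_lipid = diffusion_coefficient(lipid_fit.params.tau2d, instrument.w0)
            if not LIPID_D_RANGE[0] <= d_lipid <= LIPID_D_RANGE[1]:
                qc = False
                notes.append(f"lipid D {d_lipid:.2f} µm²/s outside {LIPID_D_RANGE}")
            if lipid_fit.lack_of_fit:
                qc = False
                notes.append("lipid channel: single-component lack of fit")
    fit_quality = np.array([np.nan if f is None else f.rms_residual for f in fits])
    return ZScanResult(
        min_pn2d=float(min_pn2d),
        min_tau2d=float(min_tau2d),
        intensity_at_min=intensity_at_min,
        phi_cluster=float(phi_cluster),
        oligomeric_state=state,
        diffusion_coeff=float(d_coeff),
        surface_conc=conc,
        fit_quality=fit_quality,
        qc_pass=bool(qc),
        vertex_z=float(vertex_z),
        pn_parabola=pn_par,
        tau_parabola=tau_par,
        notes=notes,
    )
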